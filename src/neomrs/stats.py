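"""Group comparisons and GLM confounder adjustment.

The group-comparison gate mirrors the study's analysis plan: Shapiro-Wilk
normality per group at alpha = 0.05; both normal -> two-tailed unpaired
equal-variance t-test, otherwise Mann-Whitney U (exact for small samples
without ties). Percent change is the IUGR-vs-control change of group means.
The GLM is an ordinary least squares fit of the outcome on an intercept,
the group indicator, and the confounders (primary: brain temperature and
tissue fraction; secondary: litter indicators and neighbor-stillbirth
count); no multiple-testing correction is applied by default, with an
optional Benjamini-Hochberg flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigError, DomainError

#: Rows of the effect table: pooled rows sum member concentrations first.
EFFECT_TABLE_ROWS = (
    ("Aspartate", ("aspartate",)),
    ("NAA", ("naa",)),
    ("NAA + NAAG", ("naa", "naag")),
    ("Glutamate", ("glutamate",)),
    ("Glycine", ("glycine",)),
    ("myo-Inositol + Glycine", ("myo_inositol", "glycine")),
)

GROUP_ORDER = ("control", "iugr")


@dataclass
class ComparisonResult:
    mean_control: float
    sd_control: float
    n_control: int
    mean_iugr: float
    sd_iugr: float
    n_iugr: int
    percent_change: float
    test_used: str          # "t" or "mann_whitney"
    statistic: float
    p_value: float


def compare_groups(values, group_labels, alpha=0.05,
                   equal_var=True) -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha`` -> unpaired two-tailed t-test
    (equal-variance by default, Welch via ``equal_var=False``); otherwise
    Mann-Whitney U, exact for n <= 8 per group when there are no ties.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    a = values[groups == GROUP_ORDER[0]]
    b = values[groups == GROUP_ORDER[1]]
    if a.size < 3 or b.size < 3:
        raise DomainError("need at least 3 values per group")
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:
            normal = False   # Shapiro undefined for constant data
            continue
        if sps.shapiro(g).pvalue < alpha:
            normal = False
    if normal:
        stat, p = sps.ttest_ind(b, a, equal_var=equal_var)
        test = "t"
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn("zero variance in both groups; p set to 1",
                          stacklevel=2)
            stat, p = 0.0, 1.0
        else:
            method = "exact" if (a.size <= 8 and b.size <= 8
                                 and np.unique(values).size == values.size) \
                else "auto"
            stat, p = sps.mannwhitneyu(b, a, alternative="two-sided",
                                       method=method)
        test = "mann_whitney"
    pct = 100.0 * (b.mean() - a.mean()) / a.mean() if a.mean() != 0 else np.nan
    return ComparisonResult(
        mean_control=float(a.mean()), sd_control=float(a.std(ddof=1)),
        n_control=int(a.size), mean_iugr=float(b.mean()),
        sd_iugr=float(b.std(ddof=1)), n_iugr=int(b.size),
        percent_change=float(pct), test_used=test,
        statistic=float(stat), p_value=float(p))


@dataclass
class GlmResult:
    group_effect: float
    group_se: float
    p_value: float
    covariate_names: list
    residual_df: int
    params: pd.Series
    model: object = None


def glm_adjust(outcome, group, covariates=None) -> GlmResult:
    """OLS of outcome on [intercept, group indicator, covariates].

    ``group`` may be the 0/1 indicator or control/iugr labels. The adjusted
    group effect and its two-sided p-value come from the coefficient
    t-statistic. A rank-deficient design raises an error naming the
    collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "USO":
        g = (g == GROUP_ORDER[1]).astype(float)
    else:
        g = g.astype(float)
    X = pd.DataFrame({"group": g})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X, prepend=True)
    if y.size <= X.shape[1]:
        raise DomainError("more parameters than observations")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name the offending columns via QR diagonal
        _, r = np.linalg.qr(X.values)
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ConfigError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return GlmResult(
        group_effect=float(fit.params["group"]),
        group_se=float(fit.bse["group"]),
        p_value=float(fit.pvalues["group"]),
        covariate_names=[c for c in X.columns if c not in ("const", "group")],
        residual_df=int(fit.df_resid), params=fit.params, model=fit)


def litter_design(litters) -> pd.DataFrame:
    """Litter as fixed-effect indicator columns (first litter = reference)."""
    litters = pd.Series(litters).astype(str).reset_index(drop=True)
    levels = sorted(litters.unique())
    return pd.DataFrame({f"litter_{lv}": (litters == lv).astype(float)
                         for lv in levels[1:]})


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the summaries)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        rank = n - rank_rev
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj


def significance_stars(p) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_effect_table(quant_tables: pd.DataFrame, cohort: pd.DataFrame,
                           covariates: pd.DataFrame = None, alpha=0.05,
                           min_per_group=3, bh_correct=False) -> pd.DataFrame:
    """Per-(metabolite row, region) percent change with raw and adjusted p.

    ``quant_tables`` is long-format: subject, region, metabolite,
    concentration, retained. A metabolite is excluded from a subject when
    not retained there; a pooled row requires all members retained (the
    pool is the sum of concentrations, compared as one variable). A cell
    needs ``min_per_group`` subjects per group, else it is marked
    not-evaluable. ``covariates`` (optional) is indexed like the cohort
    rows (subject, region) with the GLM confounders.
    """
    need = {"subject", "region", "metabolite", "concentration"}
    if not need <= set(quant_tables.columns):
        raise ConfigError(f"quant table needs columns {sorted(need)}")
    q = quant_tables.copy()
    if "retained" in q.columns:
        q = q[q["retained"]]
    groups = cohort.drop_duplicates("subject").set_index("subject")["group"]
    rows = []
    regions = sorted(q["region"].unique(),
                     key=lambda r: ["cortex", "hippocampus", "striatum"].index(r)
                     if r in ("cortex", "hippocampus", "striatum") else 99)
    for row_name, members in EFFECT_TABLE_ROWS:
        for region in regions:
            sub = q[(q["region"] == region) & q["metabolite"].isin(members)]
            counts = sub.groupby("subject")["metabolite"].nunique()
            complete = counts[counts == len(members)].index
            pooled = (sub[sub["subject"].isin(complete)]
                      .groupby("subject")["concentration"].sum())
            g = groups.loc[pooled.index]
            rec = dict(metabolite=row_name, region=region)
            n_ctl = int((g == "control").sum())
            n_iugr = int((g == "iugr").sum())
            if n_ctl < min_per_group or n_iugr < min_per_group:
                rec.update(percent_change=np.nan, p_raw=np.nan,
                           p_adjusted=np.nan, evaluable=False,
                           n_control=n_ctl, n_iugr=n_iugr, test="")
                rows.append(rec)
                continue
            cmp = compare_groups(pooled.values, g.values, alpha=alpha)
            rec.update(percent_change=cmp.percent_change,
                       p_raw=cmp.p_value, test=cmp.test_used,
                       evaluable=True, n_control=n_ctl, n_iugr=n_iugr)
            if covariates is not None:
                cov = covariates.loc[[(s, region) for s in pooled.index]]
                cov = cov.reset_index(drop=True)
                try:
                    glm = glm_adjust(pooled.values, g.values, cov)
                    rec["p_adjusted"] = glm.p_value
                except (ConfigError, DomainError):
                    rec["p_adjusted"] = np.nan
            else:
                rec["p_adjusted"] = np.nan
            rows.append(rec)
    out = pd.DataFrame(rows)
    if bh_correct and out["p_raw"].notna().any():
        mask = out["p_raw"].notna()
        out.loc[mask, "p_raw_bh"] = benjamini_hochberg(out.loc[mask, "p_raw"])
    out["stars"] = [significance_stars(p) if np.isfinite(p) else ""
                    for p in out["p_raw"]]
    return out


def summarize_cohort_table(cohort: pd.DataFrame, alpha=0.05) -> pd.DataFrame:
    """Group means +/- SD and tests for the per-subject cohort variables.

    Produces the perinatal/MRI summary (birth weight, placenta, brain
    volume, per-region temperatures ...) from any numeric columns present.
    """
    per_subject = cohort.drop_duplicates("subject")
    skip = {"subject", "group", "litter", "region"}
    rows = []
    for col in per_subject.columns:
        if col in skip or not np.issubdtype(per_subject[col].dtype, np.number):
            continue
        if "region" in cohort.columns and \
                cohort.groupby("subject")[col].nunique().max() > 1:
            continue   # region-varying column: summarized per region below
        vals = per_subject[col].values.astype(float)
        try:
            cmp = compare_groups(vals, per_subject["group"].values, alpha=alpha)
        except DomainError:
            continue
        rows.append(dict(
            variable=col,
            control=f"{cmp.mean_control:.1f}±{cmp.sd_control:.1f}",
            iugr=f"{cmp.mean_iugr:.1f}±{cmp.sd_iugr:.1f}",
            percent_change=round(cmp.percent_change, 1),
            test=cmp.test_used, p_value=cmp.p_value,
            stars=significance_stars(cmp.p_value)))
    # per-region variables (temperature etc.) when region rows are present
    if "region" in cohort.columns and "temp_c" in cohort.columns:
        for region in cohort["region"].dropna().unique():
            sub = cohort[cohort["region"] == region]
            vals = sub["temp_c"].values.astype(float)
            try:
                cmp = compare_groups(vals, sub["group"].values, alpha=alpha)
            except DomainError:
                continue
            rows.append(dict(
                variable=f"temp_{region}",
                control=f"{cmp.mean_control:.1f}±{cmp.sd_control:.1f}",
                iugr=f"{cmp.mean_iugr:.1f}±{cmp.sd_iugr:.1f}",
                percent_change=round(cmp.percent_change, 1),
                test=cmp.test_used, p_value=cmp.p_value,
                stars=significance_stars(cmp.p_value)))
    return pd.DataFrame(rows)
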