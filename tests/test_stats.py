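import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neomrs.errors import ConfigError, DomainError
from neomrs.simulate import CohortConfig, EffectTable, generate_cohort
from neomrs.stats import (benjamini_hochberg, compare_groups, glm_adjust,
                          summarize_effect_table)


def _labels(n_ctl, n_iugr):
    return np.array(["control"] * n_ctl + ["iugr"] * n_iugr)


def test_identical_groups():
    vals = np.array([1.0, 2, 3, 1, 2, 3])
    res = compare_groups(vals, _labels(3, 3))
    assert res.percent_change == pytest.approx(0.0)
    assert res.p_value > 0.9


def test_t_statistic_matches_textbook_formula():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    b = np.array([11.0, 12, 13, 14, 15])
    res = compare_groups(np.concatenate([a, b]), _labels(6, 5))
    assert res.test_used == "t"
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
        / (a.size + b.size - 2)
    t_ref = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    assert res.statistic == pytest.approx(t_ref, abs=1e-9)


def test_nonnormal_data_routes_to_mann_whitney():
    rng = np.random.default_rng(0)
    a = np.exp(rng.standard_normal(8) * 3)      # heavily skewed
    b = np.exp(rng.standard_normal(8) * 3) * 50
    res = compare_groups(np.concatenate([a, b]), _labels(8, 8))
    assert res.test_used == "mann_whitney"
    assert 0 <= res.p_value <= 1


def test_percent_change_scale_invariant():
    rng = np.random.default_rng(1)
    vals = np.abs(rng.standard_normal(11)) + 1
    labels = _labels(6, 5)
    r1 = compare_groups(vals, labels)
    r2 = compare_groups(vals * 1e6, labels)
    assert r2.percent_change == pytest.approx(r1.percent_change, rel=1e-12)


def test_branches_agree_on_strong_separation():
    """t and Mann-Whitney both reject on a 5-SD group shift."""
    rng = np.random.default_rng(2)
    a = rng.standard_normal(6)
    b = rng.standard_normal(5) + 5.0
    vals, labels = np.concatenate([a, b]), _labels(6, 5)
    t_res = compare_groups(vals, labels)
    u_stat, u_p = sps.mannwhitneyu(b, a, alternative="two-sided")
    assert t_res.p_value < 0.05 and u_p < 0.05


def test_group_size_guard():
    with pytest.raises(DomainError):
        compare_groups(np.arange(4.0), _labels(2, 2))


def test_published_cortex_aspartate_effect_is_detectable():
    """The -41.6% cortex aspartate change reaches p<0.05 in >=80% of seeds."""
    n_sig = 0
    for seed in range(100):
        co = generate_cohort(CohortConfig(seed=seed, make_phantoms=False,
                                          make_spectra=False))
        tc = co.true_concentrations
        sub = tc[(tc["region"] == "cortex") & (tc["metabolite"] == "aspartate")]
        res = compare_groups(sub["concentration"].values, sub["group"].values)
        n_sig += res.p_value < 0.05
    assert n_sig >= 80


def test_glm_orthogonal_covariate_equals_raw_difference():
    rng = np.random.default_rng(3)
    g = np.array([0.0] * 8 + [1.0] * 8)
    cov = np.tile([1.0, -1.0], 8)            # orthogonal to group
    y = 2.0 * g + rng.standard_normal(16) * 0.1
    res = glm_adjust(y, g, pd.DataFrame({"c": cov}))
    raw = y[g == 1].mean() - y[g == 0].mean()
    assert res.group_effect == pytest.approx(raw, abs=1e-9)


def test_glm_recovers_constructed_effect():
    hits = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        g = np.array([0.0] * 10 + [1.0] * 10)
        temp = rng.normal(31, 1, 20)
        y = 2.0 * g + 0.5 * temp + rng.standard_normal(20) * 0.3
        res = glm_adjust(y, g, pd.DataFrame({"temp": temp}))
        ci = (res.group_effect - 2 * res.group_se,
              res.group_effect + 2 * res.group_se)
        hits += ci[0] <= 2.0 <= ci[1]
    assert hits >= 27                      # ~95% coverage


def test_glm_null_p_values_uniform():
    ps = []
    for seed in range(500):
        rng = np.random.default_rng(seed)
        g = np.array([0.0] * 15 + [1.0] * 15)
        y = rng.standard_normal(30)
        ps.append(glm_adjust(y, g).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_glm_matches_t_test_without_covariates():
    rng = np.random.default_rng(5)
    vals = rng.standard_normal(11)
    labels = _labels(6, 5)
    t_res = compare_groups(vals, labels)
    glm = glm_adjust(vals, labels)
    assert glm.p_value == pytest.approx(t_res.p_value, abs=1e-12)


def test_glm_rank_deficiency_names_columns():
    g = np.array([0.0] * 5 + [1.0] * 5)
    cov = pd.DataFrame({"dup": g})          # collinear with group
    with pytest.raises(ConfigError, match="dup"):
        glm_adjust(np.arange(10.0), g, cov)


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(6)
    p = rng.random(25) ** 2
    np.testing.assert_allclose(benjamini_hochberg(p),
                               multipletests(p, method="fdr_bh")[1])


def _toy_quant(concs):
    rows = []
    for subj, group in [(f"C{i}", "control") for i in range(1, 7)] \
            + [(f"I{i}", "iugr") for i in range(1, 6)]:
        for met, base in concs.items():
            c = base * (1.3 if group == "iugr" and met == "naa" else 1.0)
            c *= 1 + 0.01 * hash((subj, met)) % 7 / 100
            rows.append(dict(subject=subj, region="cortex", metabolite=met,
                             concentration=c, retained=True))
    return pd.DataFrame(rows)


def test_pooled_row_sums_concentrations_first():
    quant = _toy_quant({"naa": 4.0, "naag": 1.0})
    meta = pd.DataFrame({"subject": quant["subject"].unique()})
    meta["group"] = np.where(meta["subject"].str.startswith("C"),
                             "control", "iugr")
    out = summarize_effect_table(quant, meta)
    row = out[(out["metabolite"] == "NAA + NAAG")
              & (out["region"] == "cortex")].iloc[0]
    # pooled change of summed concentrations: 30% NAA rise on a 4:1 pool
    q = quant.pivot_table(index="subject", columns="metabolite",
                          values="concentration")
    pool = q["naa"] + q["naag"]
    ctl = pool[pool.index.str.startswith("C")].mean()
    iug = pool[pool.index.str.startswith("I")].mean()
    assert row["percent_change"] == pytest.approx(100 * (iug / ctl - 1),
                                                  abs=1e-9)


def test_unretained_metabolite_marks_cell_not_evaluable():
    quant = _toy_quant({"aspartate": 2.0})
    quant.loc[(quant["metabolite"] == "aspartate")
              & quant["subject"].isin(["I1", "I2", "I3"]), "retained"] = False
    meta = pd.DataFrame({"subject": quant["subject"].unique()})
    meta["group"] = np.where(meta["subject"].str.startswith("C"),
                             "control", "iugr")
    out = summarize_effect_table(quant, meta)
    row = out[(out["metabolite"] == "Aspartate")
              & (out["region"] == "cortex")].iloc[0]
    assert not row["evaluable"]
    assert np.isnan(row["percent_change"])
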