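"""End-to-end pipeline: simulate (or load) -> quantify -> thermometry ->
volumetry -> classify -> statistics, under one validated config with a
single global seed and deterministic outputs.

Per-stage child seeds derive from the global seed by stable hashing of the
stage name, so each stage is independently reproducible. Re-running with
the same config reproduces every numeric output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as nio
from .classify import (ConcatVector, bootstrap_accuracy, preprocess_vector,
                       project_latent, sffs_select, train_lda)
from .core import REGIONS
from .errors import ConfigError, PipelineStageError
from .quant import FitConfig, LinearCombinationModel, absolute_concentration, \
    compute_fwhm, compute_snr
from .simulate import (CohortConfig, EffectTable, default_basis,
                       generate_cohort)
from .stats import (litter_design, summarize_cohort_table,
                    summarize_effect_table)
from .thermometry import ThermometryConfig, estimate_voxel_temperature, \
    locate_peak
from .volumetry import (CORTEX_FRACTION_LABELS, region_volumes,
                        voxel_composition)

log = logging.getLogger("neomrs")

CONCAT_CHOICES = {"ctx+hip": ("cortex", "hippocampus"),
                  "ctx+str": ("cortex", "striatum")}


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    source: str = "synthetic"          # "synthetic" | "load"
    seed: int = 0
    output_dir: str = "neomrs_out"
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    fit: dict = field(default_factory=dict)         # FitConfig overrides
    classify_reps: int = 1000
    classify_k: tuple = (1, 2, 3)
    input_dir: str = ""                # for source == "load"
    null_effects: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self):
        if self.source not in ("synthetic", "load"):
            raise ConfigError(f"source must be synthetic|load, got {self.source}")
        if self.source == "load" and not self.input_dir:
            raise ConfigError("source 'load' requires input_dir")
        if self.source == "load" and not os.path.isdir(self.input_dir):
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")
        for key in ("cohort", "fit"):
            val = getattr(self, key)
            if not isinstance(val, dict):
                raise ConfigError(f"{key} must be a mapping")
        known_cohort = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(self.cohort) - known_cohort
        if bad:
            raise ConfigError(f"unknown cohort config keys: {sorted(bad)}")
        known_fit = {f.name for f in dataclasses.fields(FitConfig)}
        bad = set(self.fit) - known_fit
        if bad:
            raise ConfigError(f"unknown fit config keys: {sorted(bad)}")
        if any(k not in (1, 2, 3) for k in self.classify_k):
            raise ConfigError("classify_k entries must be 1, 2 or 3")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def secondary_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """Litter indicator columns + neighbor-stillbirth count per
    (subject, region): the secondary confounder model."""
    per_subj = meta.drop_duplicates("subject").set_index("subject")
    lit = litter_design(per_subj["litter"])
    lit.index = per_subj.index
    cov = lit.assign(neighbor_stillbirths=per_subj["neighbor_stillbirths"]
                     .astype(float))
    rows = []
    for subj in per_subj.index:
        for region in REGIONS:
            rows.append((subj, region))
    out = cov.loc[[s for s, _ in rows]].reset_index(drop=True)
    out.index = pd.MultiIndex.from_tuples(rows, names=["subject", "region"])
    return out


def save_cohort(cohort, outdir):
    """Write a cohort bundle (spectra, phantoms, cohort table) to disk."""
    os.makedirs(os.path.join(outdir, "spectra"), exist_ok=True)
    for (subj, region), (spec, ref) in cohort.spectra.items():
        base = os.path.join(outdir, "spectra", f"{subj}_{region}")
        nio.write_spectrum(spec, base + ".txt")
        nio.write_spectrum(ref, base + "_ref.txt")
    for subj, phantom in cohort.phantoms.items():
        nio.write_label_map(
            phantom, os.path.join(outdir, f"{subj}_atlas.nii.gz"),
            os.path.join(outdir, f"{subj}_labels.tsv"))
    nio.write_cohort_table(cohort.table(),
                           os.path.join(outdir, "cohort.csv"))


def _quant_stage(cohort, fit_cfg, basis, outdir):
    qdir = os.path.join(outdir, "quant")
    os.makedirs(qdir, exist_ok=True)
    long_rows = []
    qc_rows = []
    for (subj, region), (spec, ref) in sorted(cohort.spectra.items()):
        log.info("stage=quantify subject=%s region=%s", subj, region)
        try:
            model = LinearCombinationModel(spec, basis, fit_cfg)
            res = model.fit()
            absolute_concentration(res, ref, fit_cfg, basis.protons)
            res.fwhm_hz = compute_fwhm(ref)
            res.snr = compute_snr(spec)
        except Exception as e:
            raise PipelineStageError(
                f"stage 'quantify' failed for subject={subj} "
                f"region={region}: {e}") from e
        tab = res.table.reset_index()
        tab.insert(0, "subject", subj)
        tab.insert(1, "region", region)
        tab.to_csv(os.path.join(qdir, f"{subj}_{region}.csv"), index=False,
                   float_format="%.6g")
        qc_rows.append(dict(subject=subj, region=region, fwhm_hz=res.fwhm_hz,
                            snr=res.snr, shift_ppm=res.shift_ppm,
                            phase_rad=res.phase_rad,
                            damping_hz=res.damping_hz,
                            converged=res.converged))
        keep = tab[~tab["is_macromolecule"] & ~tab["is_nuisance_line"]]
        for _, r in keep.iterrows():
            long_rows.append(dict(subject=subj, region=region,
                                  metabolite=r["component"],
                                  concentration=r["concentration"],
                                  crlb_pct=r["crlb_pct"],
                                  retained=bool(r["retained"])))
    return pd.DataFrame(long_rows), pd.DataFrame(qc_rows)


def _thermometry_stage(cohort, outdir):
    cfg = ThermometryConfig()
    rows = []
    for (subj, region), (spec, _) in sorted(cohort.spectra.items()):
        log.info("stage=thermometry subject=%s region=%s", subj, region)
        try:
            water = locate_peak(spec, cfg.water_window_ppm)
            chol = locate_peak(spec, cfg.choline_window_ppm)
            temp = estimate_voxel_temperature(spec, cfg)
        except Exception as e:
            raise PipelineStageError(
                f"stage 'thermometry' failed for subject={subj} "
                f"region={region}: {e}") from e
        rows.append(dict(subject=subj, region=region,
                         dist_ppm=round(water - chol, 5),
                         temp_c=round(temp, 3)))
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "temperatures.csv"), index=False)
    return df


def _volumetry_stage(cohort, outdir):
    rows = []
    for subj in sorted(cohort.phantoms):
        phantom = cohort.phantoms[subj]
        vols = region_volumes(phantom)
        for region in REGIONS:
            geo = cohort.voxel_geometries.get((subj, region))
            if geo is None:
                continue
            log.info("stage=volumetry subject=%s region=%s", subj, region)
            comp = voxel_composition(geo, phantom)
            if region == "cortex":
                frac = sum(comp.fraction(n) for n in CORTEX_FRACTION_LABELS)
                vol = vols.get("cortex", np.nan)
            else:
                frac = comp.fraction(region)
                vol = vols.get(region, np.nan)
            rows.append(dict(subject=subj, region=region,
                             region_volume_mm3=round(float(vol), 2),
                             brain_volume_mm3=round(float(vols.get("brain",
                                                                   np.nan)), 2),
                             tissue_fraction_pct=round(frac, 2),
                             dominant_label=comp.dominant_label,
                             voxel_volume_ul=round(comp.total_volume_ul, 2)))
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "volumetry.csv"), index=False)
    return df


def _classification_stage(cohort, cfg: PipelineConfig, outdir):
    cdir = os.path.join(outdir, "classification")
    os.makedirs(cdir, exist_ok=True)
    vectors = {}
    for (subj, region), (spec, _) in cohort.spectra.items():
        vectors[(subj, region)] = preprocess_vector(spec)
    subjects = sorted(cohort.meta["subject"])
    groups = cohort.meta.set_index("subject")["group"]
    y = np.array([groups[s] for s in subjects])
    rows = []
    for concat_name, (r1, r2) in CONCAT_CHOICES.items():
        concats = [ConcatVector.from_vectors(vectors[(s, r1)],
                                             vectors[(s, r2)])
                   for s in subjects]
        X = np.vstack([c.values for c in concats])
        fmap = concats[0].feature_map
        for k in cfg.classify_k:
            log.info("stage=classify concat=%s k=%d", concat_name, k)
            feats = sffs_select(X, y, k)
            model = train_lda(X, y, feats,
                              feature_names=[fmap[j] for j in feats])
            train_acc = model.training_accuracy(X, y)
            boot_acc, n_eff = bootstrap_accuracy(
                X, y, k, n_reps=cfg.classify_reps,
                seed=child_seed(cfg.seed, f"bootstrap:{concat_name}:{k}"))
            coords = project_latent(model, X, y)
            pd.DataFrame({"subject": subjects, "group": y,
                          "axis1": coords[:, 0], "axis2": coords[:, 1]}) \
                .to_csv(os.path.join(cdir, f"latent_{concat_name.replace('+','_')}_k{k}.csv"),
                        index=False, float_format="%.6g")
            rows.append(dict(
                concatenation=concat_name, k=k,
                features="; ".join(f"{r}@{p:.3f}ppm"
                                   for r, p in model.feature_names),
                training_accuracy_pct=round(100 * train_acc, 1),
                bootstrap_accuracy_pct=round(boot_acc, 1),
                bootstrap_reps=n_eff))
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(cdir, "report.csv"), index=False)
    return df


def run_pipeline(config: PipelineConfig):
    """Run all stages; returns a dict of the main result tables."""
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if config.source == "synthetic":
            cc = CohortConfig(**{**config.cohort,
                                 "seed": child_seed(config.seed, "cohort")})
            effects = EffectTable.null() if config.null_effects \
                else EffectTable.default()
            log.info("stage=simulate seed=%d", cc.seed)
            cohort = generate_cohort(cc, effects)
            save_cohort(cohort, outdir)
        else:
            raise NotImplementedError(
                "load mode: use the per-stage subcommands on a saved bundle")
        basis = default_basis()
        fit_cfg = FitConfig(**config.fit)
        quant_long, qc = _quant_stage(cohort, fit_cfg, basis, outdir)
        qc.to_csv(os.path.join(outdir, "quant_qc.csv"), index=False,
                  float_format="%.6g")
        temps = _thermometry_stage(cohort, outdir)
        volum = _volumetry_stage(cohort, outdir)
        classif = _classification_stage(cohort, config, outdir)

        # statistics: cohort summary + effect table with GLM adjustment
        cohort_table = cohort.table().merge(
            temps, on=["subject", "region"], how="left")
        tab1 = summarize_cohort_table(
            cohort_table.rename(columns={"temp_c": "temp_c"}))
        tab1.to_csv(os.path.join(outdir, "table1_summary.csv"), index=False,
                    float_format="%.6g")
        cov = temps.merge(volum[["subject", "region", "tissue_fraction_pct"]],
                          on=["subject", "region"], how="left") \
            if len(volum) else temps.assign(tissue_fraction_pct=np.nan)
        cov = cov.set_index(["subject", "region"])[
            ["temp_c"] + (["tissue_fraction_pct"]
                          if cov["tissue_fraction_pct"].notna().all()
                          else [])]
        tab2 = summarize_effect_table(quant_long, cohort.meta, covariates=cov)
        # secondary adjustment: litter indicators + neighbor stillbirths
        cov2 = secondary_covariates(cohort.meta)
        tab2_sec = summarize_effect_table(quant_long, cohort.meta,
                                          covariates=cov2)
        tab2["p_adjusted_litter"] = tab2_sec["p_adjusted"]
        tab2.to_csv(os.path.join(outdir, "table2_summary.csv"), index=False,
                    float_format="%.6g")

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                         "python": sys.version.split()[0]},
            "n_subjects": int(len(cohort.meta)),
            "n_spectra": int(len(cohort.spectra)),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return {"quant": quant_long, "qc": qc, "temperatures": temps,
                "volumetry": volum, "classification": classif,
                "table1": tab1, "table2": tab2, "manifest": manifest}
    finally:
        log.removeHandler(handler)
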