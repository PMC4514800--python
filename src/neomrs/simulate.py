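"""Synthetic study generator.

Emulates the in-vivo study conditions end to end so every downstream stage is
testable without any data download: short-TE (12 ms) PRESS-like spectra at
7 T built from the shipped metabolite line lists plus 11 macromolecule
components, a partially suppressed water line whose ppm position encodes the
voxel temperature, water-reference scans, labeled brain phantoms, and cohort
metadata with the study's group structure (6 controls, 5 growth-restricted
newborns from 3 litters x 3 brain regions) and published effect sizes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import (BasisSet, MacromoleculeModel, build_basis_set,
                    load_metabolite_models)
from .core import AcquisitionGrid, LabelMap, REGIONS, Spectrum, lorentzian_line
from .errors import ConfigError, DomainError
from .thermometry import dist_from_temperature

CHOLINE_PPM = 3.21

#: Default T2 of tissue water used to attenuate the simulated water signal (ms).
WATER_T2_MS = 158.0

#: Tissue water content (g water / g tissue) x molality of pure water
#: (55510 umol/g) -> umol water per g tissue.
TISSUE_WATER_MOLALITY = 0.80 * 55510.0

# ---------------------------------------------------------------------------
# Scan arithmetic
# ---------------------------------------------------------------------------

def predict_scan_duration(tr_ms, n_averages, n_dummy) -> float:
    """Acquisition duration in seconds: TR x (averages + dummy scans)."""
    if tr_ms <= 0:
        raise DomainError("tr_ms must be positive")
    if n_averages <= 0 or n_dummy < 0:
        raise DomainError("n_averages must be positive, n_dummy non-negative")
    return tr_ms * (n_averages + n_dummy) / 1000.0


# ---------------------------------------------------------------------------
# Baseline concentrations and effect sizes
# ---------------------------------------------------------------------------

#: Default baseline concentrations (umol/g) per region. The total creatine
#: pools (creatine + phosphocreatine) are anchored to the ex-vivo reference
#: values (cortex 3.0, striatum 3.9 umol/g); all other values are plausible
#: neonatal-brain defaults, configurable, not ground truth.
BASELINE_CONCENTRATIONS = {
    #                      cortex  hippocampus  striatum
    "ascorbate":            (1.3, 1.2, 1.2),
    "lactate":              (3.0, 3.0, 2.8),
    "myo_inositol":         (4.0, 4.2, 3.8),
    "phosphorylethanolamine": (2.5, 2.4, 2.6),
    "creatine":             (1.4, 1.6, 1.8),
    "phosphocreatine":      (1.6, 1.8, 2.1),
    "glutamine":            (3.0, 3.2, 3.0),
    "glutamate":            (6.0, 5.5, 5.8),
    "glutathione":          (1.5, 1.5, 1.4),
    "glycine":              (2.5, 2.3, 2.8),
    "taurine":              (6.0, 5.5, 5.0),
    "gpc":                  (1.0, 1.0, 1.1),
    "pcho":                 (0.8, 0.8, 0.9),
    "phenylalanine":        (0.3, 0.3, 0.3),
    "gaba":                 (1.5, 1.6, 1.8),
    "aspartate":            (2.5, 2.3, 2.4),
    "naa":                  (3.5, 3.3, 3.6),
    "naag":                 (0.8, 0.7, 0.9),
    "acetate":              (0.3, 0.3, 0.3),
    "alanine":              (0.6, 0.6, 0.6),
    "beta_hydroxybutyrate": (0.4, 0.4, 0.4),
    "valine":               (0.2, 0.2, 0.2),
    "glucose":              (1.5, 1.5, 1.5),
    "scyllo_inositol":      (0.3, 0.3, 0.3),
    "threonine":            (0.4, 0.4, 0.4),
}


def baseline_concentrations(region: str) -> dict:
    i = REGIONS.index(region)
    return {m: v[i] for m, v in BASELINE_CONCENTRATIONS.items()}


#: Published relative changes (fraction) of the growth-restricted group vs
#: control, per (metabolite row, region): single-metabolite rows.
TABLE2_EFFECTS = {
    ("aspartate", "cortex"): -0.416,
    ("aspartate", "hippocampus"): -0.244,
    ("aspartate", "striatum"): -0.227,
    ("naa", "cortex"): -0.242,
    ("naa", "hippocampus"): -0.164,
    ("naa", "striatum"): -0.058,
    ("glutamate", "cortex"): -0.067,
    ("glutamate", "hippocampus"): -0.137,
    ("glutamate", "striatum"): +0.006,
    ("glycine", "cortex"): +0.086,
    ("glycine", "hippocampus"): -0.027,
    ("glycine", "striatum"): +0.342,
}

#: Pooled-row changes: (pool members, region) -> fraction.
TABLE2_POOLED_EFFECTS = {
    (("naa", "naag"), "cortex"): -0.142,
    (("naa", "naag"), "hippocampus"): -0.105,
    (("naa", "naag"), "striatum"): +0.046,
    (("myo_inositol", "glycine"), "cortex"): +0.047,
    (("myo_inositol", "glycine"), "hippocampus"): +0.015,
    (("myo_inositol", "glycine"), "striatum"): +0.142,
}


@dataclass
class EffectTable:
    """Per-(metabolite, region) relative change of the IUGR group vs control.

    Defaults reproduce the published table: single-metabolite rows directly,
    while the NAAG and myo-inositol effects are solved from the pooled rows
    (NAA+NAAG, myo-inositol+glycine) under the default baseline
    concentrations, so the pooled group changes match the printed values.
    """

    effects: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "EffectTable":
        eff = dict(TABLE2_EFFECTS)
        for (pool, region), pooled in TABLE2_POOLED_EFFECTS.items():
            known, unknown = pool[0], pool[1]
            if (known, region) not in eff:
                known, unknown = unknown, known
            base = baseline_concentrations(region)
            b_known, b_unknown = base[known], base[unknown]
            e_known = eff[(known, region)]
            # (b_k (1+e_k) + b_u (1+e_u)) / (b_k + b_u) = 1 + pooled
            e_unknown = ((1 + pooled) * (b_known + b_unknown)
                         - b_known * (1 + e_known) - b_unknown) / b_unknown
            eff[(unknown, region)] = e_unknown
        return cls(effects=eff)

    @classmethod
    def null(cls) -> "EffectTable":
        return cls(effects={})

    def effect(self, metabolite, region) -> float:
        return self.effects.get((metabolite, region), 0.0)

    def apply(self, concentrations: dict, region: str) -> dict:
        return {m: c * (1.0 + self.effect(m, region))
                for m, c in concentrations.items()}


# ---------------------------------------------------------------------------
# Single-spectrum simulation
# ---------------------------------------------------------------------------

def _noiseless_signal(basis: BasisSet, concentrations: dict, temp_c,
                      target_fwhm_hz, water_suppression_factor,
                      mm_scale, water_area, shift_ppm=0.0):
    """Complex noiseless spectrum: metabolites + macromolecules + residual water.

    The water line is placed at ``dist_from_temperature(temp_c)`` ppm above
    the simulated spectrum's own total-choline magnitude peak (falling back
    to the nominal 3.21 ppm when no choline signal exists): the calibration
    is defined on the *measured* water-choline peak distance, so anchoring
    to the nominal position instead would bias the round trip by the small
    pull that neighbouring resonances exert on the choline maximum.
    """
    from .thermometry import parabolic_peak
    intrinsic = float(basis.fwhm_hz[basis.metabolite_names[0]][0]) \
        if basis.metabolite_names else 2.0
    extra = max(target_fwhm_hz - intrinsic, 0.0)
    sig = basis.mixture(concentrations, shift_ppm=shift_ppm,
                        extra_fwhm_hz=extra)
    if mm_scale:
        # field-inhomogeneity broadening applies to macromolecules too
        mm_conc = {name: mm_scale * amp for name, amp in
                   zip(basis.macromolecule_names, basis.macromolecule_model.amplitude)}
        sig = sig + basis.mixture(mm_conc, shift_ppm=shift_ppm,
                                  extra_fwhm_hz=extra)
    axis = basis.ppm_axis
    dist = dist_from_temperature(temp_c)
    chol_mask = (axis >= 3.10) & (axis <= 3.32)
    has_choline = float(np.max(np.abs(sig[chol_mask]), initial=0.0)) > 0
    metab_mask = (axis >= 0.5) & (axis <= 4.25)
    tallest = float(np.max(np.abs(sig[metab_mask]))) if np.any(np.abs(sig)) else 0.0

    water_ppm = CHOLINE_PPM + dist
    if water_suppression_factor > 0 and tallest > 0:
        height = water_suppression_factor * tallest
        area = height * np.pi * target_fwhm_hz / 2.0
        # two fixed-point iterations: the water dispersion tail itself pulls
        # the measured choline maximum slightly, so re-anchor once
        out = sig
        for _ in range(2 if has_choline else 1):
            anchor = parabolic_peak(axis, np.abs(out), (3.10, 3.32)) \
                if has_choline else CHOLINE_PPM
            water_ppm = anchor + dist
            out = sig + lorentzian_line(axis, water_ppm, area, target_fwhm_hz,
                                        basis.grid.f0_mhz)
        sig = out
    elif has_choline:
        water_ppm = parabolic_peak(axis, np.abs(sig), (3.10, 3.32)) + dist
    water_line = lorentzian_line(axis, water_ppm, water_area, target_fwhm_hz,
                                 basis.grid.f0_mhz)
    return sig, water_line, water_ppm


def _choline_height(intensity, axis):
    """QC choline peak height; shared definition with the SNR metric."""
    from .quant import choline_peak_height
    return choline_peak_height(axis, intensity)


def simulate_spectrum(concentrations, temp_c, noise_sd=None, damping_hz=10.1,
                      phase0=0.0, seed=0, basis: BasisSet = None,
                      shift_ppm=0.0, water_suppression_factor=5.0,
                      mm_scale=1.0, target_snr=47.7,
                      water_t2_ms=WATER_T2_MS,
                      tissue_water_molality=TISSUE_WATER_MOLALITY,
                      te_ms=12.0, region_label="", subject_id="",
                      n_averages=256, n_dummy=4):
    """Simulate one water-suppressed spectrum and its water reference.

    The residual water line sits at ``3.21 + dist_from_temperature(temp_c)``
    ppm, attenuated to ``water_suppression_factor`` times the tallest
    metabolite peak (partial suppression). The water reference is the
    unsuppressed line whose area encodes the tissue water pool after T2
    attenuation over the echo time, which is what the absolute-quantification
    water scaling later corrects for. ``noise_sd=None`` calibrates the noise
    to ``target_snr`` (total-choline SNR definition). Same seed, same output.
    """
    if basis is None:
        basis = default_basis()
    unknown = set(concentrations) - set(basis.metabolite_names)
    if unknown:
        raise ConfigError(f"unknown metabolite keys: {sorted(unknown)}")
    water_area = tissue_water_molality * 2.0 * np.exp(-te_ms / water_t2_ms)
    sig, water_line, _ = _noiseless_signal(
        basis, concentrations, temp_c, damping_hz, water_suppression_factor,
        mm_scale, water_area, shift_ppm=shift_ppm)
    axis = basis.ppm_axis
    if noise_sd is None:
        h = _choline_height(sig, axis)
        noise_sd = h / target_snr if (h > 0 and target_snr > 0) else 0.0
    rng = np.random.default_rng(seed)
    phase = np.exp(1j * phase0)
    n = axis.size

    def finalize(y, is_ref, navg):
        noise = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        return Spectrum(
            ppm_axis=axis.copy(), intensity=y * phase + noise_sd * noise,
            sw_hz=basis.grid.sw_hz, f0_mhz=basis.grid.f0_mhz,
            te_ms=te_ms, n_averages=navg, n_dummy=n_dummy,
            region_label=region_label, is_water_reference=is_ref,
            subject_id=subject_id)

    spec = finalize(sig, False, n_averages)
    ref = finalize(water_line, True, 8)
    return spec, ref


_DEFAULT_BASIS = {}


def default_basis(grid: AcquisitionGrid = None) -> BasisSet:
    """Shared default basis set (cached; treat as read-only)."""
    key = (grid.f0_mhz, grid.sw_hz, grid.n_points, grid.center_ppm) \
        if grid is not None else None
    if key not in _DEFAULT_BASIS:
        _DEFAULT_BASIS[key] = build_basis_set(
            load_metabolite_models(), MacromoleculeModel(),
            grid or AcquisitionGrid())
    return _DEFAULT_BASIS[key]


# ---------------------------------------------------------------------------
# Label phantom
# ---------------------------------------------------------------------------

#: Control-group region-volume targets (mm^3) used for the brain phantom;
#: cortex is split into its four sub-regions. Totals follow the published
#: control volumes; the split and the non-tabulated tissues are documented
#: package defaults.
PHANTOM_TARGETS_CONTROL = {
    "thalamus": 120.0,
    "striatum": 179.6,
    "hippocampus": 173.3,
    "white_matter": 150.0,
    "other": 191.4,
    "cingulate_cortex": 300.0,
    "frontal_cortex": 56.0,
    "medial_frontal_cortex": 40.0,
    "parietal_cortex": 80.2,
    "csf": 45.0,
}

CORTEX_LABELS = ("cingulate_cortex", "frontal_cortex",
                 "medial_frontal_cortex", "parietal_cortex")

#: Ellipsoid semi-axis ratios of the phantom (x, y, z), product 1.
_AXIS_RATIOS = np.array([1.25, 1.0, 0.8])


def generate_label_phantom(region_volume_targets: dict,
                           voxel_size=0.2) -> LabelMap:
    """Nested-ellipsoid brain phantom hitting per-label volume targets.

    Labels occupy successive shells of a normalized ellipsoidal radius
    field, innermost first in dict order; shell boundaries are placed by
    voxel rank so each label's rasterized volume matches its target to
    within one voxel (well inside the 2% contract). Zero-volume targets are
    skipped; a positive target below 8 voxels raises a resolution error.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    vox_vol = float(np.prod(voxel_size))
    targets = {k: float(v) for k, v in region_volume_targets.items() if v > 0}
    if not targets:
        raise ConfigError("at least one positive volume target required")
    for name, v in targets.items():
        if v / vox_vol < 8:
            raise DomainError(
                f"region '{name}' ({v} mm^3) spans fewer than 8 voxels at "
                f"voxel size {voxel_size.tolist()} mm")
    v_tot = sum(targets.values())
    r_sphere = (3.0 * v_tot / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = _AXIS_RATIOS / np.prod(_AXIS_RATIOS) ** (1.0 / 3.0)
    semi = ratios * r_sphere
    # grid with a 2-voxel margin per side
    half_extent = semi + 2 * voxel_size
    n = np.ceil(2 * half_extent / voxel_size).astype(int)
    coords = [ (np.arange(n[i]) + 0.5) * voxel_size[i] - n[i] * voxel_size[i] / 2
               for i in range(3) ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt((X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2)
    order = np.argsort(rho, axis=None, kind="stable")
    volume = np.zeros(rho.shape, dtype=np.int16)
    flat = volume.reshape(-1)
    names = {0: "background"}
    cum = 0.0
    start = 0
    for lid, (name, v) in enumerate(targets.items(), start=1):
        cum += v
        stop = int(round(cum / vox_vol))
        if stop > order.size:
            raise DomainError("phantom grid too small for requested volumes")
        flat[order[start:stop]] = lid
        names[lid] = name
        start = stop
    return LabelMap(volume=volume, voxel_size_mm=voxel_size,
                    origin_mm=np.zeros(3), label_names=names)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Group-level parameters: mean, SD per group, following the published
#: cohort table (weights g, volumes mm^3, temperatures degC).
GROUP_PARAMS = {
    "birth_weight": {"control": (56.0, 4.9), "iugr": (31.4, 3.4)},
    "placenta_weight": {"control": (7.3, 0.8), "iugr": (4.1, 0.6)},
    "brain_volume": {"control": (1335.5, 87.8), "iugr": (1100.6, 28.7)},
}

TEMPERATURE_PARAMS = {
    ("control", "cortex"): (31.5, 1.1),
    ("control", "hippocampus"): (31.9, 1.1),
    ("control", "striatum"): (32.0, 0.7),
    ("iugr", "cortex"): (29.7, 1.1),
    ("iugr", "hippocampus"): (31.0, 1.6),
    ("iugr", "striatum"): (30.9, 2.2),
}

BODY_TEMPERATURE_PARAMS = {"control": (34.5, 1.1), "iugr": (34.8, 0.7)}

#: Published PRESS voxel box dimensions per region (mm).
VOXEL_DIMS_MM = {
    "cortex": (1.3, 2.0, 4.0),
    "hippocampus": (1.6, 4.3, 1.5),
    "striatum": (2.1, 1.4, 3.6),
}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort (defaults = the study)."""

    n_control: int = 6
    n_iugr: int = 5
    n_litters: int = 3
    concentration_cv: float = 0.10     # between-subject log-normal CV
    target_snr: float = 47.7
    snr_between_subject_sd: float = 5.0
    target_fwhm_hz: float = 10.1
    fwhm_between_subject_sd: float = 0.8
    water_suppression_factor: float = 5.0
    phase0_range_deg: float = 15.0
    shift_sd_ppm: float = 0.005
    stillbirth_rate: float = 0.8       # Poisson mean, group-independent
    water_t2_ms: float = WATER_T2_MS
    tissue_water_molality: float = TISSUE_WATER_MOLALITY
    phantom_voxel_mm: float = 0.25
    make_phantoms: bool = True
    make_spectra: bool = True        # off: concentrations/metadata only
    seed: int = 0

    def __post_init__(self):
        if self.n_control <= 0 or self.n_iugr <= 0 or self.n_litters <= 0:
            raise ConfigError("cohort counts must be positive")
        if self.concentration_cv < 0:
            raise ConfigError("concentration_cv must be >= 0")


@dataclass
class Cohort:
    """A full synthetic study: metadata, truth, spectra and phantoms."""

    meta: pd.DataFrame                  # one row per subject
    observations: pd.DataFrame          # one row per subject x region
    spectra: dict                       # (subject, region) -> (Spectrum, ref)
    phantoms: dict                      # subject -> LabelMap
    voxel_geometries: dict              # (subject, region) -> VoxelGeometry
    true_concentrations: pd.DataFrame   # subject x region x metabolite
    config: CohortConfig
    effects: EffectTable

    def table(self) -> pd.DataFrame:
        """Cohort table (subject x region rows) for CSV export."""
        return self.observations.merge(self.meta, on=["subject", "group",
                                                      "litter"])


def _lognormal_factor(rng, cv, size=None):
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def generate_cohort(config: CohortConfig = None,
                    effect_table: EffectTable = None,
                    seed=None, basis: BasisSet = None) -> Cohort:
    """Generate the full synthetic study.

    Control concentrations are drawn around the region baselines; IUGR
    concentrations get the effect-table multipliers first. Temperatures,
    weights and brain volumes follow the group parameters; litters are
    assigned in the study's 2+2+2 / 2+2+1 pattern; neighbor-stillbirth
    counts are Poisson and group-independent. Fully deterministic per seed.
    """
    config = config or CohortConfig()
    effect_table = effect_table if effect_table is not None else EffectTable.default()
    if seed is None:
        seed = config.seed
    if basis is None:
        basis = default_basis()
    rng = np.random.default_rng(seed)

    subjects = [f"C{i+1}" for i in range(config.n_control)] + \
               [f"I{i+1}" for i in range(config.n_iugr)]
    groups = ["control"] * config.n_control + ["iugr"] * config.n_iugr
    litters = [f"L{(i % config.n_litters) + 1}"
               for i in range(config.n_control)] + \
              [f"L{(i % config.n_litters) + 1}" for i in range(config.n_iugr)]

    meta_rows, obs_rows, conc_rows = [], [], []
    spectra, phantoms, voxgeo = {}, {}, {}
    control_brain_mean = GROUP_PARAMS["brain_volume"]["control"][0]

    for subj, grp, lit in zip(subjects, groups, litters):
        bw = rng.normal(*GROUP_PARAMS["birth_weight"][grp])
        pw = rng.normal(*GROUP_PARAMS["placenta_weight"][grp])
        bv = rng.normal(*GROUP_PARAMS["brain_volume"][grp])
        body_t = rng.normal(*BODY_TEMPERATURE_PARAMS[grp])
        stillb = int(rng.poisson(config.stillbirth_rate))
        meta_rows.append(dict(subject=subj, group=grp, litter=lit,
                              birth_weight_g=round(bw, 2),
                              placenta_weight_g=round(pw, 2),
                              brain_volume_mm3=round(bv, 1),
                              body_temp_c=round(body_t, 2),
                              neighbor_stillbirths=stillb))
        if config.make_phantoms:
            scale = max(bv, 1.0) / control_brain_mean
            targets = {k: v * scale for k, v in PHANTOM_TARGETS_CONTROL.items()}
            phantom = generate_label_phantom(targets, config.phantom_voxel_mm)
            phantoms[subj] = phantom
            for region in REGIONS:
                voxgeo[(subj, region)] = _place_voxel(phantom, region)
        for region in REGIONS:
            base = baseline_concentrations(region)
            if grp == "iugr":
                base = effect_table.apply(base, region)
            factors = _lognormal_factor(rng, config.concentration_cv,
                                        size=len(base))
            conc = {m: max(c * f, 0.0)
                    for (m, c), f in zip(base.items(), factors)}
            temp = rng.normal(*TEMPERATURE_PARAMS[(grp, region)])
            snr = max(rng.normal(config.target_snr,
                                 config.snr_between_subject_sd), 10.0)
            fwhm = max(rng.normal(config.target_fwhm_hz,
                                  config.fwhm_between_subject_sd), 4.0)
            phase0 = np.deg2rad(rng.uniform(-config.phase0_range_deg,
                                            config.phase0_range_deg))
            shift = rng.normal(0.0, config.shift_sd_ppm)
            child_seed = int(rng.integers(0, 2**31 - 1))
            if config.make_spectra:
                spec, ref = simulate_spectrum(
                    conc, temp, noise_sd=None, damping_hz=fwhm, phase0=phase0,
                    seed=child_seed, basis=basis, shift_ppm=shift,
                    water_suppression_factor=config.water_suppression_factor,
                    target_snr=snr, water_t2_ms=config.water_t2_ms,
                    tissue_water_molality=config.tissue_water_molality,
                    region_label=region, subject_id=subj)
                spectra[(subj, region)] = (spec, ref)
            obs_rows.append(dict(subject=subj, group=grp, litter=lit,
                                 region=region, temp_true_c=round(temp, 3),
                                 snr_target=round(snr, 2),
                                 fwhm_target_hz=round(fwhm, 3),
                                 phase0_rad=round(phase0, 4),
                                 shift_ppm=round(shift, 5)))
            for m, c in conc.items():
                conc_rows.append(dict(subject=subj, group=grp, region=region,
                                      metabolite=m, concentration=c))

    return Cohort(meta=pd.DataFrame(meta_rows),
                  observations=pd.DataFrame(obs_rows),
                  spectra=spectra, phantoms=phantoms,
                  voxel_geometries=voxgeo,
                  true_concentrations=pd.DataFrame(conc_rows),
                  config=copy.deepcopy(config), effects=effect_table)


def _place_voxel(phantom: LabelMap, region: str):
    """Axis-aligned PRESS voxel centred on a representative point of a region.

    The phantom's labels are concentric shells, so the voxel is centred at
    the shell's mean radius along +x, which yields realistic (50-85%)
    tissue fractions rather than an artificial 100%.
    """
    from .core import VoxelGeometry  # local import avoids cycle at module load
    name_to_id = {v: k for k, v in phantom.label_names.items()}
    lid = name_to_id.get(region if region != "cortex" else "cingulate_cortex")
    shape = np.array(phantom.volume.shape)
    jc, kc = shape[1] // 2, shape[2] // 2
    # walk the +x ray through the centre: the shell's radial mid-point there
    ray = phantom.volume[:, jc, kc]
    xs = np.where(ray == lid)[0]
    xs = xs[xs >= shape[0] // 2]
    if xs.size == 0:
        xs = np.where(phantom.volume == lid)[0]  # fallback: any voxel
        if xs.size == 0:
            raise ConfigError(f"label for region '{region}' absent in phantom")
    mean_vox = np.array([float(xs.mean()), float(jc), float(kc)])
    center_mm = phantom.origin_mm + (mean_vox + 0.5) * phantom.voxel_size_mm
    return VoxelGeometry(center_mm=center_mm,
                         dims_mm=np.array(VOXEL_DIMS_MM[region]))
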