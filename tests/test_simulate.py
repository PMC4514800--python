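import numpy as np
import pytest
from scipy import stats as sps

from neomrs.core import REGIONS
from neomrs.errors import ConfigError, DomainError
from neomrs.simulate import (CohortConfig, EffectTable,
                             PHANTOM_TARGETS_CONTROL,
                             baseline_concentrations, dist_from_temperature,
                             generate_cohort, generate_label_phantom,
                             predict_scan_duration, simulate_spectrum)
from neomrs.thermometry import parabolic_peak
from neomrs.volumetry import region_volumes


@pytest.mark.parametrize("args,expected", [
    ((2500, 256, 4), 650.0),      # the study's acquisition: 10 min 50 s
    ((2500, 8, 0), 20.0),
    ((1000, 1, 0), 1.0),
])
def test_scan_duration(args, expected):
    assert predict_scan_duration(*args) == pytest.approx(expected)


def test_scan_duration_rejects_nonpositive_tr():
    with pytest.raises(DomainError):
        predict_scan_duration(0, 10, 0)


def test_dist_temperature_inverse_identity():
    assert dist_from_temperature(255.94) == pytest.approx(-1.21, abs=1e-12)
    assert dist_from_temperature(31.47) == pytest.approx(1.5163, abs=1e-3)
    from neomrs.thermometry import temperature_from_dist
    assert temperature_from_dist(
        dist_from_temperature(34.0)) == pytest.approx(34.0, abs=1e-10)


def test_same_seed_bit_identical(cortex_conc):
    a = simulate_spectrum(cortex_conc, 31.5, seed=42)
    b = simulate_spectrum(cortex_conc, 31.5, seed=42)
    np.testing.assert_array_equal(a[0].intensity, b[0].intensity)
    np.testing.assert_array_equal(a[1].intensity, b[1].intensity)


def test_water_peak_encodes_temperature(cortex_conc):
    """Residual water maximum sits at 3.21 + Dist(T) within one grid step."""
    spec, _ = simulate_spectrum(cortex_conc, 31.5, noise_sd=0.0)
    found = parabolic_peak(spec.ppm_axis, np.abs(spec.intensity), (4.2, 5.4))
    expected = 3.21 + dist_from_temperature(31.5)
    assert abs(found - expected) <= spec.ppm_step


def test_zero_signal_is_flat(basis):
    spec, _ = simulate_spectrum({}, 31.5, noise_sd=0.0, mm_scale=0.0,
                                water_suppression_factor=0.0)
    mask = spec.window_mask((0.5, 4.25))
    assert np.abs(spec.intensity[mask]).max() == 0.0


def test_unknown_metabolite_key_rejected():
    with pytest.raises(ConfigError):
        simulate_spectrum({"unobtainium": 1.0}, 31.5)


def test_cohort_structure(small_cohort):
    co = small_cohort
    assert len(co.meta) == 11
    assert (co.meta["group"] == "control").sum() == 6
    assert (co.meta["group"] == "iugr").sum() == 5
    assert len(co.spectra) == 33                    # 11 subjects x 3 regions
    assert co.meta["litter"].nunique() == 3
    # litters balanced: no litter has more than 4 subjects
    assert co.meta["litter"].value_counts().max() <= 4
    assert (co.true_concentrations["concentration"] >= 0).all()
    for (subj, region), (spec, ref) in co.spectra.items():
        assert region in REGIONS
        assert ref.is_water_reference and not spec.is_water_reference


def test_effect_table_defaults_match_published_changes():
    eff = EffectTable.default()
    assert eff.effect("aspartate", "cortex") == pytest.approx(-0.416)
    assert eff.effect("glycine", "striatum") == pytest.approx(0.342)
    # the derived NAAG/myo-inositol defaults reproduce the pooled changes
    for region, pooled in [("cortex", -0.142), ("hippocampus", -0.105),
                           ("striatum", 0.046)]:
        base = baseline_concentrations(region)
        num = base["naa"] * (1 + eff.effect("naa", region)) \
            + base["naag"] * (1 + eff.effect("naag", region))
        assert num / (base["naa"] + base["naag"]) - 1 == pytest.approx(pooled)


def test_null_effects_give_no_systematic_group_difference():
    """With a zero effect table the groups differ only by sampling noise."""
    n_sig = 0
    n_seeds = 100
    for seed in range(n_seeds):
        co = generate_cohort(CohortConfig(seed=seed, make_phantoms=False,
                                          make_spectra=False),
                             EffectTable.null())
        tc = co.true_concentrations
        sub = tc[(tc["region"] == "cortex") & (tc["metabolite"] == "naa")]
        a = sub[sub["group"] == "control"]["concentration"]
        b = sub[sub["group"] == "iugr"]["concentration"]
        if sps.ttest_ind(a, b).pvalue < 0.05:
            n_sig += 1
    assert n_sig <= 10        # non-significant in >= 90% of seeds


def test_iugr_cortex_aspartate_ratio_near_published():
    """Across seeds, the group ratio approaches 1 - 0.416 = 0.584."""
    ratios = []
    for seed in range(40):
        co = generate_cohort(CohortConfig(seed=seed, make_phantoms=False,
                                          make_spectra=False))
        tc = co.true_concentrations
        sub = tc[(tc["region"] == "cortex") & (tc["metabolite"] == "aspartate")]
        ratios.append(sub[sub["group"] == "iugr"]["concentration"].mean()
                      / sub[sub["group"] == "control"]["concentration"].mean())
    assert np.mean(ratios) == pytest.approx(0.584, abs=0.03)


def test_snr_and_fwhm_calibration():
    """Realized choline SNR and water FWHM track the configured targets."""
    from neomrs.quant import compute_fwhm, compute_snr
    snrs, fwhms = [], []
    for seed in range(8):
        spec, ref = simulate_spectrum(baseline_concentrations("cortex"),
                                      31.5, seed=seed)
        snrs.append(compute_snr(spec))
        fwhms.append(compute_fwhm(ref))
    assert abs(np.mean(snrs) - 47.7) / 47.7 < 0.20
    assert abs(np.mean(fwhms) - 10.1) / 10.1 < 0.15


def test_phantom_volumes_match_targets():
    phantom = generate_label_phantom(PHANTOM_TARGETS_CONTROL, 0.2)
    assert len(phantom.label_names) == 11
    vols = region_volumes(phantom)
    assert vols["hippocampus"] == pytest.approx(173.3, rel=0.02)
    assert vols["cortex"] == pytest.approx(476.2, rel=0.02)


def test_phantom_single_sphere_and_edge_cases():
    lm = generate_label_phantom({"blob": 100.0}, 0.5)
    assert region_volumes(lm)["blob"] == pytest.approx(100.0, abs=2.0)
    # zero-volume target: label absent
    lm2 = generate_label_phantom({"a": 50.0, "b": 0.0}, 0.5)
    assert set(lm2.label_names.values()) == {"background", "a"}
    # infeasible resolution: fewer than 8 voxels
    with pytest.raises(DomainError):
        generate_label_phantom({"tiny": 0.5}, 0.5)
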