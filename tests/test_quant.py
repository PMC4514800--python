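import numpy as np
import pandas as pd
import pytest

from neomrs.core import Spectrum, lorentzian_line
from neomrs.errors import (DegenerateInputError, DomainError,
                           UndefinedSNRError)
from neomrs.quant import (FitConfig, LinearCombinationModel,
                          absolute_concentration, compute_crlb, compute_fwhm,
                          compute_snr, filter_by_crlb, fit_water_reference)
from neomrs.simulate import simulate_spectrum


def test_noiseless_recovery(noiseless_fit, cortex_conc):
    """Noiseless simulate-then-fit recovers all amplitudes within 0.5%."""
    t = noiseless_fit.table
    for name, truth in cortex_conc.items():
        if truth > 0.5:
            assert t.loc[name, "amplitude"] == pytest.approx(truth, rel=5e-3)


def test_noiseless_nuisance_recovery(noiseless_fit):
    assert noiseless_fit.shift_ppm == pytest.approx(0.02, abs=0.002)
    assert noiseless_fit.phase_rad == pytest.approx(0.1, abs=0.01)
    assert noiseless_fit.damping_hz == pytest.approx(8.1, abs=0.3)
    assert noiseless_fit.converged


def test_residual_carries_no_basis_signal(noiseless_fit, basis, cortex_conc):
    """On noiseless input the converged residual is negligible; with noise it
    is noise-like, i.e. uncorrelated (|r| < 0.05) with every basis column."""
    mask = noiseless_fit.spectrum.window_mask((0.5, 4.25))
    data_rms = float(np.sqrt(np.mean(
        np.abs(noiseless_fit.spectrum.intensity[mask]) ** 2)))
    assert noiseless_fit.residual_rms < 1e-4 * data_rms
    spec, _ = simulate_spectrum(cortex_conc, 31.5, seed=17)
    res = LinearCombinationModel(spec, basis).fit(compute_uncertainty=False,
                                                  noise_sd=1.0)
    resid = (spec.intensity[mask] - res.fitted).real
    rs = []
    for name in ("naa", "creatine", "myo_inositol", "glutamate"):
        col = basis.evaluate(name, res.shift_ppm, res.damping_hz,
                             res.window_ppm_axis).real
        rs.append(abs(np.corrcoef(resid, col)[0, 1]))
    # each |r| consistent with pure noise; the average well below 0.05
    assert max(rs) < 3.0 / np.sqrt(resid.size)
    assert np.mean(rs) < 0.05


def test_exact_single_basis_representation(basis):
    """Data equal to 2 x (NAA basis) yield amplitude 2, all others 0."""
    y = 2.0 * basis.evaluate("naa", extra_fwhm_hz=8.0)
    # add a detectable residual-water line so the acquisition is realistic
    y = y + lorentzian_line(basis.ppm_axis, 4.7, 50.0, 10.0, basis.grid.f0_mhz)
    spec = Spectrum(ppm_axis=basis.ppm_axis, intensity=y,
                    sw_hz=basis.grid.sw_hz, f0_mhz=basis.grid.f0_mhz)
    res = LinearCombinationModel(spec, basis).fit(noise_sd=1e-3)
    assert res.table.loc["naa", "amplitude"] == pytest.approx(2.0, rel=1e-3)
    others = res.table.drop(index=["naa", "residual_water"])
    assert others["amplitude"].abs().max() < 0.01
    # a zero-amplitude metabolite has infinite CRLB and is never retained
    zero_amp = others[others["amplitude"] == 0.0]
    assert (zero_amp["crlb_pct"] == np.inf).all()
    assert not zero_amp["retained"].any()


def test_all_zero_data_rejected(basis):
    spec = Spectrum(ppm_axis=basis.ppm_axis,
                    intensity=np.zeros(basis.grid.n_points, dtype=complex),
                    sw_hz=basis.grid.sw_hz, f0_mhz=basis.grid.f0_mhz)
    with pytest.raises(DegenerateInputError):
        LinearCombinationModel(spec, basis)


def test_crlb_scales_linearly_with_noise(noiseless_fit):
    res = noiseless_fit
    c1 = compute_crlb(res._model, res._theta, res._coef, noise_sd=0.01)
    c2 = compute_crlb(res._model, res._theta, res._coef, noise_sd=0.02)
    finite = np.isfinite(c1) & np.isfinite(c2)
    assert finite.any()
    np.testing.assert_allclose(c2[finite] / c1[finite], 2.0, rtol=1e-9)


def test_absolute_concentration_round_trip(noiseless_pair, noiseless_fit,
                                           basis, cortex_conc):
    _, ref = noiseless_pair
    conc = absolute_concentration(noiseless_fit, ref,
                                  proton_counts=basis.protons)
    tcr = conc["creatine"] + conc["phosphocreatine"]
    truth = cortex_conc["creatine"] + cortex_conc["phosphocreatine"]
    assert tcr == pytest.approx(truth, abs=0.15)       # generator baseline 3.0
    assert np.exp(-12.0 / 158.0) == pytest.approx(0.9269, abs=5e-5)


def test_doubling_water_molality_doubles_concentrations(
        noiseless_pair, noiseless_fit, basis):
    _, ref = noiseless_pair
    c1 = absolute_concentration(noiseless_fit, ref,
                                FitConfig(), basis.protons)
    c2 = absolute_concentration(
        noiseless_fit, ref,
        FitConfig(tissue_water_molality=2 * FitConfig().tissue_water_molality),
        basis.protons)
    valid = c1.dropna().index
    np.testing.assert_allclose(c2[valid] / c1[valid], 2.0, rtol=1e-12)


def test_missing_or_bad_water_reference(noiseless_fit, basis):
    with pytest.raises(DomainError):
        absolute_concentration(noiseless_fit, None, FitConfig(), basis.protons)


def test_filter_by_crlb_threshold():
    tab = pd.DataFrame({"crlb_pct": [10.0, 49.0, 51.0, np.inf],
                        "amplitude": [1, 1, 1, 0]},
                       index=["a", "b", "c", "d"])
    assert len(filter_by_crlb(tab, 50.0)) == 2
    finite = tab[np.isfinite(tab["crlb_pct"])]
    assert len(filter_by_crlb(finite, 100.0)) == 3
    assert len(filter_by_crlb(tab.iloc[:0], 50.0)) == 0


def test_constant_offset_absorbed_by_baseline(noiseless_pair, noiseless_fit,
                                              basis, cortex_conc):
    spec, _ = noiseless_pair
    shifted = spec.copy()
    shifted.intensity = shifted.intensity + 0.3          # constant DC offset
    res = LinearCombinationModel(shifted, basis).fit(
        compute_uncertainty=False, noise_sd=1.0)
    for name, truth in cortex_conc.items():
        if truth > 0.5:
            a0 = noiseless_fit.table.loc[name, "amplitude"]
            a1 = res.table.loc[name, "amplitude"]
            assert a1 == pytest.approx(a0, rel=0.01)


def test_fwhm_closed_form(grid):
    """A Lorentzian from FID damping R s^-1 measures FWHM = R/pi Hz."""
    R = 40.0    # s^-1 -> FWHM 12.732 Hz
    fwhm_hz = R / np.pi
    axis = grid.ppm_axis()
    y = lorentzian_line(axis, 4.7, 100.0, fwhm_hz, grid.f0_mhz)
    spec = Spectrum(ppm_axis=axis, intensity=y, sw_hz=grid.sw_hz,
                    f0_mhz=grid.f0_mhz, is_water_reference=True)
    assert compute_fwhm(spec) == pytest.approx(fwhm_hz, rel=0.01)


def test_fwhm_scales_with_transmitter_frequency(grid):
    """Fixed ppm width doubles in Hz when f0 doubles."""
    from neomrs.core import AcquisitionGrid
    width_ppm = 0.04
    out = []
    for f0 in (grid.f0_mhz, 2 * grid.f0_mhz):
        g = AcquisitionGrid(f0_mhz=f0, sw_hz=grid.sw_hz * f0 / grid.f0_mhz)
        axis = g.ppm_axis()
        y = lorentzian_line(axis, 4.7, 100.0, width_ppm * f0, f0)
        spec = Spectrum(ppm_axis=axis, intensity=y, sw_hz=g.sw_hz, f0_mhz=f0)
        out.append(compute_fwhm(spec))
    assert out[1] / out[0] == pytest.approx(2.0, rel=0.02)


def test_fwhm_peak_touching_edge(grid):
    axis = grid.ppm_axis()
    y = lorentzian_line(axis, 4.7, 100.0, 3000.0, grid.f0_mhz)
    spec = Spectrum(ppm_axis=axis, intensity=y, sw_hz=grid.sw_hz,
                    f0_mhz=grid.f0_mhz)
    with pytest.raises(DomainError):
        compute_fwhm(spec, window_ppm=(4.6, 4.8))


def test_water_reference_fit_recovers_area(grid):
    axis = grid.ppm_axis()
    y = lorentzian_line(axis, 4.72, 1234.5, 10.1, grid.f0_mhz) \
        * np.exp(1j * 0.2)
    spec = Spectrum(ppm_axis=axis, intensity=y, sw_hz=grid.sw_hz,
                    f0_mhz=grid.f0_mhz, is_water_reference=True)
    fit = fit_water_reference(spec)
    assert fit["area"] == pytest.approx(1234.5, rel=1e-3)
    assert fit["ppm"] == pytest.approx(4.72, abs=1e-3)
    assert fit["fwhm_hz"] == pytest.approx(10.1, rel=0.01)


def test_snr_matches_construction(cortex_conc):
    """SNR = choline height / injected noise SD within 10% on average."""
    spec0, _ = simulate_spectrum(cortex_conc, 31.5, noise_sd=0.0)
    from neomrs.quant import choline_peak_height
    h = choline_peak_height(spec0.ppm_axis, spec0.intensity)
    sd = h / 40.0
    snrs = [compute_snr(simulate_spectrum(cortex_conc, 31.5, noise_sd=sd,
                                          seed=s)[0]) for s in range(30)]
    assert np.mean(snrs) == pytest.approx(40.0, rel=0.10)


def test_snr_undefined_without_noise(noiseless_pair):
    spec, _ = noiseless_pair
    clean = spec.copy()
    clean.intensity[clean.window_mask((-2.0, -0.5))] = 0.0  # truly noise-free
    with pytest.raises(UndefinedSNRError):
        compute_snr(clean)
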