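"""Core in-memory containers: spectra, label maps, voxel geometry, acquisition grid.

Conventions used throughout the package:

* ppm axes are stored **ascending**; readers flip descending input. Display
  order (high field left/right) is a presentation concern only.
* All spatial coordinates are physical millimetres in a right-handed frame
  with the origin at the label-map corner; MRS voxels are axis-aligned boxes.
* Complex spectra follow the NMR convention of a causal decaying FID, so a
  single resonance appears as an absorption Lorentzian in the real channel
  and its dispersion partner in the imaginary channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import wofz

from .errors import DomainError, IntegrityError

REGIONS = ("cortex", "hippocampus", "striatum")

#: Required chemical-shift coverage (ppm) for an in-vivo spectrum.
PPM_COVERAGE = (0.5, 5.5)


@dataclass
class Spectrum:
    """A single-voxel 1H spectrum with its acquisition metadata.

    Parameters
    ----------
    ppm_axis : ndarray
        Chemical shift (ppm), strictly monotonic; normalized to ascending.
    intensity : ndarray
        Complex (or real) intensities, same length as ``ppm_axis``.
    sw_hz : float
        Spectral width in Hz.
    f0_mhz : float
        Transmitter frequency in MHz (1 ppm == ``f0_mhz`` Hz).
    tr_ms, te_ms : float
        Repetition and echo time, ms.
    n_averages, n_dummy : int
        Signal averages and dummy scans.
    region_label : str
        One of ``cortex``, ``hippocampus``, ``striatum`` (or "" for fixtures).
    is_water_reference : bool
        True for the non-suppressed water scan.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    sw_hz: float
    f0_mhz: float
    tr_ms: float = 2500.0
    te_ms: float = 12.0
    n_averages: int = 256
    n_dummy: int = 4
    region_label: str = ""
    is_water_reference: bool = False
    subject_id: str = ""

    def __post_init__(self):
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.ppm_axis.shape != self.intensity.shape:
            raise IntegrityError(
                f"ppm_axis length {self.ppm_axis.size} != intensity length "
                f"{self.intensity.size}"
            )
        if self.ppm_axis.size < 2:
            raise IntegrityError("spectrum needs at least 2 points")
        d = np.diff(self.ppm_axis)
        if np.all(d < 0):  # descending input: normalize
            self.ppm_axis = self.ppm_axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise IntegrityError("ppm_axis must be strictly monotonic")
        if self.sw_hz <= 0:
            raise DomainError("sw_hz must be > 0")
        if self.te_ms <= 0:
            raise DomainError("te_ms must be > 0")
        lo, hi = PPM_COVERAGE
        if self.ppm_axis[0] > lo or self.ppm_axis[-1] < hi:
            raise DomainError(
                f"ppm axis [{self.ppm_axis[0]:.2f}, {self.ppm_axis[-1]:.2f}] "
                f"does not cover required [{lo}, {hi}] ppm"
            )

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    @property
    def ppm_step(self) -> float:
        return float(self.ppm_axis[1] - self.ppm_axis[0])

    def window_mask(self, window_ppm) -> np.ndarray:
        """Boolean mask of points inside a (low, high) ppm window."""
        lo, hi = sorted(window_ppm)
        return (self.ppm_axis >= lo) & (self.ppm_axis <= hi)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.ppm_axis = out.ppm_axis.copy()
        out.intensity = out.intensity.copy()
        return out


@dataclass
class AcquisitionGrid:
    """Spectral sampling grid shared by simulator, basis set and fitter."""

    f0_mhz: float = 300.3
    sw_hz: float = 4200.0
    n_points: int = 2048
    center_ppm: float = 4.7

    def ppm_axis(self) -> np.ndarray:
        """Ascending ppm axis centred on ``center_ppm``."""
        k = np.arange(self.n_points)
        hz = (k - self.n_points / 2) * self.sw_hz / self.n_points
        return self.center_ppm + hz / self.f0_mhz

    @property
    def hz_per_point(self) -> float:
        return self.sw_hz / self.n_points


@dataclass
class LabelMap:
    """Integer parcellation volume in physical space."""

    volume: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume)
        if not np.issubdtype(self.volume.dtype, np.integer):
            raise TypeError(f"label volume must be integer, got {self.volume.dtype}")
        if self.volume.ndim != 3:
            raise IntegrityError("label volume must be 3-D")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if np.any(self.voxel_size_mm <= 0):
            raise DomainError("voxel_size_mm components must be > 0")
        present = set(np.unique(self.volume).tolist())
        orphan = present - set(self.label_names)
        if orphan:
            raise IntegrityError(f"label IDs absent from names table: {sorted(orphan)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class VoxelGeometry:
    """Axis-aligned MRS voxel box in label-map physical space (mm)."""

    center_mm: np.ndarray
    dims_mm: np.ndarray

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.dims_mm = np.asarray(self.dims_mm, dtype=float)
        if np.any(self.dims_mm <= 0):
            raise DomainError("voxel dims must be > 0")

    @property
    def lo_mm(self) -> np.ndarray:
        return self.center_mm - self.dims_mm / 2

    @property
    def hi_mm(self) -> np.ndarray:
        return self.center_mm + self.dims_mm / 2


# ---------------------------------------------------------------------------
# Lineshapes (closed-form frequency-domain evaluation)
# ---------------------------------------------------------------------------

def lorentzian_line(ppm_axis, pos_ppm, area, fwhm_hz, f0_mhz):
    """Complex Lorentzian (absorption + dispersion).

    Normalized so the real (absorption) channel integrates to ``area`` over a
    frequency axis in Hz, with absorption FWHM exactly ``fwhm_hz``; peak
    height is ``2*area/(pi*fwhm_hz)``.
    """
    delta_hz = (np.asarray(ppm_axis) - pos_ppm) * f0_mhz
    hwhm = fwhm_hz / 2.0
    denom = hwhm**2 + delta_hz**2
    re = (area / np.pi) * hwhm / denom
    im = (area / np.pi) * delta_hz / denom
    return re + 1j * im


def voigt_line(ppm_axis, pos_ppm, area, gauss_fwhm_hz, lorentz_fwhm_hz, f0_mhz):
    """Complex Voigt line via the Faddeeva function.

    A Gaussian of FWHM ``gauss_fwhm_hz`` convolved with a Lorentzian of FWHM
    ``lorentz_fwhm_hz``; unit-area normalization matching
    :func:`lorentzian_line` (same dispersion sign convention).
    """
    delta_hz = (np.asarray(ppm_axis) - pos_ppm) * f0_mhz
    sigma = gauss_fwhm_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gamma = max(lorentz_fwhm_hz, 1e-9) / 2.0
    z = (delta_hz + 1j * gamma) / (sigma * np.sqrt(2.0))
    return area * wofz(z) / (sigma * np.sqrt(2.0 * np.pi))


def evaluate_lines(ppm_axis, positions_ppm, areas, fwhm_hz, is_gauss, f0_mhz,
                   shift_ppm=0.0, extra_lorentz_fwhm_hz=0.0):
    """Evaluate a set of spectral lines with optional global shift and damping.

    Lorentzian lines get their FWHM increased by ``extra_lorentz_fwhm_hz``
    (Lorentzian-with-Lorentzian convolution adds widths); Gaussian lines
    become Voigt profiles with the extra Lorentzian width.

    Returns the complex spectrum (sum over lines).
    """
    ppm_axis = np.asarray(ppm_axis)
    out = np.zeros(ppm_axis.shape, dtype=complex)
    for pos, area, w, g in zip(positions_ppm, areas, fwhm_hz, is_gauss):
        p = pos + shift_ppm
        if g:
            out += voigt_line(ppm_axis, p, area, w, extra_lorentz_fwhm_hz, f0_mhz)
        else:
            out += lorentzian_line(ppm_axis, p, area, w + extra_lorentz_fwhm_hz,
                                   f0_mhz)
    return out
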