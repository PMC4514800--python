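"""Metabolite/macromolecule models and basis-set construction.

A basis set holds one unit-concentration model spectrum per metabolite (a sum
of Lorentzian lines at its resonances, line area proportional to proton
count) plus 11 broad Gaussian macromolecule components at the fixed in-vivo
positions. Basis spectra are evaluated analytically from their line
parameters, so the fitter can re-evaluate them under a global frequency
shift and extra Lorentzian damping without interpolation error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np

from .core import AcquisitionGrid, evaluate_lines
from .errors import ConfigError

#: In-vivo macromolecule (and mobile lipid) positions, ppm.
MACROMOLECULE_POSITIONS_PPM = (3.0, 2.8, 2.25, 2.05, 1.95, 1.67, 1.4, 1.3,
                               1.2, 0.9, 0.85)

#: Intrinsic (pre-broadening) metabolite linewidth, Hz.
DEFAULT_INTRINSIC_FWHM_HZ = 2.0

METABOLITE_PPM_RANGE = (0.5, 4.5)


@dataclass
class MetaboliteModel:
    """Line-list model of one metabolite.

    resonances : list of (ppm position, relative proton amplitude)
    protons_per_molecule : total modeled proton amplitude (defaults to the
        sum over resonances; exchangeable protons outside the observed window
        are simply not modeled).
    """

    name: str
    resonances: list
    protons_per_molecule: float = 0.0

    def __post_init__(self):
        if not self.resonances:
            raise ConfigError(f"{self.name}: at least one resonance required")
        lo, hi = METABOLITE_PPM_RANGE
        for ppm, amp in self.resonances:
            if amp <= 0:
                raise ConfigError(f"{self.name}: amplitudes must be > 0")
            if not (lo <= ppm <= hi):
                raise ConfigError(
                    f"{self.name}: resonance {ppm} ppm outside [{lo}, {hi}]")
        if not self.protons_per_molecule:
            self.protons_per_molecule = float(sum(a for _, a in self.resonances))


@dataclass
class MacromoleculeModel:
    """The 11 broad macromolecule components fitted alongside metabolites."""

    positions_ppm: tuple = MACROMOLECULE_POSITIONS_PPM
    width_ppm: np.ndarray = None        # Gaussian FWHM per component
    amplitude: np.ndarray = None        # default simulation areas

    def __post_init__(self):
        if tuple(self.positions_ppm) != MACROMOLECULE_POSITIONS_PPM:
            raise ConfigError(
                "macromolecule positions must be exactly "
                f"{MACROMOLECULE_POSITIONS_PPM}")
        n = len(self.positions_ppm)
        if self.width_ppm is None:
            self.width_ppm = np.full(n, 0.15)
        self.width_ppm = np.broadcast_to(
            np.asarray(self.width_ppm, float), (n,)).copy()
        if self.amplitude is None:
            self.amplitude = np.array(
                [2.0, 1.0, 1.5, 2.5, 1.5, 1.0, 2.0, 3.0, 2.0, 3.0, 1.5])
        self.amplitude = np.broadcast_to(
            np.asarray(self.amplitude, float), (n,)).copy()

    def component_names(self):
        return [f"mm_{p:g}" for p in self.positions_ppm]


def load_metabolite_models(path=None) -> dict:
    """Load the shipped (or a user) TSV of line lists into MetaboliteModel's.

    The TSV has columns ``metabolite``, ``ppm``, ``protons``, one row per
    resonance; lines starting with ``#`` are comments.
    """
    if path is None:
        ref = importlib_resources.files("neomrs.resources") / "metabolite_lines.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    lines: dict[str, list] = {}
    for rec in reader:
        lines.setdefault(rec["metabolite"], []).append(
            (float(rec["ppm"]), float(rec["protons"])))
    return {name: MetaboliteModel(name, res) for name, res in lines.items()}


@dataclass
class BasisSet:
    """Per-metabolite model spectra plus macromolecule components.

    Components are stored as line parameters and evaluated analytically;
    ``matrix`` returns the (n_points x n_components) complex design matrix
    under a global shift (ppm) and extra Lorentzian damping (Hz).
    """

    grid: AcquisitionGrid
    names: list                       # component order: metabolites then MMs
    positions: dict = field(default_factory=dict)   # name -> ndarray ppm
    areas: dict = field(default_factory=dict)       # name -> ndarray
    fwhm_hz: dict = field(default_factory=dict)     # name -> ndarray
    is_gauss: dict = field(default_factory=dict)    # name -> ndarray bool
    protons: dict = field(default_factory=dict)     # metabolite -> count
    metabolite_names: list = field(default_factory=list)
    macromolecule_names: list = field(default_factory=list)

    _ppm_cache: np.ndarray = field(default=None, repr=False)

    @property
    def ppm_axis(self) -> np.ndarray:
        if self._ppm_cache is None:
            self._ppm_cache = self.grid.ppm_axis()
        return self._ppm_cache

    def evaluate(self, name, shift_ppm=0.0, extra_fwhm_hz=0.0,
                 ppm_axis=None) -> np.ndarray:
        """Evaluate one component's complex spectrum."""
        axis = self.ppm_axis if ppm_axis is None else ppm_axis
        return evaluate_lines(axis, self.positions[name], self.areas[name],
                              self.fwhm_hz[name], self.is_gauss[name],
                              self.grid.f0_mhz, shift_ppm, extra_fwhm_hz)

    def matrix(self, shift_ppm=0.0, extra_fwhm_hz=0.0, ppm_axis=None,
               names=None) -> np.ndarray:
        """Vectorized (n_points x n_components) complex design matrix."""
        names = self.names if names is None else names
        axis = np.asarray(self.ppm_axis if ppm_axis is None else ppm_axis)
        pos = np.concatenate([self.positions[n] for n in names]) + shift_ppm
        area = np.concatenate([self.areas[n] for n in names])
        fwhm = np.concatenate([self.fwhm_hz[n] for n in names])
        gauss = np.concatenate([self.is_gauss[n] for n in names])
        nlines = np.array([self.positions[n].size for n in names])
        f0 = self.grid.f0_mhz

        lines = np.empty((axis.size, pos.size), dtype=complex)
        lor = ~gauss
        if lor.any():
            delta = (axis[:, None] - pos[None, lor]) * f0
            hwhm = (fwhm[lor] + extra_fwhm_hz) / 2.0
            denom = hwhm[None, :] ** 2 + delta**2
            lines[:, lor] = (area[lor] / np.pi) * (hwhm[None, :] + 1j * delta) \
                / denom
        if gauss.any():
            from scipy.special import wofz
            delta = (axis[:, None] - pos[None, gauss]) * f0
            sigma = fwhm[gauss] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            gamma = max(extra_fwhm_hz, 1e-9) / 2.0
            z = (delta + 1j * gamma) / (sigma[None, :] * np.sqrt(2.0))
            lines[:, gauss] = area[gauss] * wofz(z) \
                / (sigma[None, :] * np.sqrt(2.0 * np.pi))
        # sum contiguous line blocks into their components
        starts = np.concatenate([[0], np.cumsum(nlines)[:-1]])
        return np.add.reduceat(lines, starts, axis=1)

    def mixture(self, concentrations: dict, shift_ppm=0.0,
                extra_fwhm_hz=0.0) -> np.ndarray:
        """Sum of components weighted by a {name: concentration} mapping."""
        unknown = set(concentrations) - set(self.names)
        if unknown:
            raise ConfigError(f"unknown basis components: {sorted(unknown)}")
        out = np.zeros(self.grid.n_points, dtype=complex)
        for name, c in concentrations.items():
            if c != 0:
                out += c * self.evaluate(name, shift_ppm, extra_fwhm_hz)
        return out


def build_basis_set(metabolite_models, macromolecule_model=None,
                    acquisition: AcquisitionGrid = None,
                    intrinsic_fwhm_hz=DEFAULT_INTRINSIC_FWHM_HZ) -> BasisSet:
    """Build the linear-combination basis on a shared acquisition grid.

    Each metabolite contributes one unit-concentration spectrum: Lorentzian
    lines at its resonances, area equal to the relative proton amplitude, so
    a fitted amplitude is directly in concentration units of the simulator.
    """
    if acquisition is None:
        acquisition = AcquisitionGrid()
    if macromolecule_model is None:
        macromolecule_model = MacromoleculeModel()
    if isinstance(metabolite_models, dict):
        metabolite_models = list(metabolite_models.values())
    seen = set()
    for m in metabolite_models:
        if m.name in seen:
            raise ConfigError(f"duplicate metabolite name: {m.name}")
        seen.add(m.name)

    bs = BasisSet(grid=acquisition, names=[])
    for m in metabolite_models:
        pos = np.array([p for p, _ in m.resonances])
        amp = np.array([a for _, a in m.resonances], dtype=float)
        bs.positions[m.name] = pos
        bs.areas[m.name] = amp
        bs.fwhm_hz[m.name] = np.full(pos.size, float(intrinsic_fwhm_hz))
        bs.is_gauss[m.name] = np.zeros(pos.size, dtype=bool)
        bs.protons[m.name] = m.protons_per_molecule
        bs.metabolite_names.append(m.name)

    mm = macromolecule_model
    for name, pos, width, amp in zip(mm.component_names(), mm.positions_ppm,
                                     mm.width_ppm, mm.amplitude):
        bs.positions[name] = np.array([pos])
        bs.areas[name] = np.array([1.0])
        bs.fwhm_hz[name] = np.array([width * acquisition.f0_mhz])
        bs.is_gauss[name] = np.array([True])
        bs.macromolecule_names.append(name)
    bs.names = list(bs.metabolite_names) + list(bs.macromolecule_names)
    bs.macromolecule_model = mm
    return bs
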