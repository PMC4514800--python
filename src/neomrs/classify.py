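"""Spectral-pattern classification.

Pipeline: per-spectrum vector preprocessing (autophase, 4 Hz Lorentzian
apodization, linear baseline, choline referencing to 3.21 ppm, resampling
of the 4.25-0.5 ppm window to 512 points, unit-length normalization),
per-subject region concatenation, sequential forward floating feature
selection (SFFS) with a leave-one-out LDA criterion, Fisher linear
discriminant training, 2-D latent projection, and out-of-bag bootstrap
evaluation.

All selection/training code is deterministic: ties in the selection
criterion break by the larger Fisher criterion, then by the lower feature
index; bootstrap randomness is fully governed by its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Spectrum
from .errors import ConfigError, PreprocessingError
from .thermometry import NOISE_WINDOW_PPM, parabolic_peak

VECTOR_WINDOW_PPM = (0.5, 4.25)
VECTOR_POINTS = 512
CHOLINE_REF_PPM = 3.21
CHOLINE_SEARCH_PPM = (3.10, 3.32)
BASELINE_FLANKS_PPM = ((4.20, 4.25), (0.50, 0.55))


@dataclass
class SpectralVector:
    """Unit-norm spectral vector over the 4.25-0.5 ppm window."""

    values: np.ndarray
    ppm_grid: np.ndarray
    region_label: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ppm_grid = np.asarray(self.ppm_grid, dtype=float)
        if self.values.shape != self.ppm_grid.shape:
            raise ConfigError("values and ppm_grid must match")
        n = np.linalg.norm(self.values)
        if abs(n - 1.0) > 1e-9:
            raise ConfigError(f"vector norm {n} != 1")


@dataclass
class ConcatVector:
    """Concatenation of two region vectors in fixed order (cortex first)."""

    values: np.ndarray
    feature_map: list                 # index -> (region, ppm)
    subject_id: str = ""

    @classmethod
    def from_vectors(cls, first: SpectralVector, second: SpectralVector):
        values = np.concatenate([first.values, second.values])
        fmap = [(first.region_label, p) for p in first.ppm_grid] + \
               [(second.region_label, p) for p in second.ppm_grid]
        return cls(values=values, feature_map=fmap,
                   subject_id=first.subject_id)


def preprocess_vector(spectrum: Spectrum, lb_hz=4.0,
                      n_points=VECTOR_POINTS,
                      window_ppm=VECTOR_WINDOW_PPM) -> SpectralVector:
    """Turn a spectrum into a unit-norm spectral vector.

    Steps: (1) zero-order autophase maximizing the real-channel integral
    over the window; (2) Lorentzian apodization (``lb_hz`` line broadening)
    applied in the time domain; (3) linear baseline through the medians of
    the two flank windows; (4) ppm grid shifted so the total-choline
    maximum sits at 3.21 ppm; (5) resampling to a fixed grid; (6) scaling
    to unit Euclidean norm. Scale-invariant by construction.
    """
    axis = spectrum.ppm_axis
    data = np.asarray(spectrum.intensity, dtype=complex)
    wmask = spectrum.window_mask(window_ppm)
    if not wmask.any() or axis[0] > window_ppm[0] or axis[-1] < window_ppm[1]:
        raise PreprocessingError(f"spectrum does not cover {window_ppm} ppm")
    # (1) autophase: integral of Re(e^{-i phi} S) is maximal at phi=angle(sum S)
    phi = float(np.angle(np.sum(data[wmask])))
    data = data * np.exp(-1j * phi)
    # (2) 4 Hz Lorentzian apodization through the time domain
    if lb_hz:
        fid = np.fft.ifft(np.fft.ifftshift(data))
        t = np.arange(data.size) / spectrum.sw_hz
        fid *= np.exp(-np.pi * lb_hz * t)
        data = np.fft.fftshift(np.fft.fft(fid))
    real = data.real
    # choline detectability gate
    nmask = spectrum.window_mask(NOISE_WINDOW_PPM)
    noise_sd = float(np.std(real[nmask])) if nmask.any() else 0.0
    cmask = spectrum.window_mask(CHOLINE_SEARCH_PPM)
    peak = float(np.max(real[cmask]))
    if noise_sd > 0 and peak / noise_sd < 3.0:
        raise PreprocessingError(
            f"choline peak undetectable (SNR {peak / noise_sd:.2f} < 3)")
    if peak <= 0:
        raise PreprocessingError("no positive choline peak; cannot reference")
    # (3) linear baseline through the flank-window medians
    (f1lo, f1hi), (f2lo, f2hi) = BASELINE_FLANKS_PPM
    m1 = (axis >= f1lo) & (axis <= f1hi)
    m2 = (axis >= f2lo) & (axis <= f2hi)
    x1, y1 = (f1lo + f1hi) / 2, float(np.median(real[m1]))
    x2, y2 = (f2lo + f2hi) / 2, float(np.median(real[m2]))
    slope = (y1 - y2) / (x1 - x2)
    real = real - (y2 + slope * (axis - x2))
    # (4) referencing: shift the grid so choline sits at 3.21 ppm
    chol = parabolic_peak(axis, real, CHOLINE_SEARCH_PPM)
    shifted_axis = axis + (CHOLINE_REF_PPM - chol)
    # (5) resample onto the fixed output grid
    grid = np.linspace(window_ppm[0], window_ppm[1], n_points)
    values = np.interp(grid, shifted_axis, real)
    # (6) unit-length (UL2) normalization
    norm = np.linalg.norm(values)
    if norm == 0:
        raise PreprocessingError("all-zero vector after preprocessing")
    return SpectralVector(values=values / norm, ppm_grid=grid,
                          region_label=spectrum.region_label,
                          subject_id=spectrum.subject_id)


# ---------------------------------------------------------------------------
# Batched LDA machinery
# ---------------------------------------------------------------------------

def _ridge_eps(trace, p):
    return 1e-6 * trace / max(p, 1) + 1e-12


def _batch_loo_accuracy(Xc, y):
    """Leave-one-out LDA accuracy for a batch of candidate feature sets.

    Xc : (C, n, p) feature matrices, y : (n,) in {0, 1}.
    Returns (C,) accuracies.
    """
    C, n, p = Xc.shape
    m0, m1 = (y == 0), (y == 1)
    S0 = Xc[:, m0].sum(axis=1)                       # (C, p)
    S1 = Xc[:, m1].sum(axis=1)
    G0 = np.einsum("cnp,cnq->cpq", Xc[:, m0], Xc[:, m0])
    G1 = np.einsum("cnp,cnq->cpq", Xc[:, m1], Xc[:, m1])
    outer = np.einsum("cnp,cnq->cnpq", Xc, Xc)       # (C, n, p, p)
    n0, n1 = int(m0.sum()), int(m1.sum())

    is1 = y.astype(bool)
    S0_loo = S0[:, None, :] - np.where(~is1[None, :, None], Xc, 0.0)
    S1_loo = S1[:, None, :] - np.where(is1[None, :, None], Xc, 0.0)
    n0_loo = n0 - (~is1).astype(int)                  # (n,)
    n1_loo = n1 - is1.astype(int)
    G0_loo = G0[:, None] - np.where(~is1[None, :, None, None], outer, 0.0)
    G1_loo = G1[:, None] - np.where(is1[None, :, None, None], outer, 0.0)

    mu0 = S0_loo / n0_loo[None, :, None]
    mu1 = S1_loo / n1_loo[None, :, None]
    Sw = (G0_loo - n0_loo[None, :, None, None]
          * np.einsum("cnp,cnq->cnpq", mu0, mu0)
          + G1_loo - n1_loo[None, :, None, None]
          * np.einsum("cnp,cnq->cnpq", mu1, mu1))
    tr = np.trace(Sw, axis1=-2, axis2=-1)
    eps = _ridge_eps(tr, p)
    Sw = Sw + eps[..., None, None] * np.eye(p)[None, None]
    d = mu1 - mu0
    w = np.linalg.solve(Sw, d[..., None])[..., 0]     # (C, n, p)
    score = np.einsum("cnp,cnp->cn", w, Xc) \
        - 0.5 * np.einsum("cnp,cnp->cn", w, mu0 + mu1)
    pred = score > 0
    return (pred == is1[None, :]).mean(axis=1)


def _batch_fisher(Xc, y):
    """Full-data Fisher criterion d' Sw^-1 d for a batch of feature sets."""
    C, n, p = Xc.shape
    m0, m1 = (y == 0), (y == 1)
    mu0 = Xc[:, m0].mean(axis=1)
    mu1 = Xc[:, m1].mean(axis=1)
    X0 = Xc[:, m0] - mu0[:, None, :]
    X1 = Xc[:, m1] - mu1[:, None, :]
    Sw = np.einsum("cnp,cnq->cpq", X0, X0) + np.einsum("cnp,cnq->cpq", X1, X1)
    tr = np.trace(Sw, axis1=-2, axis2=-1)
    eps = _ridge_eps(tr, p)
    Sw = Sw + eps[:, None, None] * np.eye(p)[None]
    d = mu1 - mu0
    return np.einsum("cp,cp->c", d, np.linalg.solve(Sw, d[..., None])[..., 0])


def _criterion_batch(X, y, sets):
    """(accuracy, fisher) criterion for a list of candidate feature sets."""
    sets = np.asarray(sets)
    Xc = X[:, sets].transpose(1, 0, 2)    # (C, n, p)
    return _batch_loo_accuracy(Xc, y), _batch_fisher(Xc, y)


def _better(a, b):
    """Lexicographic comparison of (accuracy, fisher) criterion tuples."""
    if b is None:
        return True
    if abs(a[0] - b[0]) > 1e-12:
        return a[0] > b[0]
    return a[1] > b[1] + 1e-12


def sffs_select(vectors, labels, k, floating=True, search_margin=2,
                exhaustive_limit=600):
    """Sequential forward (floating) feature selection.

    Criterion: leave-one-out accuracy of an LDA restricted to the candidate
    set; ties break by the larger Fisher criterion, then the lower feature
    indices. When the subset space is small (at most ``exhaustive_limit``
    candidate sets) the criterion optimum is found exactly by enumeration —
    the greedy search cannot do worse than that, so this only removes its
    small-space suboptimality. Otherwise the floating variant runs: greedy
    forward steps with conditional backward eliminations whenever removing
    a feature beats the best criterion recorded for the smaller size, and
    ``search_margin`` sizes of exploration past the target. Returns the
    best recorded set of size ``k`` (feature indices, sorted).
    """
    import math
    X = np.asarray(vectors, dtype=float)
    y = _as_binary_labels(labels)
    n, d = X.shape
    if k >= d:
        raise ConfigError(f"k={k} must be smaller than n_features={d}")
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n // 3:
        warnings.warn(
            f"k={k} exceeds n_subjects/3={n // 3}: risk of overtraining",
            stacklevel=2)
    if math.comb(d, k) <= exhaustive_limit:
        return _exhaustive_select(X, y, k)
    max_size = k if not floating else min(k + search_margin, d - 1)
    selected: list = []
    best: dict = {}    # size -> (criterion, feature set)

    def record(size, crit, feats):
        if size not in best or _better(crit, best[size][0]):
            best[size] = (crit, list(feats))
            return True
        return False

    while len(selected) < max_size:
        # forward step
        remaining = [j for j in range(d) if j not in selected]
        cand_sets = [selected + [j] for j in remaining]
        acc, fis = _criterion_batch(X, y, cand_sets)
        order = np.lexsort((remaining, -fis, -acc))
        j_best = remaining[order[0]]
        crit = (acc[order[0]], fis[order[0]])
        selected = selected + [j_best]
        record(len(selected), crit, selected)
        # conditional backward (floating) steps
        while floating and len(selected) > 2:
            size = len(selected) - 1
            cand_sets = [[f for f in selected if f != r] for r in selected]
            acc, fis = _criterion_batch(X, y, cand_sets)
            order = np.lexsort((selected, -fis, -acc))
            r_crit = (acc[order[0]], fis[order[0]])
            prev = best.get(size)
            if prev is not None and not _better(r_crit, prev[0]):
                break
            selected = cand_sets[order[0]]
            record(size, r_crit, selected)
    return sorted(best[k][1])


def _exhaustive_select(X, y, k):
    """Exact criterion optimum over all size-k subsets (small spaces only)."""
    import itertools
    sets = [list(c) for c in itertools.combinations(range(X.shape[1]), k)]
    acc, fis = _criterion_batch(X, y, sets)
    order = np.lexsort((np.arange(len(sets)), -fis, -acc))
    return sorted(sets[order[0]])


def _as_binary_labels(labels):
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        classes = sorted(set(labels.tolist()))
        if len(classes) != 2:
            raise ConfigError(f"need exactly two classes, got {classes}")
        return (labels == classes[1]).astype(int)
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])) or uniq.size != 2:
        raise ConfigError("labels must contain exactly the two classes")
    return labels.astype(int)


# ---------------------------------------------------------------------------
# Fisher LDA model
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Two-class Fisher linear discriminant over selected features."""

    selected_features: list
    weights: np.ndarray
    intercept: float
    class_means_latent: tuple
    feature_names: list = field(default_factory=list)
    ridge_used: bool = False

    def scores(self, vectors) -> np.ndarray:
        X = np.asarray(vectors, dtype=float)[:, self.selected_features]
        return X @ self.weights + self.intercept

    def predict(self, vectors) -> np.ndarray:
        return (self.scores(vectors) > 0).astype(int)

    def training_accuracy(self, vectors, labels) -> float:
        y = _as_binary_labels(labels)
        return float((self.predict(vectors) == y).mean())


def train_lda(vectors, labels, selected_features,
              feature_names=None) -> LDAModel:
    """Fit the Fisher discriminant w ~ Sw^-1 (mu1 - mu0) on selected features.

    A ridge ``eps*I`` (eps = 1e-6 trace/d) is added when the pooled
    within-class scatter is singular (e.g. single-member classes), with a
    warning. The intercept puts the decision boundary at the midpoint of
    the projected class means.
    """
    X = np.asarray(vectors, dtype=float)[:, list(selected_features)]
    y = _as_binary_labels(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 1:
        raise ConfigError("both classes must be present")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    X0, X1 = X[y == 0] - mu0, X[y == 1] - mu1
    Sw = X0.T @ X0 + X1.T @ X1
    p = X.shape[1]
    ridge_used = False
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular within-class scatter; adding ridge",
                      stacklevel=2)
        Sw = Sw + _ridge_eps(np.trace(Sw), p) * np.eye(p)
        ridge_used = True
    w = np.linalg.solve(Sw, mu1 - mu0)
    intercept = -0.5 * float(w @ (mu0 + mu1))
    return LDAModel(
        selected_features=list(selected_features), weights=w,
        intercept=intercept,
        class_means_latent=(float(w @ mu0 + intercept),
                            float(w @ mu1 + intercept)),
        feature_names=list(feature_names) if feature_names else [],
        ridge_used=ridge_used)


def project_latent(model: LDAModel, vectors, labels=None) -> np.ndarray:
    """2-D latent coordinates: discriminant score and within-class residual PC.

    Axis 1 is the Fisher score; axis 2 the projection onto the leading
    principal direction of the within-class residual orthogonal to ``w``
    (zero when only one feature dimension exists). Deterministic,
    order-invariant sign convention: with labels given, axis 1 is oriented
    so the control (class 0) mean — and hence the first control subject on
    separable data — is non-negative; the leading PC's largest component
    is positive.
    """
    X = np.asarray(vectors, dtype=float)[:, model.selected_features]
    axis1 = X @ model.weights + model.intercept
    n, p = X.shape
    if p < 2:
        coords = np.column_stack([axis1, np.zeros(n)])
    else:
        if labels is not None:
            y = _as_binary_labels(labels)
            centered = X.copy()
            for c in (0, 1):
                centered[y == c] -= X[y == c].mean(axis=0)
        else:
            centered = X - X.mean(axis=0)
        wn = model.weights / np.linalg.norm(model.weights)
        resid = centered - np.outer(centered @ wn, wn)
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        pc = vt[0]
        if pc[np.argmax(np.abs(pc))] < 0:
            pc = -pc
        coords = np.column_stack([axis1, resid @ pc])
    if labels is not None:
        y = _as_binary_labels(labels)
        if coords[y == 0, 0].mean() < 0:
            coords = coords * np.array([-1.0, 1.0])
    elif coords[0, 0] < 0:
        coords = coords * np.array([-1.0, 1.0])
    return coords


def plot_latent(coords, labels, ax=None):
    """Scatter plot of the 2-D latent space, colour-coded by class."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    y = _as_binary_labels(labels)
    for c, (marker, name) in enumerate ([("o", "class 0"), ("s", "class 1")]):
        ax.scatter(coords[y == c, 0], coords[y == c, 1], marker=marker,
                   label=name)
    ax.set_xlabel("discriminant score")
    ax.set_ylabel("within-class residual PC")
    ax.legend(frameon=False)
    return ax


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

def bootstrap_accuracy(vectors, labels, k_features, n_reps=1000, seed=0,
                       freeze_features=False, floating=True):
    """Out-of-bag bootstrap accuracy (%) of the SFFS+LDA classifier.

    Each repetition resamples subjects with replacement stratified by
    class, reruns feature selection on the resample (unless
    ``freeze_features``, which reuses the full-data selection — the
    optimistic variant), trains the LDA, and classifies the out-of-bag
    subjects. Repetitions without out-of-bag subjects are skipped and
    counted. Returns (mean accuracy %, n_effective_reps).
    """
    X = np.asarray(vectors, dtype=float)
    y = _as_binary_labels(labels)
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx0 = np.where(y == 0)[0]
    idx1 = np.where(y == 1)[0]
    frozen = sffs_select(X, y, k_features, floating=floating) \
        if freeze_features else None
    accs = []
    skipped = 0
    for _ in range(n_reps):
        boot = np.concatenate([rng.choice(idx0, size=idx0.size, replace=True),
                               rng.choice(idx1, size=idx1.size, replace=True)])
        oob = np.setdiff1d(np.arange(y.size), boot)
        if oob.size == 0:
            skipped += 1
            continue
        feats = frozen if frozen is not None else sffs_select(
            X[boot], y[boot], k_features, floating=floating)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_lda(X[boot], y[boot], feats)
        pred = model.predict(X[oob])
        accs.append(float((pred == y[oob]).mean()))
    if not accs:
        raise ConfigError("no repetition produced out-of-bag subjects")
    return 100.0 * float(np.mean(accs)), len(accs)
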