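import itertools
import warnings

import numpy as np
import pytest

from neomrs.classify import (ConcatVector, _criterion_batch,
                             bootstrap_accuracy, preprocess_vector,
                             project_latent, sffs_select, train_lda)
from neomrs.errors import ConfigError, PreprocessingError
from neomrs.simulate import simulate_spectrum

LABELS_11 = np.array([0] * 6 + [1] * 5)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_contract(cortex_conc):
    spec, _ = simulate_spectrum(cortex_conc, 31.5, seed=2, phase0=0.2)
    vec = preprocess_vector(spec)
    assert vec.values.size == 512
    assert np.linalg.norm(vec.values) == pytest.approx(1.0, abs=1e-9)
    assert vec.ppm_grid[0] == 0.5 and vec.ppm_grid[-1] == 4.25
    # idempotent normalization
    renorm = vec.values / np.linalg.norm(vec.values)
    np.testing.assert_array_equal(renorm, vec.values)


def test_preprocess_scale_invariance(cortex_conc):
    spec, _ = simulate_spectrum(cortex_conc, 31.5, seed=2, phase0=0.2)
    v1 = preprocess_vector(spec)
    scaled = spec.copy()
    scaled.intensity = scaled.intensity * 10.0
    v2 = preprocess_vector(scaled)
    np.testing.assert_allclose(v1.values, v2.values, atol=1e-12)


def test_preprocess_references_choline_to_321(cortex_conc):
    """A spectrum shifted so choline sits near 3.19 is re-referenced to 3.21."""
    spec, _ = simulate_spectrum(cortex_conc, 31.5, noise_sd=0.0,
                                shift_ppm=-0.02)
    vec = preprocess_vector(spec)
    cmask = (vec.ppm_grid >= 3.10) & (vec.ppm_grid <= 3.32)
    found = vec.ppm_grid[cmask][np.argmax(vec.values[cmask])]
    step = vec.ppm_grid[1] - vec.ppm_grid[0]
    assert abs(found - 3.21) <= step + 1e-12


def test_preprocess_rejects_undetectable_choline(basis):
    spec, _ = simulate_spectrum({}, 31.5, noise_sd=0.05, mm_scale=0.0,
                                water_suppression_factor=0.0, seed=0)
    with pytest.raises(PreprocessingError):
        preprocess_vector(spec)


def test_concat_order_and_feature_map(cortex_conc):
    s1, _ = simulate_spectrum(cortex_conc, 31.5, seed=1,
                              region_label="cortex", subject_id="C1")
    s2, _ = simulate_spectrum(cortex_conc, 31.5, seed=2,
                              region_label="hippocampus", subject_id="C1")
    cv = ConcatVector.from_vectors(preprocess_vector(s1),
                                   preprocess_vector(s2))
    assert cv.values.size == 1024
    assert len(cv.feature_map) == 1024
    assert cv.feature_map[0][0] == "cortex"
    assert cv.feature_map[600][0] == "hippocampus"


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

def test_sffs_picks_disjoint_support_feature():
    """A feature whose class supports do not overlap wins the first step."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((11, 20))
        X[:, 7] = np.where(LABELS_11 == 1, 1.0, 0.0) \
            + 0.05 * rng.standard_normal(11)
        if sffs_select(X, LABELS_11, 1) == [7]:
            hits += 1
    assert hits >= 95


def test_sffs_k2_matches_exhaustive_pairs():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((11, 10))
        X[LABELS_11 == 1, :2] += rng.uniform(0.5, 1.5)
        sel = sffs_select(X, LABELS_11, 2)
        acc_sel, _ = _criterion_batch(X, LABELS_11, [sel])
        best = max(_criterion_batch(X, LABELS_11, [list(p)])[0][0]
                   for p in itertools.combinations(range(10), 2))
        assert acc_sel[0] == pytest.approx(best, abs=1e-12)


def test_sffs_floating_never_worse_than_forward():
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((11, 16))
        X[LABELS_11 == 1, :3] += 0.8
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_float, _ = _criterion_batch(
                X, LABELS_11, [sffs_select(X, LABELS_11, 3, floating=True)])
            a_fwd, _ = _criterion_batch(
                X, LABELS_11, [sffs_select(X, LABELS_11, 3, floating=False)])
        assert a_float[0] >= a_fwd[0] - 1e-12


def test_sffs_config_errors():
    X = np.random.default_rng(0).standard_normal((11, 4))
    with pytest.raises(ConfigError):
        sffs_select(X, LABELS_11, 4)
    with pytest.raises(ConfigError):
        sffs_select(X, np.zeros(11, dtype=int), 1)   # one class only
    # 3 features from only 8 subjects exceeds the 1/3 guideline
    X8 = np.random.default_rng(1).standard_normal((8, 6))
    y8 = np.array([0] * 5 + [1] * 3)
    with pytest.warns(UserWarning, match="overtraining"):
        sffs_select(X8, y8, 3, floating=False)


# ---------------------------------------------------------------------------
# LDA + latent projection
# ---------------------------------------------------------------------------

def test_lda_separable_means_1d():
    X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    with pytest.warns(UserWarning, match="ridge"):
        model = train_lda(X, y, [0])
    assert model.training_accuracy(X, y) == 1.0
    # decision threshold at the midpoint 0.5
    assert model.scores(np.array([[0.5]]))[0] == pytest.approx(0.0, abs=1e-9)
    assert model.predict(np.array([[0.4], [0.6]])).tolist() == [0, 1]


def test_lda_matches_closed_form_and_sklearn():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 3))
    y = (rng.random(40) > 0.5).astype(int)
    X[y == 1] += 1.5
    model = train_lda(X, y, [0, 1, 2])
    mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
    Sw = sum((X[y == c] - X[y == c].mean(axis=0)).T
             @ (X[y == c] - X[y == c].mean(axis=0)) for c in (0, 1))
    w_ref = np.linalg.solve(Sw, mu1 - mu0)
    cos = w_ref @ model.weights / np.linalg.norm(w_ref) \
        / np.linalg.norm(model.weights)
    assert cos > 0.999
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
    np.testing.assert_array_equal(model.predict(X), sk.predict(X))


def test_lda_null_training_accuracy():
    accs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 3))
        y = rng.permutation([0] * 20 + [1] * 20)
        accs.append(train_lda(X, y, [0, 1, 2]).training_accuracy(X, y))
    assert np.mean(accs) == pytest.approx(0.5, abs=0.2)


def test_latent_projection_properties():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((11, 5)) * 0.2
    X[LABELS_11 == 1, 0] += 3.0
    model = train_lda(X, LABELS_11, [0, 1])
    coords = project_latent(model, X, LABELS_11)
    # separable data: class-wise axis-1 intervals disjoint
    c0, c1 = coords[LABELS_11 == 0, 0], coords[LABELS_11 == 1, 0]
    assert c0.min() > c1.max() or c1.min() > c0.max()
    # control side non-negative on average (sign convention)
    assert c0.mean() >= 0
    # permutation invariance of the per-subject coordinates
    perm = rng.permutation(11)
    coords_p = project_latent(model, X[perm], LABELS_11[perm])
    np.testing.assert_allclose(coords_p, coords[perm], atol=1e-9)
    # 1-feature model: axis 2 identically zero
    m1 = train_lda(X, LABELS_11, [0])
    assert np.all(project_latent(m1, X, LABELS_11)[:, 1] == 0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_separable():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((11, 40)) * 0.05
    X[LABELS_11 == 1, 3] += 1.0
    a1, n1 = bootstrap_accuracy(X, LABELS_11, 1, n_reps=200, seed=9)
    a2, n2 = bootstrap_accuracy(X, LABELS_11, 1, n_reps=200, seed=9)
    assert (a1, n1) == (a2, n2)
    assert a1 >= 95.0


def test_bootstrap_null_is_chance_level():
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(6):
            X = np.random.default_rng(50 + seed).standard_normal((11, 40))
            a, _ = bootstrap_accuracy(X, LABELS_11, 1, n_reps=150, seed=seed)
            accs.append(a)
    assert 35.0 <= np.mean(accs) <= 65.0
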