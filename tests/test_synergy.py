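"""Synergy extraction: NNMF properties, matching, longitudinal statistics."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.decomposition import NMF

import stsnorm as s
from stsnorm.errors import DegenerateInputError, ValidationError
from stsnorm.synergy import (
    SynergyModel,
    default_spatial_templates,
    extract_synergies,
    longitudinal_feature_table,
    longitudinal_stats,
    match_synergies,
    percent_change,
    reconstruction_quality,
)
from stsnorm.synthetic import SynthConfig, gen_activation_matrix, gen_activations


def _noisy_matrix(seed=1):
    return gen_activation_matrix(SynthConfig(), seed)


# -- NNMF core ---------------------------------------------------------------

def test_factorization_invariants():
    M = _noisy_matrix()
    W, C, errors = extract_synergies(M, 4, seed=0, restarts=5)
    assert np.all(W >= 0) and np.all(C >= 0)
    np.testing.assert_allclose(W.max(axis=0), 1.0)          # column convention
    q = reconstruction_quality(M, W, C)
    assert 0.0 <= q <= 100.0
    # multiplicative updates are monotone non-increasing in Frobenius error
    assert np.all(np.diff(errors) <= 1e-10)


def test_nested_capacity():
    """More synergies never reconstruct worse (same data, same seeds)."""
    M = _noisy_matrix()
    qs = []
    for n in (1, 2, 3, 4):
        W, C, _ = extract_synergies(M, n, seed=0, restarts=5)
        qs.append(reconstruction_quality(M, W, C))
    assert all(b >= a - 1e-6 for a, b in zip(qs, qs[1:]))


def test_rescaling_invariance():
    """Column rescaling of W with compensating C leaves WC identical and
    shifts features predictably."""
    M = _noisy_matrix()
    res = SynergyModel(M).fit(seed=0, restarts=5)
    scale = np.array([2.0, 0.5, 1.5, 3.0])
    W2 = res.W / scale[None, :]
    C2 = res.C * scale[:, None]
    np.testing.assert_allclose(W2 @ C2, res.W @ res.C, rtol=1e-12)
    f1, f2 = res.features(), None
    res2 = s.synergy.SynergyResult(
        W=W2, C=C2, n_synergies=4, reconstruction_quality=res.reconstruction_quality,
        muscle_labels=res.muscle_labels, progress=res.progress, seed=0, restarts=5)
    f2 = res2.features()
    np.testing.assert_allclose(f2["peak_level"], f1["peak_level"] * scale)
    np.testing.assert_array_equal(f2["peak_time_pct"], f1["peak_time_pct"])


def test_sklearn_cross_check():
    """Independent oracle: our best restart is at least as good as sklearn's
    multiplicative-update NMF on the same matrix (within 1 % relative)."""
    M = _noisy_matrix()
    _, _, errors = extract_synergies(M, 4, seed=0, restarts=20)
    ours = errors[-1]
    ref = NMF(n_components=4, solver="mu", init="random", max_iter=2000,
              random_state=0, tol=1e-7)
    Wr = ref.fit_transform(M)
    theirs = float(np.linalg.norm(M - Wr @ ref.components_))
    assert ours <= theirs * 1.01


def test_recovery_noise_free_and_noisy():
    M0, _, _ = gen_activations(SynthConfig())
    W, C, _ = extract_synergies(M0, 4, seed=0, restarts=10)
    assert reconstruction_quality(M0, W, C) >= 99.5
    Mn = _noisy_matrix()
    W, C, _ = extract_synergies(Mn, 4, seed=0, restarts=10)
    assert reconstruction_quality(Mn, W, C) >= 90.0


def test_extraction_validation():
    with pytest.raises(ValidationError):
        extract_synergies(np.full((4, 10), -1.0), 2)
    with pytest.raises(ValidationError):
        extract_synergies(np.ones((3, 10)), 4)         # more synergies than rows
    with pytest.raises(ValidationError):
        extract_synergies(np.ones((3, 10)), 0)
    with pytest.raises(ValidationError):
        extract_synergies(np.full((3, 10), np.nan), 2)
    with pytest.raises(DegenerateInputError):
        reconstruction_quality(np.zeros((3, 4)), np.zeros((3, 1)), np.zeros((1, 4)))


# -- matching ----------------------------------------------------------------

def test_match_synergies_examples():
    ref = np.eye(5)[:, :4]                              # orthogonal one-hots
    np.testing.assert_array_equal(match_synergies(ref, ref), np.arange(4))
    perm = np.array([2, 0, 3, 1])
    np.testing.assert_array_equal(match_synergies(ref[:, perm], ref),
                                  np.argsort(perm))
    with pytest.raises(ValidationError):
        match_synergies(ref, ref[:, :3])


def test_match_recovers_generated_order():
    """Templates align NNMF output to the generator's synergy order."""
    M, W_true, _ = gen_activations(SynthConfig())
    res = SynergyModel(M).fit(seed=0, restarts=10)
    perm = match_synergies(res.W, default_spatial_templates())
    aligned = res.reorder(perm)
    for j in range(4):
        dominant_true = int(np.argmax(W_true[:, j]))
        assert int(np.argmax(aligned.W[:, j])) == dominant_true


# -- longitudinal statistics -------------------------------------------------

def test_longitudinal_stats_oracles():
    g = np.arange(1.0, 11.0)
    stat, p, test = longitudinal_stats([g, g])
    assert test == "wilcoxon_rank_sum"
    assert p > 0.9
    _, p, _ = longitudinal_stats([g, g + 100.0])
    assert p < 0.001
    _, p3, test3 = longitudinal_stats([g, g, g])
    assert test3 == "kruskal_wallis"
    assert p3 > 0.9
    with pytest.raises(ValidationError):
        longitudinal_stats([g])
    with pytest.raises(ValidationError):
        longitudinal_stats([g, np.array([1.0])])


def test_kruskal_null_uniformish():
    """Three identically drawn groups: p > 0.05 in >= 90 % of replicates."""
    rng = np.random.default_rng(0)
    passed = sum(
        longitudinal_stats([rng.normal(size=8) for _ in range(3)])[1] > 0.05
        for _ in range(100))
    assert passed >= 90


def test_percent_change_examples():
    assert percent_change(2.0, 4.0) == 100.0
    assert percent_change(4.0, 2.0) == -50.0
    assert percent_change(1.0, 9.92) == pytest.approx(892.0)
    with pytest.raises(ValidationError):
        percent_change(0.0, 1.0)


def test_longitudinal_feature_table():
    day1 = np.column_stack([np.arange(1.0, 9.0), np.full(8, 5.0)])
    day2 = np.column_stack([np.arange(1.0, 9.0) * 2.0, np.full(8, 5.0)])
    records = longitudinal_feature_table([day1, day2], ["f1", "f2"])
    rec1 = next(r for r in records if r["feature"] == "f1")
    assert rec1["percent_change"] == pytest.approx(100.0)
    assert rec1["test"] == "wilcoxon_rank_sum"
    with pytest.raises(ValidationError):
        longitudinal_feature_table([day1], ["f1", "f2"])
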