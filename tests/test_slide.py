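"""Knockoff construction, the multistage filter and CV significance.

Key properties under test: the knockoff sample matches the model-X
second-moment targets; the W statistic is antisymmetric under swapping
originals and knockoffs; the threshold reproduces hand-computed examples;
selection is deterministic given a seed; the permutation p-value respects
its 1/(n_perm+1) floor.
"""

import numpy as np
import pytest

from rewirekit import (
    SlideSelection,
    cv_significance,
    estimate_latent_scores,
    interaction_search,
    knockoff_filter,
    multistage_select,
    sample_knockoffs,
)
from rewirekit.love import LoveModel
from rewirekit.slide import _knockoff_threshold, _standardize, select_by_frequency


def equicorr_scores(n, K, rho=0.3, seed=0):
    rng = np.random.default_rng(seed)
    Sigma = np.full((K, K), rho) + (1 - rho) * np.eye(K)
    return rng.standard_normal((n, K)) @ np.linalg.cholesky(Sigma).T, Sigma


def test_knockoffs_match_second_moment_targets():
    n, K = 50_000, 4
    Z, Sigma = equicorr_scores(n, K, rho=0.3, seed=1)
    Zt = sample_knockoffs(Z, seed=2)
    Zs = _standardize(Z)
    emp_self = Zt.T @ Zt / n
    emp_cross = Zs.T @ Zt / n
    emp_sigma = Zs.T @ Zs / n
    s = 2 * np.linalg.eigvalsh(emp_sigma).min()
    target_cross = emp_sigma - min(s, 1.0) * np.eye(K)
    assert np.max(np.abs(emp_self - emp_sigma)) < 0.03
    assert np.max(np.abs(emp_cross - target_cross)) < 0.03
    with pytest.raises(ValueError, match="K \\+ 2"):
        sample_knockoffs(np.ones((3, 4)))


def test_w_statistic_antisymmetric_under_swap():
    Z, _ = equicorr_scores(400, 5, seed=3)
    Zt = sample_knockoffs(Z, seed=4)
    y = (Z[:, 0] + 0.5 * np.random.default_rng(5).standard_normal(400) > 0).astype(int)
    _, W = knockoff_filter(Z, Zt, y, w_method="inner")
    _, W_swap = knockoff_filter(Zt, Z, y, w_method="inner")
    assert np.allclose(W_swap, -W)


def test_knockoff_threshold_hand_examples():
    # tau = min{t : (offset + #{W <= -t}) / max(1, #{W >= t}) <= q}
    W = np.array([3.0, 2.0, 1.5, -1.0])
    assert _knockoff_threshold(W, 0.5, offset=1) == 1.5
    # equality of the ratio with the target level is accepted
    assert _knockoff_threshold(np.array([2.0, 1.0, -1.0]), 0.5, offset=0) == 1.0
    # knockoff+ can be infeasible on few candidates
    assert _knockoff_threshold(np.array([2.0, 1.0, -1.0]), 0.5, offset=1) == np.inf
    assert _knockoff_threshold(np.array([0.0, 0.0]), 0.5) == np.inf


def test_selection_keeps_w_at_threshold():
    # with tau = 1.5 the factor sitting exactly at the threshold is selected
    Z, _ = equicorr_scores(300, 4, seed=6)
    Zt = sample_knockoffs(Z, seed=7)
    y = (Z[:, 0] > 0).astype(int)
    selected, W = knockoff_filter(Z, Zt, y, fdr_level=0.5, offset=0)
    tau = _knockoff_threshold(W, 0.5, offset=0)
    assert selected == [int(j) for j in np.flatnonzero(W >= tau)]
    assert 0 in selected


def test_filter_rejects_single_class_outcome():
    Z, _ = equicorr_scores(100, 3, seed=8)
    Zt = sample_knockoffs(Z, seed=9)
    with pytest.raises(ValueError, match="both outcome classes"):
        knockoff_filter(Z, Zt, np.zeros(100))
    with pytest.raises(ValueError, match="w_method"):
        knockoff_filter(Z, Zt, (Z[:, 0] > 0).astype(int), w_method="ols")


def test_multistage_is_deterministic_and_frequency_thresholded():
    Z, _ = equicorr_scores(500, 4, rho=0.2, seed=10)
    y = (Z[:, 1] + 0.3 * np.random.default_rng(11).standard_normal(500) > 0).astype(int)
    sel1, freq1 = multistage_select(Z, y, iterations=20, seed=42, w_method="inner")
    sel2, freq2 = multistage_select(Z, y, iterations=20, seed=42, w_method="inner")
    assert sel1 == sel2 and np.array_equal(freq1, freq2)
    assert 1 in sel1
    assert np.all((freq1 >= 0) & (freq1 <= 1))
    assert sel1 == select_by_frequency(freq1, 0.2)


def test_frequency_threshold_is_inclusive():
    assert select_by_frequency([0.50, 0.10, 0.25], 0.2) == [0, 2]
    assert select_by_frequency([0.2], 0.2) == [0]
    assert select_by_frequency([np.nextafter(0.2, 0)], 0.2) == []


def test_interaction_search_targets_products():
    rng = np.random.default_rng(12)
    Z = rng.standard_normal((1200, 4))
    logit = 2.0 * Z[:, 0] + 2.0 * Z[:, 0] * Z[:, 2]
    y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
    pairs, freq = interaction_search(Z, y, [0], iterations=25, seed=13)
    assert pairs == [(0, 2)]
    assert set(freq) == {(0, 1), (0, 2), (0, 3)}
    assert interaction_search(Z, y, [], iterations=5, seed=0) == ([], {})


def test_latent_scores_project_onto_allocation():
    rng = np.random.default_rng(14)
    A = np.vstack([np.eye(3), np.eye(3), rng.normal(size=(4, 3))])
    Z = rng.standard_normal((200, 3))
    X = Z @ A.T  # noise-free
    model = LoveModel(K=3, pure_sets=[[0], [1], [2]],
                      allocation=A, latent_cov=np.eye(3), delta=0.1, lam=0.0)
    scores = estimate_latent_scores(X, model)
    Xs = _standardize(X)
    expected = np.linalg.lstsq(A, Xs.T, rcond=None)[0].T
    assert np.allclose(scores, expected, atol=1e-8)
    with pytest.raises(ValueError, match="match model genes"):
        estimate_latent_scores(X[:, :5], model)


def test_cv_significance_floor_and_null_behavior():
    rng = np.random.default_rng(15)
    Z = rng.standard_normal((300, 2))
    y = (Z[:, 0] > 0).astype(int)
    table, p = cv_significance(Z[:, :1], y, folds=5, replicates=2, n_perm=19, seed=0)
    assert p == pytest.approx(1 / 20)
    assert table["auc"].mean() > 0.9
    y_null = rng.integers(0, 2, size=300)
    _, p_null = cv_significance(Z[:, :1], y_null, folds=5, replicates=2,
                                n_perm=19, seed=0)
    assert p_null > 0.1
    with pytest.raises(ValueError, match="non-empty"):
        cv_significance(np.empty((300, 0)), y)


def test_selection_container_checks_frequencies():
    with pytest.raises(ValueError, match="below spec"):
        SlideSelection(
            marginal_ids=[0],
            marginal_freq=np.array([0.1]),
            interaction_pairs=[],
            interaction_freq={},
            spec=0.2,
            iterations=10,
            fdr_level=0.1,
        )
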