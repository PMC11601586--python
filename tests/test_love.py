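"""The three-step overlapping-factor estimator.

Oracles: numpy's corrcoef/cov for the second-moment step; exact algebra on
noise-free implied covariances for pure-variable detection and allocation;
feasibility + objective comparison against the single-gene linear program
for the batched mixed-row solver.
"""

import numpy as np
import pytest

from rewirekit import (
    LoveModel,
    NoLatentStructureError,
    estimate_covariance,
    estimate_latent_covariance,
    estimate_mixed_rows,
    find_pure_variables,
    fit_love,
    make_truth,
    simulate_gaussian,
)
from rewirekit.love import _correlation, _solve_mixed_row


def toy_truth(seed=0):
    return make_truth(
        p=60, K=4, pure_per_factor=5, n_mixed=40, signal_factors=(),
        interaction_pairs=(), seed=seed,
    )


def align_to_truth(pure_sets, A_est, truth):
    """Match estimated factors to true factors via their pure sets; returns
    the aligned allocation or None if the partitions differ."""
    perm, signs = [], []
    for est_set in pure_sets:
        matches = [a for a, s in enumerate(truth.pure_sets) if set(s) == set(est_set)]
        if len(matches) != 1:
            return None
        a = matches[0]
        perm.append(a)
        anchor = sorted(est_set)[0]
        signs.append(truth.A_true[anchor, a])  # estimator anchors at +1
    if sorted(perm) != list(range(truth.K)):
        return None
    aligned = np.zeros_like(A_est)
    for est_f, (a, s) in enumerate(zip(perm, signs)):
        aligned[:, a] = s * A_est[:, est_f]
    return aligned


def test_correlation_matches_numpy(rng):
    X = rng.normal(size=(50, 6))
    corr, ok = _correlation(X, scale="correlation")
    assert ok.all()
    assert np.allclose(corr, np.corrcoef(X.T))
    cov, _ = _correlation(X, scale="covariance")
    assert np.allclose(cov, np.cov(X.T, ddof=0))
    with pytest.raises(ValueError, match="scale"):
        _correlation(X, scale="precision")


def test_constant_genes_are_dropped(rng):
    X = rng.normal(size=(30, 4))
    X[:, 2] = 7.0
    est = estimate_covariance(X)
    assert list(est.gene_ids) == ["g0", "g1", "g3"]
    assert est.sigma.shape == (3, 3)
    with pytest.raises(ValueError, match=">= 3 cells"):
        estimate_covariance(X[:2])


def test_pure_variable_detection_exact_on_noise_free_covariance():
    truth = toy_truth()
    sigma0 = truth.A_true @ truth.C_true @ truth.A_true.T
    K, pure_sets, signs = find_pure_variables(sigma0, delta=0.05)
    assert K == truth.K
    assert [sorted(s) for s in pure_sets] == [sorted(s) for s in truth.pure_sets]
    # recovered signs agree with the true loading signs up to a per-factor flip
    for a, members in enumerate(pure_sets):
        rel = signs[members] * truth.A_true[members, a]
        assert np.all(rel == rel[0]) and abs(rel[0]) == 1.0


def test_no_structure_raises():
    with pytest.raises(NoLatentStructureError):
        find_pure_variables(np.eye(8), delta=0.05)
    with pytest.raises(ValueError, match="delta"):
        find_pure_variables(np.eye(8), delta=0.0)


def test_latent_covariance_and_allocation_exact_on_noise_free_covariance():
    truth = toy_truth()
    sigma0 = truth.A_true @ truth.C_true @ truth.A_true.T
    _, pure_sets, signs = find_pure_variables(sigma0, delta=0.05)
    C = estimate_latent_covariance(sigma0, pure_sets, signs)
    A = estimate_mixed_rows(sigma0, pure_sets, signs, C, lam=0.0)
    aligned = align_to_truth(pure_sets, A, truth)
    assert aligned is not None
    assert np.max(np.abs(aligned - truth.A_true)) < 1e-10
    # C matches the true latent covariance after the same factor matching;
    # the estimator's per-factor sign convention (anchor gene = +1) flips
    # the corresponding rows/columns of C.
    perm = np.array([
        next(a for a, s in enumerate(truth.pure_sets) if set(s) == set(g))
        for g in pure_sets
    ])
    flips = np.array([truth.A_true[sorted(g)[0], a] for g, a in zip(pure_sets, perm)])
    C_adj = np.outer(flips, flips) * C
    inv = np.argsort(perm)
    assert np.allclose(C_adj[np.ix_(inv, inv)], truth.C_true)


def test_batched_mixed_rows_match_single_gene_program(rng):
    from rewirekit.love import _solve_mixed_rows_batch

    K = 4
    M = rng.normal(size=(K, K))
    C = M @ M.T / K + np.eye(K)
    H = rng.normal(size=(7, K))
    lam = 0.05
    rows = _solve_mixed_rows_batch(C, H, lam)
    assert rows is not None
    for h, row in zip(H, rows):
        single = _solve_mixed_row(C, h, lam)
        # the minimum-l1 program can have several optima; compare the
        # objective and check feasibility instead of the solutions
        assert np.max(np.abs(C @ row - h)) <= lam + 1e-7
        assert np.abs(row).sum() == pytest.approx(np.abs(single).sum(), abs=1e-6)


def test_fit_love_recovers_structure_from_sampled_cells():
    truth = toy_truth(seed=3)
    X, _, _ = simulate_gaussian(truth, 1500, seed=11)
    model = fit_love(X, scale="covariance", seed=0)
    assert model.K == truth.K
    aligned = align_to_truth(model.pure_sets, model.allocation, truth)
    assert aligned is not None, "pure-gene partition not recovered"
    assert np.max(np.abs(aligned - truth.A_true)) < 0.15
    assert model.unassigned().size == 0
    assert len(model.cv_errors) == 24  # full grid explored


def test_correlation_scale_is_invariant_to_global_rescaling():
    truth = toy_truth(seed=5)
    X, _, _ = simulate_gaussian(truth, 600, seed=7)
    corr1, _ = _correlation(X, scale="correlation")
    corr2, _ = _correlation(X * 3.7, scale="correlation")
    assert np.allclose(corr1, corr2, atol=1e-12)
    K1, p1, s1 = find_pure_variables(corr1, delta=0.1)
    K2, p2, s2 = find_pure_variables(corr2, delta=0.1)
    assert K1 == K2 and p1 == p2 and np.array_equal(s1, s2)


def test_love_model_validates_pure_rows():
    A = np.zeros((4, 2))
    A[0, 0] = A[1, 0] = 1.0
    A[2, 1] = -1.0
    A[3, 1] = 1.0
    C = np.eye(2)
    LoveModel(K=2, pure_sets=[[0, 1], [2, 3]], allocation=A, latent_cov=C,
              delta=0.1, lam=0.0)
    bad = A.copy()
    bad[0, 1] = 0.5
    with pytest.raises(ValueError, match="signed unit"):
        LoveModel(K=2, pure_sets=[[0, 1], [2, 3]], allocation=bad, latent_cov=C,
                  delta=0.1, lam=0.0)
    with pytest.raises(ValueError, match="disjoint"):
        LoveModel(K=2, pure_sets=[[0, 1], [1, 3]], allocation=A, latent_cov=C,
                  delta=0.1, lam=0.0)
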