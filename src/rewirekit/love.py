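"""Identifiable overlapping latent-factor estimation from the gene-gene
correlation matrix.

The model is X = Z A^T + E with a genes x factors allocation matrix A in
which every factor owns at least two *pure* genes — genes loading on that
factor alone.  Pure genes make the factorization identifiable (up to
factor permutation and sign) without orthogonality assumptions, and they
can be detected directly from the data covariance: two pure genes of the
same factor are the most strongly correlated partners of one another, up
to a tolerance 2*delta that absorbs estimation noise.

Estimation is a three-step procedure:

1. pure-variable detection partitions a subset of genes into K groups and
   fixes within-group signs;
2. the K x K latent covariance C is estimated by averaging sign-corrected
   correlations over pure pairs;
3. each remaining (mixed) gene's allocation row is the minimum-l1 solution
   of ``C a ~ h`` within an L-infinity tolerance ``lambda``, where h
   averages that gene's sign-corrected correlations with each pure group.

``fit_love`` selects (delta, lambda) on a grid by held-out covariance
reconstruction error and refits on all cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .io_data import ExpressionMatrix

logger = logging.getLogger("rewirekit")

DEFAULT_DELTA_GRID = (0.02, 0.05, 0.08, 0.12, 0.16, 0.20)
DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.05, 0.1)


class NoLatentStructureError(ValueError):
    """Raised when no pure variable exists at the requested tolerance."""


@dataclass
class CovarianceEstimate:
    """Gene-gene Pearson correlation matrix (constant genes dropped)."""

    sigma: np.ndarray  # genes x genes, symmetric, unit diagonal
    n_cells: int
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        p = self.sigma.shape[0]
        if self.sigma.shape != (p, p):
            raise ValueError("sigma must be square")


@dataclass
class LoveModel:
    """Fitted overlapping-factor model.

    ``pure_sets`` holds K disjoint gene-index lists; rows of ``allocation``
    for pure genes are signed unit vectors in their factor's column.
    Genes with an all-zero allocation row are unassigned.
    """

    K: int
    pure_sets: list  # K lists of gene indices
    allocation: np.ndarray  # genes x K
    latent_cov: np.ndarray  # K x K
    delta: float
    lam: float
    gene_ids: np.ndarray = field(default=None)
    signs: np.ndarray = field(default=None)  # per-gene pure-variable signs
    cv_errors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        flat = [g for s in self.pure_sets for g in s]
        if len(flat) != len(set(flat)):
            raise ValueError("pure_sets must be pairwise disjoint")
        for s in self.pure_sets:
            if not s:
                raise ValueError("pure sets must be non-empty")
        for s_idx, members in enumerate(self.pure_sets):
            rows = self.allocation[members]
            nz = np.abs(rows) > 0
            if not (nz.sum(axis=1) == 1).all() or not nz[:, s_idx].all():
                raise ValueError("pure rows must be signed unit vectors")
            if not np.allclose(np.abs(rows[:, s_idx]), 1.0):
                raise ValueError("pure rows must have magnitude 1")

    @property
    def n_genes(self) -> int:
        return self.allocation.shape[0]

    def unassigned(self) -> np.ndarray:
        return np.flatnonzero(np.all(self.allocation == 0, axis=1))


def _correlation(values: np.ndarray, scale: str = "correlation") -> tuple[np.ndarray, np.ndarray]:
    """Gene-gene second-moment matrix over the cell axis.

    ``correlation`` standardizes genes (scale-free, suits heteroskedastic
    counts); ``covariance`` only centers them, which preserves the
    l1-normalized allocation geometry the pure-variable criterion relies
    on.  Returns (matrix, non-constant gene mask); constant-gene rows and
    columns are zeroed with unit diagonal.
    """
    sd = values.std(axis=0)
    ok = sd > 0
    Xc = values - values.mean(axis=0)
    if scale == "correlation":
        Xs = Xc / np.where(ok, sd, 1.0)
        corr = (Xs.T @ Xs) / values.shape[0]
        np.clip(corr, -1.0, 1.0, out=corr)
    elif scale == "covariance":
        corr = (Xc.T @ Xc) / values.shape[0]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    if scale == "correlation":
        np.fill_diagonal(corr, 1.0)
    return corr, ok


def _as_values(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, ExpressionMatrix):
        return X.values, X.gene_ids
    X = np.asarray(X, dtype=float)
    return X, np.array([f"g{j}" for j in range(X.shape[1])], dtype=object)


def estimate_covariance(X) -> CovarianceEstimate:
    """Pearson correlation of genes across cells.

    Genes constant across cells carry no correlation signal and are
    dropped with a warning.  Requires at least 3 cells.
    """
    values, gene_ids = _as_values(X)
    if values.shape[0] < 3:
        raise ValueError("estimate_covariance requires >= 3 cells")
    corr, ok = _correlation(values)
    if not ok.all():
        logger.warning("estimate_covariance: dropped %d constant genes", int((~ok).sum()))
    idx = np.flatnonzero(ok)
    return CovarianceEstimate(
        sigma=corr[np.ix_(idx, idx)], n_cells=values.shape[0], gene_ids=gene_ids[idx]
    )


def find_pure_variables(
    sigma, delta: float, allow_singletons: bool = False
) -> tuple[int, list, np.ndarray]:
    """Detect pure variables and group them into K factors.

    For gene i let M_i = max_{j != i} |Sigma_ij| and
    S_i = {j != i : |Sigma_ij| >= M_i - 2*delta}.  Gene i is pure iff
    M_i > 2*delta (it has a genuinely correlated partner) and for every
    j in S_i, | M_j - |Sigma_ij| | <= 2*delta.  Pure genes are grouped by
    connected components of the mutual-partner relation; signs are
    propagated from the lowest-index anchor of each group.

    Returns (K, pure_sets, signs) where ``signs`` is a full-length vector
    with +-1 on pure genes and 0 elsewhere.
    """
    S = sigma.sigma if isinstance(sigma, CovarianceEstimate) else np.asarray(sigma, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be > 0")
    p = S.shape[0]
    absS = np.abs(S).astype(float)
    np.fill_diagonal(absS, -np.inf)
    M = absS.max(axis=1)

    # S_i membership matrix (j in S_i), excluding the diagonal
    in_Si = absS >= (M[:, None] - 2 * delta)

    # pure criterion: every close partner j reciprocates within tolerance
    cond = np.abs(M[None, :] - absS) <= 2 * delta
    pure = (M > 2 * delta) & np.all(~in_Si | cond, axis=1)
    pure_idx = np.flatnonzero(pure)
    if pure_idx.size == 0:
        raise NoLatentStructureError(f"no latent structure at delta={delta}")

    # group pure genes: i ~ j iff j in S_i (or i in S_j), components
    adj = {int(i): set() for i in pure_idx}
    for i in pure_idx:
        for j in pure_idx:
            if i != j and (in_Si[i, j] or in_Si[j, i]):
                adj[int(i)].add(int(j))
                adj[int(j)].add(int(i))
    seen: set = set()
    groups = []
    for i in sorted(map(int, pure_idx)):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        groups.append(sorted(comp))

    kept = []
    for g in groups:
        if len(g) == 1 and not allow_singletons:
            logger.debug("find_pure_variables: dropping singleton pure group %s", g)
            continue
        kept.append(g)
    if not kept:
        raise NoLatentStructureError(
            f"no pure group of size >= 2 at delta={delta} (singletons not allowed)"
        )
    kept.sort(key=lambda g: g[0])

    signs = np.zeros(p)
    for g in kept:
        anchor = g[0]
        signs[anchor] = 1.0
        # propagate signs along a BFS tree of the group
        remaining = set(g[1:])
        frontier = [anchor]
        while frontier:
            u = frontier.pop()
            for v in sorted(remaining):
                if absS[u, v] > 0 and np.isfinite(absS[u, v]):
                    s = np.sign(S[u, v])
                    if s != 0:
                        signs[v] = signs[u] * s
                        remaining.discard(v)
                        frontier.append(v)
        for v in remaining:  # disconnected within group: default +
            signs[v] = 1.0
    return len(kept), kept, signs


def estimate_latent_covariance(
    sigma, pure_sets: list, signs: np.ndarray, allow_singletons: bool = False
) -> np.ndarray:
    """Estimate the K x K latent covariance from pure-pair correlations.

    C_aa averages sign-corrected correlations over distinct pure pairs in
    group a (for an allowed singleton, the max sign-corrected entry);
    C_ab averages sign-corrected correlations across groups a and b.
    """
    S = sigma.sigma if isinstance(sigma, CovarianceEstimate) else np.asarray(sigma, dtype=float)
    K = len(pure_sets)
    C = np.zeros((K, K))
    for a, ga in enumerate(pure_sets):
        if len(ga) == 1:
            if not allow_singletons:
                raise ValueError(f"pure group {a} has size 1; allow_singletons not set")
            i = ga[0]
            others = np.delete(np.arange(S.shape[0]), i)
            C[a, a] = np.max(np.abs(S[i, others]))
        else:
            vals = [
                signs[i] * signs[j] * S[i, j]
                for ii, i in enumerate(ga)
                for j in ga[ii + 1 :]
            ]
            C[a, a] = float(np.mean(vals))
        for b in range(a + 1, K):
            gb = pure_sets[b]
            vals = [signs[i] * signs[j] * S[i, j] for i in ga for j in gb]
            C[a, b] = C[b, a] = float(np.mean(vals))
    return C


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _solve_mixed_row(C: np.ndarray, h: np.ndarray, lam: float) -> np.ndarray:
    """min ||a||_1  s.t.  ||C a - h||_inf <= lam  (exact solve at lam=0)."""
    K = C.shape[0]
    if lam == 0:
        try:
            return np.linalg.solve(C, h)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "latent covariance is singular; use lam > 0 or regularize"
            )
    # LP over [a; u]: min sum(u), -u <= a <= u, -lam <= C a - h <= lam
    c = np.concatenate([np.zeros(K), np.ones(K)])
    I = np.eye(K)
    A_ub = np.block(
        [[C, np.zeros((K, K))], [-C, np.zeros((K, K))], [I, -I], [-I, -I]]
    )
    b_ub = np.concatenate([h + lam, lam - h, np.zeros(2 * K)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * (2 * K), method="highs")
    if res.status == 0:
        a = res.x[:K]
    else:  # degenerate program: soft-thresholded least squares fallback
        try:
            a = _soft_threshold(np.linalg.solve(C, h), lam)
        except np.linalg.LinAlgError:
            a = _soft_threshold(np.linalg.lstsq(C, h, rcond=None)[0], lam)
    a[np.abs(a) < 1e-10] = 0.0
    return a


def estimate_mixed_rows(
    sigma, pure_sets: list, signs: np.ndarray, C: np.ndarray, lam: float = 0.0
) -> np.ndarray:
    """Allocate mixed-gene weights; returns the full genes x K matrix A.

    Pure rows are signed unit vectors.  Each mixed gene j solves the
    minimum-l1 program against h_j[a] = mean of sign-corrected
    correlations with the pure genes of group a.  All-zero rows mean
    "unassigned".
    """
    S = sigma.sigma if isinstance(sigma, CovarianceEstimate) else np.asarray(sigma, dtype=float)
    p = S.shape[0]
    K = len(pure_sets)
    A = np.zeros((p, K))
    pure_all = set()
    for a, g in enumerate(pure_sets):
        for i in g:
            A[i, a] = signs[i] if signs[i] != 0 else 1.0
            pure_all.add(i)
    # h for all genes at once: average sign-corrected correlation per group
    H = np.zeros((p, K))
    for a, g in enumerate(pure_sets):
        H[:, a] = (S[:, g] * signs[g][None, :]).mean(axis=1)
    mixed = np.array([j for j in range(p) if j not in pure_all], dtype=int)
    if mixed.size == 0:
        return A
    if lam == 0:
        try:
            A[mixed] = np.linalg.solve(C, H[mixed].T).T
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "latent covariance is singular; use lam > 0 or regularize"
            )
        A[np.abs(A) < 1e-10] = 0.0
        return A
    rows = _solve_mixed_rows_batch(C, H[mixed], lam)
    if rows is not None:
        A[mixed] = rows
    else:  # joint program failed: solve gene by gene with fallbacks
        for j in mixed:
            A[j] = _solve_mixed_row(C, H[j], lam)
    return A


def _solve_mixed_rows_batch(C: np.ndarray, H_mixed: np.ndarray, lam: float):
    """All mixed rows in one block-diagonal LP; None if the LP fails.

    The per-gene programs are independent, so stacking them as
    kron(I_m, B) costs one solver call instead of m, which dominates the
    runtime of the (delta, lambda) grid search.
    """
    m, K = H_mixed.shape[0], C.shape[0]
    I = np.eye(K)
    B = np.block(
        [[C, np.zeros((K, K))], [-C, np.zeros((K, K))], [I, -I], [-I, -I]]
    )
    A_ub = sparse.kron(sparse.eye(m, format="csr"), sparse.csr_matrix(B), format="csr")
    b_ub = np.concatenate(
        [np.concatenate([h + lam, lam - h, np.zeros(2 * K)]) for h in H_mixed]
    )
    c = np.tile(np.concatenate([np.zeros(K), np.ones(K)]), m)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(None, None), method="highs")
    if res.status != 0:
        return None
    rows = res.x.reshape(m, 2 * K)[:, :K]
    rows[np.abs(rows) < 1e-10] = 0.0
    return rows


def _fit_steps(
    sigma: np.ndarray, delta: float, lam: float, allow_singletons: bool = False
):
    K, pure_sets, signs = find_pure_variables(sigma, delta, allow_singletons)
    C = estimate_latent_covariance(sigma, pure_sets, signs, allow_singletons)
    A = estimate_mixed_rows(sigma, pure_sets, signs, C, lam)
    return K, pure_sets, signs, C, A


def _offdiag_error(sigma: np.ndarray, A: np.ndarray, C: np.ndarray) -> float:
    R = sigma - A @ C @ A.T
    np.fill_diagonal(R, 0.0)
    return float(np.linalg.norm(R))


def fit_love(
    X,
    delta_grid=DEFAULT_DELTA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    n_repeats: int = 5,
    allow_singletons: bool = False,
    scale: str = "correlation",
) -> LoveModel:
    """Run the three-step estimator with (delta, lambda) selected by
    held-out covariance reconstruction.

    Cells are split in half ``n_repeats`` times; each grid point is fit on
    one half and scored by the off-diagonal Frobenius error between the
    implied correlation A C A^T and the held-out half's correlation.  The
    best pair (ties -> first in grid order) is refit on all cells.
    """
    values, gene_ids = _as_values(X)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        half = n // 2
        splits.append((perm[:half], perm[half:]))
        splits.append((perm[half:], perm[:half]))

    fold_corrs = [
        (_correlation(values[tr], scale)[0], _correlation(values[te], scale)[0])
        for tr, te in splits
    ]

    errors = {(d, l): [] for d in delta_grid for l in lambda_grid}
    diagnostics = {}
    for corr_tr, corr_te in fold_corrs:
        for delta in delta_grid:
            # pure sets and C depend on delta only; share them across lambda
            try:
                _, pure_sets, signs = find_pure_variables(
                    corr_tr, delta, allow_singletons
                )
                C = estimate_latent_covariance(
                    corr_tr, pure_sets, signs, allow_singletons
                )
            except (NoLatentStructureError, np.linalg.LinAlgError) as exc:
                for lam in lambda_grid:
                    diagnostics[(delta, lam)] = str(exc)
                    errors[(delta, lam)].append(np.inf)
                continue
            for lam in lambda_grid:
                try:
                    A = estimate_mixed_rows(corr_tr, pure_sets, signs, C, lam)
                    errors[(delta, lam)].append(_offdiag_error(corr_te, A, C))
                except np.linalg.LinAlgError as exc:
                    diagnostics[(delta, lam)] = str(exc)
                    errors[(delta, lam)].append(np.inf)
    errors = {key: float(np.mean(errs)) for key, errs in errors.items()}

    best = None
    for key in ((d, l) for d in delta_grid for l in lambda_grid):
        if best is None or errors[key] < errors[best]:
            best = key
    if not np.isfinite(errors[best]):
        raise NoLatentStructureError(
            "no grid point produced a valid model; diagnostics: " + repr(diagnostics)
        )
    delta, lam = best

    corr_full, ok = _correlation(values, scale)
    if not ok.all():
        logger.warning("fit_love: %d constant genes excluded", int((~ok).sum()))
    idx = np.flatnonzero(ok)
    sub = corr_full[np.ix_(idx, idx)]
    K, pure_sub, signs_sub, C, A_sub = _fit_steps(sub, delta, lam, allow_singletons)

    p = values.shape[1]
    A = np.zeros((p, K))
    A[idx] = A_sub
    signs = np.zeros(p)
    signs[idx] = signs_sub
    pure_sets = [[int(idx[i]) for i in g] for g in pure_sub]
    return LoveModel(
        K=K,
        pure_sets=pure_sets,
        allocation=A,
        latent_cov=C,
        delta=float(delta),
        lam=float(lam),
        gene_ids=gene_ids,
        signs=signs,
        cv_errors={f"{d}|{l}": e for (d, l), e in errors.items()},
    )
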