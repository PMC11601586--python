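"""Supervised latent-factor selection with iterative multistage knockoffs.

Per-cell factor scores are least-squares projections of standardized
expression onto the allocation matrix.  Significant factors are found by
repeating a model-X knockoff filter over many iterations with fresh
knockoff draws: each iteration builds second-order Gaussian knockoffs of
the factor scores (equicorrelated construction), computes antisymmetric
W statistics from an l1-regularized linear-probability fit, and applies
the knockoff+ threshold at the target FDR.  A factor is reported when its
selection frequency across iterations reaches ``spec`` (default 0.2 over
300 iterations).  Interacting factors are found the same way on products
of scores after residualizing the outcome on the marginal factors, and
model significance is assessed by replicated stratified cross-validation
with permutation testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

from .io_data import ExpressionMatrix
from .love import LoveModel
from .networks import definitive_assignment
from .preprocess import gene_condition_auc

logger = logging.getLogger("rewirekit")


@dataclass
class SlideSelection:
    """Selected standalone and interacting factors with frequencies."""

    marginal_ids: list
    marginal_freq: np.ndarray  # frequency for every factor
    interaction_pairs: list  # (anchor, partner) tuples passing spec
    interaction_freq: dict  # pair -> frequency, all candidates
    spec: float
    iterations: int
    fdr_level: float
    cv_auc: pd.DataFrame | None = None
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        for j in self.marginal_ids:
            if self.marginal_freq[j] < self.spec:
                raise ValueError("reported marginal below spec frequency")


def _standardize(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def estimate_latent_scores(X, model: LoveModel, ridge: float = 0.0) -> np.ndarray:
    """Least-squares factor scores: Z_hat = X_c A (A^T A)^{-1}.

    ``X`` is an ExpressionMatrix (genes matched to the model) or an
    array whose columns already align with the model's genes.  Columns
    are standardized first; a rank-deficient A falls back to a ridge-
    regularized inverse with a logged regularizer.
    """
    if isinstance(X, ExpressionMatrix):
        idx = X.gene_index(model.gene_ids)
        values = X.values[:, idx]
    else:
        values = np.asarray(X, dtype=float)
    if values.shape[1] != model.n_genes:
        raise ValueError("X columns must match model genes")
    Xs = _standardize(values)
    A = model.allocation
    G = A.T @ A
    try:
        if ridge:
            raise np.linalg.LinAlgError
        Z = np.linalg.solve(G, A.T @ Xs.T).T
    except np.linalg.LinAlgError:
        reg = ridge if ridge else 1e-6 * np.trace(G) / max(G.shape[0], 1)
        logger.warning("estimate_latent_scores: ridge fallback, regularizer %g", reg)
        Z = np.linalg.solve(G + reg * np.eye(G.shape[0]), A.T @ Xs.T).T
    return Z


def sample_knockoffs(Z: np.ndarray, seed=None, min_eig: float = 1e-3) -> np.ndarray:
    """Second-order Gaussian knockoffs, equicorrelated construction.

    Scores are standardized; with correlation Sigma and
    s = min(2*lambda_min(Sigma), 1) on every coordinate,
    Ztilde = Z (I - Sigma^{-1} diag(s)) + N(0, 2 diag(s) -
    diag(s) Sigma^{-1} diag(s)), so the joint second moments of
    [Z, Ztilde] match the model-X target blocks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = _standardize(Z)
    n, K = Z.shape
    if n < K + 2:
        raise ValueError("need at least K + 2 cells for knockoff construction")
    Sigma = (Z.T @ Z) / n
    # shrink toward identity until comfortably positive definite
    gamma = 0.0
    for _ in range(60):
        S_try = (1 - gamma) * Sigma + gamma * np.eye(K)
        if np.linalg.eigvalsh(S_try).min() >= min_eig:
            Sigma = S_try
            break
        gamma = max(gamma * 2, 1e-4)
    else:
        raise ValueError("factor covariance not positive definite after shrinkage")
    lam_min = float(np.linalg.eigvalsh(Sigma).min())
    s = np.full(K, min(2 * lam_min, 1.0))
    Sinv = np.linalg.inv(Sigma)
    D = np.diag(s)
    mean = Z @ (np.eye(K) - Sinv @ D)
    V = 2 * D - D @ Sinv @ D
    V = (V + V.T) / 2
    w, Q = np.linalg.eigh(V)
    w = np.clip(w, 0, None)
    L = Q @ np.diag(np.sqrt(w))
    return mean + rng.standard_normal((n, K)) @ L.T


def _knockoff_threshold(W: np.ndarray, fdr_level: float, offset: int = 1) -> float:
    ts = np.sort(np.unique(np.abs(W[W != 0])))
    for t in ts:
        ratio = (offset + np.sum(W <= -t)) / max(1, np.sum(W >= t))
        if ratio <= fdr_level:
            return float(t)
    return np.inf


def knockoff_filter(
    Z: np.ndarray,
    Z_tilde: np.ndarray,
    y: np.ndarray,
    fdr_level: float = 0.1,
    w_method: str = "lasso",
    n_alphas: int = 25,
    offset: int = 1,
) -> tuple[list, np.ndarray]:
    """Knockoff selection at the target FDR.

    W_j = |beta_j| - |beta_{j+K}| from an l1-regularized linear-
    probability fit of y on [Z, Ztilde] (regularization by 5-fold CV);
    ``w_method='inner'`` uses the faster marginal inner-product statistic.
    A binary response must contain both classes.

    ``offset=1`` (default) is the knockoff+ threshold
    tau = min{t : (1 + #{W <= -t}) / max(1, #{W >= t}) <= fdr_level},
    which controls the FDR but by construction cannot make fewer than
    1/fdr_level discoveries; ``offset=0`` drops the +1 (modified-FDR
    control) and is what the frequency-stabilized multistage loop uses
    per iteration, where stability across iterations — not the
    per-iteration threshold — provides the control.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if set(classes) <= {0.0, 1.0} and len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    ZZ = _standardize(np.hstack([Z, Z_tilde]))
    yc = y - y.mean()
    K = Z.shape[1]
    if w_method == "lasso":
        # 5-fold CV path with the one-standard-error rule: the min-MSE
        # alpha retains chance-level coefficients (over-selection), which
        # would let a finite-sample fluke of a null factor persist across
        # knockoff draws; the 1-SE alpha zeroes them.
        path = LassoCV(cv=5, alphas=n_alphas, max_iter=5000).fit(ZZ, yc)
        mse = path.mse_path_.mean(axis=1)
        se = path.mse_path_.std(axis=1) / np.sqrt(path.mse_path_.shape[1])
        imin = int(np.argmin(mse))
        # alphas_ is descending; the first index within 1 SE is the largest
        i1se = int(np.argmax(mse <= mse[imin] + se[imin]))
        beta = Lasso(alpha=path.alphas_[i1se], max_iter=5000).fit(ZZ, yc).coef_
        W = np.abs(beta[:K]) - np.abs(beta[K:])
    elif w_method == "inner":
        corr = ZZ.T @ yc / len(yc)
        W = np.abs(corr[:K]) - np.abs(corr[K:])
    else:
        raise ValueError(f"unknown w_method {w_method!r}")
    tau = _knockoff_threshold(W, fdr_level, offset=offset)
    selected = [int(j) for j in np.flatnonzero(W >= tau)] if np.isfinite(tau) else []
    return selected, W


def select_by_frequency(freq, spec: float) -> list:
    """Indices whose selection frequency meets the threshold.

    The threshold is inclusive: a factor selected in exactly a ``spec``
    fraction of iterations is reported.
    """
    return [int(j) for j in np.flatnonzero(np.asarray(freq, dtype=float) >= spec)]


def multistage_select(
    Z: np.ndarray,
    y: np.ndarray,
    iterations: int = 300,
    spec: float = 0.2,
    fdr_level: float = 0.1,
    seed: int = 0,
    w_method: str = "lasso",
    offset: int = 0,
) -> tuple[list, np.ndarray]:
    """Frequency-stabilized knockoff selection.

    Repeats (fresh knockoff draw -> knockoff filter) ``iterations``
    times with seeds derived deterministically from ``seed``; returns
    the factors whose selection frequency is >= ``spec`` (inclusive)
    together with all frequencies.

    The per-iteration filter defaults to the offset-0 threshold: the
    knockoff+ (+1) variant cannot select fewer than 1/fdr_level factors
    in any iteration, so with the typical handful of factors every
    iteration would return the empty set and the frequency criterion
    would be vacuous.  Stability control comes from requiring selection
    in a ``spec`` fraction of iterations.
    """
    Z = np.asarray(Z, dtype=float)
    K = Z.shape[1]
    counts = np.zeros(K)
    children = np.random.SeedSequence(seed).spawn(iterations)
    for child in children:
        rng = np.random.default_rng(child)
        Zt = sample_knockoffs(Z, seed=rng)
        sel, _ = knockoff_filter(
            Z, Zt, y, fdr_level=fdr_level, w_method=w_method, offset=offset
        )
        counts[sel] += 1
    freq = counts / iterations
    return select_by_frequency(freq, spec), freq


def interaction_search(
    Z: np.ndarray,
    y: np.ndarray,
    marginals,
    iterations: int = 300,
    spec: float = 0.2,
    fdr_level: float = 0.1,
    seed: int = 0,
    w_method: str = "lasso",
    offset: int = 0,
) -> tuple[list, dict]:
    """Select interacting factor pairs anchored on the marginals.

    Candidate terms are standardized products Z_j * Z_k for anchors j in
    ``marginals`` and partners k != j (unordered pairs deduplicated).
    The outcome is residualized on the marginal scores before running the
    multistage selection on the candidate matrix.
    """
    marginals = list(marginals)
    if not marginals:
        return [], {}
    Z = np.asarray(Z, dtype=float)
    K = Z.shape[1]
    pairs, cols = [], []
    seen = set()
    for j in marginals:
        for k in range(K):
            if k == j:
                continue
            key = (min(j, k), max(j, k))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((j, k))
            cols.append(Z[:, j] * Z[:, k])
    Zint = _standardize(np.column_stack(cols))
    # residualize the outcome on the marginal scores (with intercept)
    Zm = np.column_stack([np.ones(len(y)), Z[:, marginals]])
    coef, *_ = np.linalg.lstsq(Zm, np.asarray(y, dtype=float), rcond=None)
    r = np.asarray(y, dtype=float) - Zm @ coef
    selected_idx, freq = multistage_select(
        Zint, r, iterations=iterations, spec=spec, fdr_level=fdr_level,
        seed=seed, w_method=w_method, offset=offset,
    )
    freq_by_pair = {pairs[i]: float(freq[i]) for i in range(len(pairs))}
    return [pairs[i] for i in selected_idx], freq_by_pair


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment; reduces fold count when a
    class is rarer than the requested number of folds."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    k = min(folds, counts[counts > 0].min())
    if k < folds:
        logger.warning("cv_significance: reducing folds from %d to %d", folds, k)
    if k < 2:
        raise ValueError("cannot form at least 2 folds with both classes")
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % k
    return [(assign != f, assign == f) for f in range(k)]


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    return gene_condition_auc(scores, y)


def _cv_mean_auc(F: np.ndarray, y: np.ndarray, folds: int, replicates: int,
                 rng: np.random.Generator):
    rows = []
    for rep in range(replicates):
        for f, (tr, te) in enumerate(_stratified_folds(y, folds, rng)):
            Xtr = np.column_stack([np.ones(tr.sum()), F[tr]])
            Xte = np.column_stack([np.ones(te.sum()), F[te]])
            coef, *_ = np.linalg.lstsq(Xtr, y[tr].astype(float), rcond=None)
            rows.append({"replicate": rep, "fold": f, "auc": _auc(Xte @ coef, y[te])})
    table = pd.DataFrame(rows)
    return float(table["auc"].mean()), table


def cv_significance(
    Z_selected: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    replicates: int = 20,
    n_perm: int = 100,
    seed: int = 0,
    interactions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Replicated stratified CV of a linear-probability model on the
    selected factors (+ interaction terms), with a permutation null.

    The statistic is the mean out-of-fold AUC; permutation_p =
    (1 + #{null >= observed}) / (n_perm + 1).
    """
    Z_selected = np.asarray(Z_selected, dtype=float)
    if Z_selected.ndim != 2 or Z_selected.shape[1] == 0:
        raise ValueError("selected factor matrix must be non-empty")
    F = Z_selected if interactions is None else np.hstack([Z_selected, interactions])
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    observed, table = _cv_mean_auc(F, y, folds, replicates, rng)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        null_stat, _ = _cv_mean_auc(F, y_perm, folds, max(1, replicates // 4), rng)
        exceed += null_stat >= observed
    p = (1 + exceed) / (n_perm + 1)
    return table, float(p)


def factor_member_table(
    model: LoveModel,
    X: ExpressionMatrix,
    y: np.ndarray,
    selected_factors,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top-member lists per selected factor.

    Per factor: the union of the ``top_n`` genes by |allocation weight|
    and the ``top_n`` factor genes with condition AUC farthest from 0.5,
    annotated with the AUC and a condition tag (exposed if AUC > 0.5,
    control if < 0.5, neutral at exactly 0.5).
    """
    assign = definitive_assignment(model.allocation)
    idx = X.gene_index(model.gene_ids)
    rows = []
    for f in selected_factors:
        members = np.flatnonzero(assign == f)
        if members.size == 0:
            continue
        aucs = {
            int(g): gene_condition_auc(X.values[:, idx[g]], y) for g in members
        }
        by_weight = sorted(members, key=lambda g: (-abs(model.allocation[g, f]), g))
        by_auc = sorted(members, key=lambda g: (-abs(aucs[int(g)] - 0.5), g))
        union = sorted(set(map(int, by_weight[:top_n])) | set(map(int, by_auc[:top_n])))
        for g in union:
            auc = aucs[g]
            tag = "exposed" if auc > 0.5 else ("control" if auc < 0.5 else "neutral")
            rows.append(
                {
                    "factor": f,
                    "gene": str(model.gene_ids[g]),
                    "weight": float(model.allocation[g, f]),
                    "auc": float(auc),
                    "condition_tag": tag,
                }
            )
    return pd.DataFrame(rows, columns=["factor", "gene", "weight", "auc", "condition_tag"])
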