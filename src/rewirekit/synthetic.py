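"""Synthetic single-cell data with a known overlapping factor model.

The generator emulates the statistical structure of droplet single-cell
count matrices from a two-arm exposure study: ~90% zeros, two exposure
groups, several animals per group, multiple cell types, and a second
batch-shifted dataset.  The latent layer is an overlapping factor model
with at least two pure genes per factor (so the unsupervised estimator's
identifiability conditions hold by construction); the count layer is
Poisson with a log link on the latent Gaussian signal, which produces
zero inflation through the mean function rather than post-hoc zeroing so
rank statistics stay well defined.

Defaults describe the study conditions used throughout the test suite:
p = 300 genes, K = 6 factors, 5 pure genes per factor, equicorrelated
latent covariance (rho = 0.2), Gaussian noise sd 0.3, dropout target 0.9
and a 3-latent-SD condition shift on the signal factors (a strong,
clearly separable exposure effect: the shift alone separates the groups
with AUC Phi(3/sqrt(2)) ~ 0.983 on the latent scale, leaving margin for
the attenuation introduced by the Poisson count layer).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_data import ExpressionMatrix

logger = logging.getLogger("rewirekit")

DEFAULT_EFFECT = 3.0  # condition shift on signal factors, latent SD units
DEFAULT_RHO = 0.2


@dataclass
class TruthModel:
    """Ground truth for the generator; the acceptance oracle."""

    A_true: np.ndarray  # genes x K
    C_true: np.ndarray  # K x K, symmetric positive definite
    pure_sets: list  # K lists of gene indices
    beta_marginal: np.ndarray  # per-factor effect on the condition logit / shift
    beta_interaction: dict  # (j, k) -> effect
    noise_sd: float
    dropout_rate: float
    batch_shift: np.ndarray  # per-gene log-scale offset for dataset B
    interactome_edges: list  # planted module + background edges (gene names)
    seed: int
    gene_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        flat = [g for s in self.pure_sets for g in s]
        if len(flat) != len(set(flat)):
            raise ValueError("pure sets must be disjoint")
        if any(len(s) < 2 for s in self.pure_sets):
            raise ValueError("every factor needs >= 2 pure genes")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if np.linalg.eigvalsh((self.C_true + self.C_true.T) / 2).min() <= 0:
            raise ValueError("C_true must be positive definite")
        if self.gene_ids is None:
            self.gene_ids = np.array(
                [f"g{j}" for j in range(self.A_true.shape[0])], dtype=object
            )

    @property
    def p(self) -> int:
        return self.A_true.shape[0]

    @property
    def K(self) -> int:
        return self.A_true.shape[1]

    @property
    def signal_factors(self) -> np.ndarray:
        return np.flatnonzero(self.beta_marginal != 0)

    def implied_covariance(self) -> np.ndarray:
        return self.A_true @ self.C_true @ self.A_true.T + self.noise_sd**2 * np.eye(self.p)


def make_truth(
    p: int = 300,
    K: int = 6,
    pure_per_factor: int = 5,
    n_mixed: int = 60,
    overlap_frac: float = 0.5,
    signal_factors=(0, 1),
    interaction_pairs=((0, 1),),
    marginal_effect: float = DEFAULT_EFFECT,
    interaction_effect: float = DEFAULT_EFFECT,
    rho: float = DEFAULT_RHO,
    noise_sd: float = 0.3,
    dropout_rate: float = 0.9,
    batch_shift_sd: float = 0.3,
    n_background_edges: int | None = None,
    seed: int = 0,
) -> TruthModel:
    """Build a deterministic ground-truth model.

    The first K * pure_per_factor genes are pure (signed unit rows), the
    next ``n_mixed`` are mixed with 2-3 non-zero weights drawn from
    +-Uniform(0.3, 1) and l1-normalized (``overlap_frac`` is the chance
    of a third factor), and any remaining genes are structureless
    background.  The latent covariance is equicorrelated with unit
    variance.
    """
    if p < K * pure_per_factor + n_mixed:
        raise ValueError("p must be >= K * pure_per_factor + n_mixed")
    rng = np.random.default_rng(seed)
    A = np.zeros((p, K))
    pure_sets = []
    g = 0
    for a in range(K):
        members = list(range(g, g + pure_per_factor))
        for i in members:
            A[i, a] = rng.choice([-1.0, 1.0])
        pure_sets.append(members)
        g += pure_per_factor
    for j in range(g, g + n_mixed):
        n_nz = 2 + (rng.random() < overlap_frac)
        factors = rng.choice(K, size=n_nz, replace=False)
        w = rng.uniform(0.3, 1.0, size=n_nz) * rng.choice([-1.0, 1.0], size=n_nz)
        A[j, factors] = w / np.abs(w).sum()
    C = np.full((K, K), rho) + (1 - rho) * np.eye(K)

    beta = np.zeros(K)
    beta[list(signal_factors)] = marginal_effect
    beta_int = {tuple(sorted(pair)): interaction_effect for pair in interaction_pairs}

    gene_ids = np.array([f"g{j}" for j in range(p)], dtype=object)
    edges = set()
    for a in range(K):
        members = [j for j in range(p) if A[j, a] != 0]
        # ring through the factor module keeps it connected and sparse
        for i in range(len(members)):
            u, v = members[i], members[(i + 1) % len(members)]
            if u != v:
                edges.add(tuple(sorted((u, v))))
        for u in pure_sets[a]:
            for v in pure_sets[a]:
                if u < v:
                    edges.add((u, v))
    n_bg = n_background_edges if n_background_edges is not None else p // 2
    while n_bg > 0:
        u, v = rng.integers(0, p, size=2)
        if u != v:
            e = tuple(sorted((int(u), int(v))))
            if e not in edges:
                edges.add(e)
                n_bg -= 1
    edge_names = sorted((str(gene_ids[u]), str(gene_ids[v])) for u, v in edges)

    return TruthModel(
        A_true=A,
        C_true=C,
        pure_sets=pure_sets,
        beta_marginal=beta,
        beta_interaction=beta_int,
        noise_sd=noise_sd,
        dropout_rate=dropout_rate,
        batch_shift=rng.normal(0, batch_shift_sd, size=p),
        interactome_edges=edge_names,
        seed=seed,
        gene_ids=gene_ids,
    )


def simulate_latent(
    truth: TruthModel,
    n_cells: int,
    seed: int = 0,
    label_mode: str = "shift",
    group_proportions=(0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent factor scores Z and condition labels y.

    ``shift`` mode fixes group sizes by proportion and adds the marginal
    effect to the signal factors of exposed cells; ``model`` mode draws
    labels from a logistic model with marginal and interaction terms.
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.C_true)
    Z = rng.standard_normal((n_cells, truth.K)) @ L.T
    if label_mode == "shift":
        n1 = int(round(n_cells * group_proportions[1]))
        y = np.zeros(n_cells, dtype=int)
        y[n_cells - n1 :] = 1
        for f in truth.signal_factors:
            Z[y == 1, f] += truth.beta_marginal[f]
    elif label_mode == "model":
        logit = Z @ truth.beta_marginal
        for (j, k), b in truth.beta_interaction.items():
            logit = logit + b * Z[:, j] * Z[:, k]
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")
    return Z, y


def simulate_gaussian(
    truth: TruthModel, n_cells: int, seed: int = 0, label_mode: str = "shift"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian signal layer X = Z A^T + noise (no count sampling)."""
    Z, y = simulate_latent(truth, n_cells, seed=seed, label_mode=label_mode)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    X = Z @ truth.A_true.T + truth.noise_sd * rng.standard_normal((n_cells, truth.p))
    return X, Z, y


def _calibrate_intercept(Y: np.ndarray, b: float, target_zero: float) -> float:
    """Bisection on the intercept of the log-linear Poisson mean so the
    expected zero fraction E[exp(-exp(a + b Y))] hits the target."""

    def zero_frac(a):
        return float(np.mean(np.exp(-np.exp(a + b * Y))))

    lo, hi = -15.0, 8.0
    if not (zero_frac(hi) <= target_zero <= zero_frac(lo)):
        raise ValueError(
            f"cannot calibrate dropout {target_zero}: attainable range "
            f"[{zero_frac(hi):.3f}, {zero_frac(lo):.3f}]"
        )
    for _ in range(80):
        mid = (lo + hi) / 2
        if zero_frac(mid) > target_zero:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_cells(
    truth: TruthModel,
    n_cells: int = 2000,
    group_proportions=(0.5, 0.5),
    samples_per_group: int = 4,
    cell_types=("epithelial",),
    dataset_tag: str = "A",
    seed: int = 0,
    label_mode: str = "shift",
    count_slope: float = 1.5,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Simulate a raw-count cells x genes matrix with annotations.

    counts ~ Poisson(exp(a + b * Y [+ batch_shift])), with the intercept
    ``a`` calibrated by bisection so the realized zero fraction matches
    the truth's dropout target (within a fraction of a point in
    expectation); dataset tag "B" applies the per-gene batch shift.
    Returns (matrix, latent Z, condition labels).
    """
    rng = np.random.default_rng(seed)
    Z, y = simulate_latent(
        truth, n_cells, seed=seed, label_mode=label_mode,
        group_proportions=group_proportions,
    )
    Y = Z @ truth.A_true.T + truth.noise_sd * rng.standard_normal((n_cells, truth.p))
    shift = truth.batch_shift if dataset_tag == "B" else 0.0
    a = _calibrate_intercept(Y + (shift / count_slope if dataset_tag == "B" else 0.0),
                             count_slope, truth.dropout_rate)
    mu = np.exp(a + count_slope * Y + shift)
    counts = rng.poisson(mu).astype(float)

    # per-cell annotations: equal sample blocks within each condition
    sample_id = np.empty(n_cells, dtype=object)
    for cond in (0, 1):
        idx = np.flatnonzero(y == cond)
        for i, cell in enumerate(idx):
            block = i * samples_per_group // max(len(idx), 1)
            sample_id[cell] = f"{dataset_tag}-m{cond}{block}"
    cell_type = np.array(
        [cell_types[i % len(cell_types)] for i in range(n_cells)], dtype=object
    )
    X = ExpressionMatrix(
        values=counts,
        gene_ids=truth.gene_ids.copy(),
        cell_ids=np.array([f"{dataset_tag}-c{i}" for i in range(n_cells)], dtype=object),
        condition=y,
        cell_type=cell_type,
        sample_id=sample_id,
        dataset_tag=dataset_tag,
        normalized=False,
    )
    realized = float((counts == 0).mean())
    if abs(realized - truth.dropout_rate) > 0.05:
        logger.warning(
            "simulate_cells: realized zero fraction %.3f vs target %.3f",
            realized,
            truth.dropout_rate,
        )
    return X, Z, y


def emit_truth_files(truth: TruthModel, out_dir, Z: np.ndarray | None = None,
                     labels: np.ndarray | None = None) -> None:
    """Write ground-truth TSV/JSON files for use as test oracles."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = truth.gene_ids.astype(str)
    pd.DataFrame(truth.A_true, index=genes,
                 columns=[f"F{a}" for a in range(truth.K)]).to_csv(
        out / "A_true.tsv", sep="\t")
    pd.DataFrame(truth.C_true).to_csv(out / "C_true.tsv", sep="\t",
                                      header=False, index=False)
    rows = [
        {"gene": genes[i], "factor": a, "sign": float(truth.A_true[i, a])}
        for a, members in enumerate(truth.pure_sets)
        for i in members
    ]
    pd.DataFrame(rows).to_csv(out / "pure_sets.tsv", sep="\t", index=False)
    pd.DataFrame({"factor": range(truth.K), "beta": truth.beta_marginal}).to_csv(
        out / "beta_marginal.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"factor_j": j, "factor_k": k, "beta": b}
         for (j, k), b in sorted(truth.beta_interaction.items())]
    ).to_csv(out / "beta_interaction.tsv", sep="\t", index=False)
    pd.DataFrame(truth.interactome_edges, columns=["gene_a", "gene_b"]).to_csv(
        out / "interactome.tsv", sep="\t", index=False, header=False)
    (out / "meta.json").write_text(json.dumps({
        "noise_sd": truth.noise_sd,
        "dropout_rate": truth.dropout_rate,
        "seed": truth.seed,
        "K": truth.K,
        "p": truth.p,
    }, indent=2))
    pd.DataFrame({"gene": genes, "batch_shift": truth.batch_shift}).to_csv(
        out / "batch_shift.tsv", sep="\t", index=False)
    if Z is not None:
        df = pd.DataFrame(Z, columns=[f"F{a}" for a in range(truth.K)])
        if labels is not None:
            df["condition"] = labels
        df.to_csv(out / "latent_scores.tsv", sep="\t", index=False)


def load_truth_files(out_dir) -> TruthModel:
    """Round-trip partner of emit_truth_files."""
    out = Path(out_dir)
    A = pd.read_csv(out / "A_true.tsv", sep="\t", index_col=0)
    C = pd.read_csv(out / "C_true.tsv", sep="\t", header=None).to_numpy(dtype=float)
    meta = json.loads((out / "meta.json").read_text())
    pure = pd.read_csv(out / "pure_sets.tsv", sep="\t")
    gene_pos = {g: i for i, g in enumerate(A.index)}
    pure_sets = [
        sorted(gene_pos[g] for g in pure.loc[pure["factor"] == a, "gene"])
        for a in range(meta["K"])
    ]
    beta = pd.read_csv(out / "beta_marginal.tsv", sep="\t")["beta"].to_numpy()
    bi = pd.read_csv(out / "beta_interaction.tsv", sep="\t")
    beta_int = {
        (int(r.factor_j), int(r.factor_k)): float(r.beta) for r in bi.itertuples()
    }
    edges = pd.read_csv(out / "interactome.tsv", sep="\t", header=None)
    shift = pd.read_csv(out / "batch_shift.tsv", sep="\t")["batch_shift"].to_numpy()
    return TruthModel(
        A_true=A.to_numpy(dtype=float),
        C_true=C,
        pure_sets=pure_sets,
        beta_marginal=beta,
        beta_interaction=beta_int,
        noise_sd=meta["noise_sd"],
        dropout_rate=meta["dropout_rate"],
        batch_shift=shift,
        interactome_edges=[tuple(r) for r in edges.to_numpy()],
        seed=meta["seed"],
        gene_ids=A.index.to_numpy(dtype=object),
    )
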