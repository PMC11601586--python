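"""Quality control, normalization, differential expression and enrichment.

Cell QC keeps cells with strictly more than ``min_genes`` detected genes,
strictly fewer than ``max_genes``, and a mitochondrial-count fraction
strictly below ``max_mito_frac`` — all thresholds exclusive.  Sparsity
filtering drops genes with more than 99.5% zeros and then cells with more
than 90% zeros.  Differential expression uses the two-sided Wilcoxon
rank-sum test with a natural-log fold change on de-logged group means, and
over-representation uses the one-sided hypergeometric (Fisher exact) test
with Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_data import ExpressionMatrix

logger = logging.getLogger("rewirekit")


@dataclass
class DEResult:
    """Per-gene differential expression between exposed and control cells."""

    genes: np.ndarray
    lnfc: np.ndarray  # natural-log fold change, exposed vs control
    p_value: np.ndarray
    p_adjusted: np.ndarray  # Benjamini-Hochberg
    mean_control: np.ndarray
    mean_exposed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes.astype(str),
                "lnFC": self.lnfc,
                "p_value": self.p_value,
                "p_adjusted": self.p_adjusted,
                "mean_control": self.mean_control,
                "mean_exposed": self.mean_exposed,
            }
        )


def qc_filter_cells(
    X: ExpressionMatrix,
    min_genes: int = 200,
    max_genes: int = 3000,
    max_mito_frac: float = 0.25,
    mito_prefix: str = "mt-",
) -> ExpressionMatrix:
    """Keep cells with min_genes < detected genes < max_genes and a
    mitochondrial count fraction < max_mito_frac (all strict).

    Mitochondrial genes are identified by a case-insensitive id prefix.
    """
    if X.normalized:
        raise ValueError("qc_filter_cells expects raw counts")
    detected = (X.values > 0).sum(axis=1)
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in X.gene_ids]
    )
    totals = X.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, X.values[:, is_mito].sum(axis=1) / np.maximum(totals, 1e-300), 1.0
        )
    keep_lo = detected > min_genes
    keep_hi = detected < max_genes
    keep_mito = mito_frac < max_mito_frac
    keep = keep_lo & keep_hi & keep_mito
    logger.info(
        "qc_filter_cells: removed %d (low genes), %d (high genes), %d (mito); kept %d/%d",
        int((~keep_lo).sum()),
        int((~keep_hi).sum()),
        int((~keep_mito).sum()),
        int(keep.sum()),
        X.n_cells,
    )
    if not keep.any():
        raise ValueError("qc_filter_cells removed all cells")
    return X.subset_cells(keep)


def normalize_log(X: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per-cell total-count normalization followed by log1p:
    value -> ln(1 + scale * value / cell_total)."""
    if X.normalized:
        raise ValueError("matrix is already normalized")
    totals = X.values.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total cell encountered; run qc_filter_cells first")
    values = np.log1p(scale * X.values / totals[:, None])
    out = X.subset_cells(np.ones(X.n_cells, dtype=bool))
    out.values = values
    out.normalized = True
    return out


def sparsity_filter(
    X: ExpressionMatrix, gene_zero_max: float = 0.995, cell_zero_max: float = 0.90
) -> ExpressionMatrix:
    """Drop genes whose zero fraction is strictly > gene_zero_max, then
    (after recomputing) cells strictly > cell_zero_max."""
    gene_zero = (X.values == 0).mean(axis=0)
    keep_genes = ~(gene_zero > gene_zero_max)
    out = X.subset_genes(keep_genes)
    cell_zero = (out.values == 0).mean(axis=1) if out.n_genes else np.ones(out.n_cells)
    keep_cells = ~(cell_zero > cell_zero_max)
    logger.info(
        "sparsity_filter: dropped %d/%d genes, %d/%d cells",
        int((~keep_genes).sum()),
        X.n_genes,
        int((~keep_cells).sum()),
        X.n_cells,
    )
    out = out.subset_cells(keep_cells)
    if out.n_genes == 0 or out.n_cells == 0:
        raise ValueError("sparsity_filter removed everything")
    return out


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Handles ties through midranks; feasible for groups of <= 8 each.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    mu = n1 * (len(b)) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= dev_obs - 1e-12
        total += 1
    return count / total


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact permutation enumeration when
    both groups have <= 8 observations, else the normal approximation
    with tie correction."""
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(a) <= 8 and len(b) <= 8:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def wilcoxon_de(X: ExpressionMatrix, condition: np.ndarray | None = None,
                pseudocount: float = 1.0) -> DEResult:
    """Two-sided Wilcoxon rank-sum DE per gene with BH adjustment.

    lnFC = ln[(mean(expm1(exposed)) + eps) / (mean(expm1(control)) + eps)]
    with eps = 1, computed on the de-logged normalized values.
    """
    if condition is None:
        condition = X.condition
    condition = np.asarray(condition, dtype=int)
    g0 = condition == 0
    g1 = condition == 1
    if not g0.any() or not g1.any():
        raise ValueError("both condition groups must be non-empty")
    V0, V1 = X.values[g0], X.values[g1]
    m0 = np.expm1(V0).mean(axis=0)
    m1 = np.expm1(V1).mean(axis=0)
    lnfc = np.log((m1 + pseudocount) / (m0 + pseudocount))
    pvals = np.array([_ranksum_p(V1[:, j], V0[:, j]) for j in range(X.n_genes)])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return DEResult(
        genes=X.gene_ids.copy(),
        lnfc=lnfc,
        p_value=pvals,
        p_adjusted=np.maximum(padj, pvals),
        mean_control=m0,
        mean_exposed=m1,
    )


def de_significant(de: DEResult, p_max: float = 0.05, lnfc_min: float = 0.1):
    """Genes with raw p < p_max and |lnFC| > lnfc_min (strict), split into
    up- and down-regulated lists.  Returns (up, down)."""
    sig = (de.p_value < p_max) & (np.abs(de.lnfc) > lnfc_min)
    up = de.genes[sig & (de.lnfc > 0)]
    down = de.genes[sig & (de.lnfc < 0)]
    return list(up), list(down)


def gene_condition_auc(values: np.ndarray, condition: np.ndarray) -> float:
    """AUC = P(exposed value > control value) + 0.5 P(equal), via ranks.

    Equals the Mann-Whitney U statistic divided by n0*n1.  Constant input
    returns 0.5.
    """
    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition, dtype=int)
    v0 = values[condition == 0]
    v1 = values[condition == 1]
    if len(v0) == 0 or len(v1) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        return 0.5
    ranks = stats.rankdata(values)
    u1 = ranks[condition == 1].sum() - len(v1) * (len(v1) + 1) / 2
    return float(u1 / (len(v0) * len(v1)))


def read_gmt(path) -> dict:
    """Read a GMT pathway collection: name, description, genes per line."""
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return pathways


def fisher_enrichment(
    hits, universe, pathways: dict, fdr_max: float = 0.10
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway with BH
    q-values; rows with q < fdr_max are flagged significant."""
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, genes in pathways.items():
        pw = genes & universe
        overlap = len(hits & pw)
        # P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|pw|, n=|hits|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(pw), len(hits)))
        rows.append({"pathway": name, "size": len(pw), "overlap": overlap, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["pathway", "size", "overlap", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["significant"] = table["q"] < fdr_max
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table
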