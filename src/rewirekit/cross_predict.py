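"""Cross-cell-type / cross-dataset gene-set transfer prediction.

A selected factor's gene set (genes + allocation weights) learned in a
source cell type or dataset is projected onto a target matrix as an
allocation-weighted sum of z-scored expression.  Whether the resulting
per-cell score separates the exposure groups is tested by AUC and a
two-sided Mann-Whitney test; the factor's top members are also exported
as a Pearson correlation network with an |r| >= 0.1 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_data import ExpressionMatrix, GeneNetwork
from .preprocess import _ranksum_p, gene_condition_auc

logger = logging.getLogger("rewirekit")


@dataclass
class FactorGeneSet:
    """A transferable factor signature: genes with allocation weights."""

    factor_id: str
    genes: np.ndarray
    weights: np.ndarray
    source_dataset: str = ""
    source_cell_type: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must align")
        if len(set(map(str, self.genes))) != len(self.genes):
            raise ValueError("gene set contains duplicates")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def project_score(
    gene_set: FactorGeneSet, X_target: ExpressionMatrix, weighted: bool = True
) -> tuple[np.ndarray, float]:
    """Score target cells with a transferred gene set.

    score(cell) = sum_g w_g * z_g(cell) over genes measured in the
    target (matched case-insensitively); ``weighted=False`` uses the
    unweighted mean of z-scores.  Returns (scores, coverage fraction).
    """
    lookup = {str(g).lower(): j for j, g in enumerate(X_target.gene_ids)}
    cols, w = [], []
    missing = []
    for g, wg in zip(gene_set.genes, gene_set.weights):
        j = lookup.get(str(g).lower())
        if j is None:
            missing.append(str(g))
        else:
            cols.append(j)
            w.append(wg)
    if not cols:
        raise ValueError(
            f"no gene of set {gene_set.factor_id!r} measured in target; "
            f"missing: {', '.join(missing[:10])}"
        )
    V = X_target.values[:, cols]
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd[sd == 0] = 1.0
    Zg = (V - mu) / sd
    w = np.asarray(w)
    scores = Zg @ w if weighted else Zg.mean(axis=1)
    coverage = len(cols) / len(gene_set.genes)
    if missing:
        logger.info(
            "project_score: %d/%d genes unmeasured in target", len(missing), len(gene_set.genes)
        )
    return scores, float(coverage)


def predict_group(score: np.ndarray, condition: np.ndarray) -> tuple[float, float]:
    """(AUC, two-sided Mann-Whitney p) for score vs exposure group."""
    score = np.asarray(score, dtype=float)
    condition = np.asarray(condition, dtype=int)
    s0 = score[condition == 0]
    s1 = score[condition == 1]
    if len(s0) == 0 or len(s1) == 0:
        raise ValueError("both exposure groups must be non-empty")
    auc = gene_condition_auc(score, condition)
    p = _ranksum_p(s1, s0)
    return float(auc), float(p)


def correlation_network(
    X: ExpressionMatrix,
    genes,
    cutoff: float = 0.1,
    signed: bool = False,
) -> GeneNetwork:
    """Pearson correlation network over the given genes.

    Edge (g, h) iff |r| >= cutoff (``signed=True`` requires r >= cutoff
    instead, dropping strong negative correlations); edge weight = r.
    Constant genes keep their node but gain no edges (warned).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("correlation_network needs at least 2 genes")
    idx = X.gene_index(genes)
    V = X.values[:, idx]
    sd = V.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "correlation_network: %d constant genes have no edges", int(constant.sum())
        )
    g = nx.Graph()
    for gene in genes:
        g.add_node(str(gene), role="marker")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V.T)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if constant[i] or constant[j]:
                continue
            r = float(R[i, j])
            keep = (r >= cutoff) if signed else (abs(r) >= cutoff)
            if keep:
                g.add_edge(str(genes[i]), str(genes[j]), weight=r)
    return GeneNetwork(graph=g)
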