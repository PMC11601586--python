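"""Nested factorization and protein-interaction subnetwork assembly.

After the unsupervised factor fit, every gene is exclusively attributed to
the factor where it carries maximal absolute weight.  The two largest
groups (empirically a housekeeping/homeostasis group and a functional-
differentiation group) are re-factorized independently; the strongest 50
features per nested factor become marker candidates; a median-of-nonzero
expression filter removes uniformly low-expressed candidates; and the
surviving markers seed an interactome subnetwork built with "OR" logic
(every interactome edge touching at least one marker is retained).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .io_data import ExpressionMatrix, GeneNetwork, match_symbols
from .love import DEFAULT_DELTA_GRID, DEFAULT_LAMBDA_GRID, LoveModel, fit_love

logger = logging.getLogger("rewirekit")


def definitive_assignment(A: np.ndarray) -> np.ndarray:
    """Exclusive gene -> factor map by maximal |weight|.

    Returns one factor index per gene; ties break to the lowest factor
    index; all-zero rows get -1 (unassigned).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValueError("allocation must be a genes x factors matrix")
    out = np.argmax(np.abs(A), axis=1)  # argmax takes the first maximum
    out[np.all(A == 0, axis=1)] = -1
    return out


def principal_split(model: LoveModel) -> tuple[np.ndarray, np.ndarray]:
    """Gene indices of the two largest factors after definitive assignment.

    Warns (does not fail) when more than two non-empty groups exist — the
    two-group structure is an empirical observation, not a guarantee.
    A single non-empty group is an error.
    """
    assign = definitive_assignment(model.allocation)
    sizes = np.bincount(assign[assign >= 0], minlength=model.K)
    nonempty = np.flatnonzero(sizes > 0)
    if len(nonempty) <= 1:
        raise ValueError("no split possible: a single factor holds all assigned genes")
    if len(nonempty) != 2:
        logger.warning(
            "principal_split: %d non-empty factors (sizes %s); taking the two largest",
            len(nonempty),
            sizes.tolist(),
        )
    order = sorted(nonempty, key=lambda f: (-sizes[f], f))
    f1, f2 = order[0], order[1]
    return np.flatnonzero(assign == f1), np.flatnonzero(assign == f2)


def nested_love(
    X,
    groups,
    delta_grid=DEFAULT_DELTA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    min_genes: int = 10,
) -> dict:
    """Fit the factor model independently on each gene group.

    ``groups`` maps a name to gene indices (or is a sequence, named by
    position).  Groups below ``min_genes`` are skipped with a warning.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    models = {}
    for name, idx in groups.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size < min_genes:
            logger.warning(
                "nested_love: skipping %s (%d genes < %d)", name, idx.size, min_genes
            )
            continue
        if isinstance(X, ExpressionMatrix):
            sub = X.subset_genes(idx)
        else:
            sub = np.asarray(X)[:, idx]
        models[name] = fit_love(
            sub, delta_grid=delta_grid, lambda_grid=lambda_grid, seed=seed
        )
    return models


def top_features(model: LoveModel, k: int = 50) -> dict:
    """Per factor, the k definitively assigned genes of largest |weight|.

    Smaller factors return all members; ties break by gene index.
    """
    assign = definitive_assignment(model.allocation)
    out = {}
    for f in range(model.K):
        members = np.flatnonzero(assign == f)
        order = sorted(members, key=lambda g: (-abs(model.allocation[g, f]), g))
        out[f] = [int(g) for g in order[:k]]
    return out


def _nonzero_median(col: np.ndarray) -> float:
    nz = col[col != 0]
    return float(np.median(nz)) if nz.size else -np.inf


def median_nonzero_filter(
    X_cond0: ExpressionMatrix,
    X_cond1: ExpressionMatrix,
    candidates,
    q: float = 0.25,
) -> list:
    """Drop candidates whose median-of-nonzero expression sits in the
    lowest q-quantile under BOTH conditions.

    Medians ignore zeros; a gene with no non-zero value in a condition
    ranks lowest there.  Quantile boundaries are inclusive on the low
    side (a gene exactly at the boundary counts as low).
    """
    candidates = list(candidates)
    if not candidates:
        return []
    low_masks = []
    for X in (X_cond0, X_cond1):
        idx = X.gene_index(candidates)
        med = np.array([_nonzero_median(X.values[:, j]) for j in idx])
        finite = med[np.isfinite(med)]
        if finite.size == 0:
            low_masks.append(np.ones(len(candidates), dtype=bool))
            continue
        thr = np.quantile(finite, q)
        low_masks.append(med <= thr)
    drop = low_masks[0] & low_masks[1]
    return [g for g, d in zip(candidates, drop) if not d]


def build_subnetwork(
    markers,
    interactome: nx.Graph,
    logic: str = "OR",
    X_group: ExpressionMatrix | None = None,
) -> GeneNetwork:
    """Interactome subnetwork seeded by marker genes.

    OR logic keeps every edge with at least one endpoint in the marker
    set; AND requires both endpoints.  Marker symbols are matched to
    interactome nodes case-insensitively.  Node roles are marker /
    interactor; ``intensity`` is the mean expression across the group's
    cells for genes measured in ``X_group``.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("markers must be non-empty")
    if logic not in ("OR", "AND"):
        raise ValueError(f"logic must be OR or AND, got {logic!r}")
    mapping = match_symbols(markers, interactome)
    marker_nodes = set(mapping.values())
    g = nx.Graph()
    if not marker_nodes:
        logger.warning("build_subnetwork: no marker matches any interactome node")
        return GeneNetwork(graph=g)
    for node in marker_nodes:
        g.add_node(node, role="marker")
    for a, b in interactome.edges():
        hits = (a in marker_nodes) + (b in marker_nodes)
        keep = hits >= 1 if logic == "OR" else hits == 2
        if keep:
            for n in (a, b):
                if n not in g:
                    g.add_node(n, role="interactor")
            g.add_edge(a, b)
    if X_group is not None:
        expr_lookup = {str(gid).lower(): j for j, gid in enumerate(X_group.gene_ids)}
        means = X_group.values.mean(axis=0)
        for node in g.nodes:
            j = expr_lookup.get(str(node).lower())
            if j is not None:
                g.nodes[node]["intensity"] = float(means[j])
    return GeneNetwork(graph=g)
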