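"""Core data containers and file I/O.

The pipeline's universal input is a cells x genes expression matrix with
per-cell annotations (binary exposure condition, cell type, sample id,
dataset tag).  Matrices are read from Matrix Market sparse triplets or
delimited dense tables; the undirected protein-protein interactome is a
two-column edge list of gene symbols; networks are exported as GraphML
plus a SIF edge list with a node-attribute table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("rewirekit")

ANNOTATION_COLUMNS = ("cell_id", "condition", "cell_type", "sample_id")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values plus per-cell annotations.

    ``values`` holds raw counts or normalized units; ``normalized`` flags
    which.  Gene-wise statistics are always computed over the cell axis
    (axis 0).
    """

    values: np.ndarray  # cells x genes, nonnegative, finite
    gene_ids: np.ndarray  # unique strings
    cell_ids: np.ndarray  # unique strings
    condition: np.ndarray  # per-cell 0 (control/air) or 1 (exposed/smoke)
    cell_type: np.ndarray  # per-cell categorical
    sample_id: np.ndarray  # per-cell categorical (mouse/donor)
    dataset_tag: str = "dataset"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.condition = np.asarray(self.condition, dtype=int)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        n_cells, n_genes = self.values.shape
        for name, arr, n in (
            ("gene_ids", self.gene_ids, n_genes),
            ("cell_ids", self.cell_ids, n_cells),
            ("condition", self.condition, n_cells),
            ("cell_type", self.cell_type, n_cells),
            ("sample_id", self.sample_id, n_cells),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} entries, expected {n}")
        for name, arr in (("gene_ids", self.gene_ids), ("cell_ids", self.cell_ids)):
            ids, counts = np.unique(arr.astype(str), return_counts=True)
            dups = ids[counts > 1]
            if dups.size:
                raise ValueError(f"duplicate {name}: {', '.join(map(str, dups[:10]))}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values contain negative entries")
        if not np.isin(self.condition, (0, 1)).all():
            raise ValueError("condition labels must be 0 or 1")

    # -- convenience -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            cell_ids=self.cell_ids[mask],
            condition=self.condition[mask],
            cell_type=self.cell_type[mask],
            sample_id=self.sample_id[mask],
        )

    def subset_genes(self, mask_or_index: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_index)
        return replace(
            self, values=self.values[:, idx], gene_ids=self.gene_ids[idx]
        )

    def gene_index(self, genes) -> np.ndarray:
        lookup = {str(g): i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if str(g) not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(map(str, missing[:10]))}")
        return np.array([lookup[str(g)] for g in genes], dtype=int)

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(
            {
                "condition": self.condition,
                "cell_type": self.cell_type.astype(str),
                "sample_id": self.sample_id.astype(str),
            },
            index=self.cell_ids.astype(str),
        )
        var = pd.DataFrame(index=self.gene_ids.astype(str))
        ad = anndata.AnnData(X=self.values.copy(), obs=obs, var=var)
        ad.uns["dataset_tag"] = self.dataset_tag
        ad.uns["normalized"] = self.normalized
        return ad

    @classmethod
    def from_anndata(cls, ad) -> "ExpressionMatrix":
        X = ad.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        return cls(
            values=np.asarray(X, dtype=float),
            gene_ids=ad.var_names.to_numpy(),
            cell_ids=ad.obs_names.to_numpy(),
            condition=ad.obs["condition"].to_numpy(),
            cell_type=ad.obs["cell_type"].to_numpy(),
            sample_id=ad.obs["sample_id"].to_numpy(),
            dataset_tag=str(ad.uns.get("dataset_tag", "dataset")),
            normalized=bool(ad.uns.get("normalized", False)),
        )


@dataclass
class GeneNetwork:
    """Undirected gene network with marker/interactor roles.

    Node attributes: ``role`` in {"marker", "interactor"}; ``intensity`` =
    mean normalized expression across the cells of the group the network
    was built for (absent for unmeasured interactors).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            role = data.get("role")
            if role not in ("marker", "interactor"):
                raise ValueError(f"node {node} has invalid role {role!r}")
            if "intensity" in data and data["intensity"] < 0:
                raise ValueError(f"node {node} has negative intensity")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# -- expression I/O --------------------------------------------------------


def _read_annotations(path, n_cells: int) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    if len(ann) != n_cells:
        raise ValueError(
            f"annotation rows ({len(ann)}) do not match cell count ({n_cells})"
        )
    return ann


def read_expression(
    path,
    format: str = "matrix-market-triplet",
    annotations=None,
    orientation: str = "cells-by-genes",
    gene_ids=None,
    dataset_tag: str = "dataset",
    normalized: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix plus its per-cell annotation table.

    ``orientation`` declares the on-disk layout; the returned matrix is
    always cells x genes.  For the Matrix Market format gene ids come from
    ``gene_ids`` (a file of one id per line) or are generated.
    """
    if format == "matrix-market-triplet":
        mat = scipy.io.mmread(str(path))
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if orientation == "genes-by-cells":
            values = values.T
        elif orientation != "cells-by-genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        if gene_ids is not None:
            genes = np.loadtxt(str(gene_ids), dtype=str, ndmin=1).astype(object)
        else:
            genes = np.array([f"g{j}" for j in range(values.shape[1])], dtype=object)
    elif format == "delimited-table":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "genes-by-cells":
            table = table.T
        values = table.to_numpy(dtype=float)
        genes = table.columns.to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    if annotations is None:
        raise ValueError("an annotation file is required")
    ann = _read_annotations(annotations, values.shape[0])
    return ExpressionMatrix(
        values=values,
        gene_ids=genes,
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        condition=ann["condition"].astype(int).to_numpy(),
        cell_type=ann["cell_type"].to_numpy(dtype=object),
        sample_id=ann["sample_id"].to_numpy(dtype=object),
        dataset_tag=dataset_tag,
        normalized=normalized,
    )


def write_expression(X: ExpressionMatrix, matrix_path, annotations_path, genes_path=None):
    """Write a matrix as Matrix Market triplets plus a TSV annotation table."""
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(X.values))
    pd.DataFrame(
        {
            "cell_id": X.cell_ids.astype(str),
            "condition": X.condition,
            "cell_type": X.cell_type.astype(str),
            "sample_id": X.sample_id.astype(str),
        }
    ).to_csv(annotations_path, sep="\t", index=False)
    if genes_path is not None:
        Path(genes_path).write_text("\n".join(map(str, X.gene_ids)) + "\n")


# -- interactome I/O -------------------------------------------------------


def read_interactome(path) -> nx.Graph:
    """Read a two-column edge list into a simple undirected graph.

    Self-loops and duplicate (including reversed) edges are dropped with a
    logged count.  An empty file is an error.
    """
    edges_raw = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line.rstrip()!r}")
            edges_raw.append((parts[0], parts[1]))
    if not edges_raw:
        raise ValueError(f"interactome file {path} contains no edges")

    g = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b in edges_raw:
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        logger.info(
            "read_interactome: dropped %d self-loops and %d duplicate edges",
            n_self,
            n_dup,
        )
    return g


def match_symbols(genes, interactome: nx.Graph) -> dict:
    """Case-insensitive mapping from gene ids to interactome node names.

    Returns {gene_id: node_name} for matched symbols; unmatched symbols
    are reported to the log (mouse/human case conventions differ).
    """
    by_lower = {}
    for node in interactome.nodes:
        by_lower.setdefault(str(node).lower(), node)
    mapping = {}
    unmatched = []
    for g in genes:
        node = by_lower.get(str(g).lower())
        if node is None:
            unmatched.append(str(g))
        else:
            mapping[g] = node
    if unmatched:
        logger.info(
            "match_symbols: %d/%d symbols not in interactome (e.g. %s)",
            len(unmatched),
            len(mapping) + len(unmatched),
            ", ".join(unmatched[:5]),
        )
    return mapping


# -- network export --------------------------------------------------------


def write_network(net: GeneNetwork, path_prefix) -> None:
    """Write a network as GraphML, SIF, and a node-attribute TSV.

    ``path_prefix`` gets extensions .graphml, .sif and .nodes.tsv.  SIF
    carries edges only; roles and intensities live in GraphML and the TSV.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if net.n_nodes == 0:
        logger.warning("write_network: exporting an empty network to %s", prefix)
    nx.write_graphml(net.graph, str(prefix) + ".graphml")
    with open(str(prefix) + ".sif", "w") as fh:
        for a, b in sorted(map(sorted, net.graph.edges())):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(nx.isolates(net.graph)):
            fh.write(f"{node}\n")
    rows = []
    for node, data in sorted(net.graph.nodes(data=True)):
        rows.append(
            {
                "gene": node,
                "role": data.get("role", ""),
                "intensity": data.get("intensity", np.nan),
            }
        )
    pd.DataFrame(rows, columns=["gene", "role", "intensity"]).to_csv(
        str(prefix) + ".nodes.tsv", sep="\t", index=False
    )


def read_network(path_prefix) -> GeneNetwork:
    """Read back a GraphML export (round-trip partner of write_network)."""
    g = nx.read_graphml(str(Path(path_prefix)) + ".graphml")
    return GeneNetwork(graph=nx.Graph(g))
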