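"""End-to-end orchestration of the analysis graph.

The unsupervised path runs separately on the control (air) and exposed
(smoke) cells of each cell type: QC -> sparsity filter -> normalization
-> factor fit -> principal split -> nested factor fit -> top-feature
extraction -> median-of-nonzero filter -> OR-logic interactome
subnetwork.  The supervised path pools conditions per cell type, fits
the factor model, runs multistage knockoff selection with interaction
search and CV/permutation significance, and finally transfers each
selected factor's gene set across cell types and datasets, reporting
AUC and Mann-Whitney p per transfer.  Every stage that consumes
randomness records its derived seed in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import networks as net
from . import preprocess as pp
from . import slide as sl
from .config import PipelineConfig
from .cross_predict import FactorGeneSet, predict_group, project_score
from .io_data import ExpressionMatrix, write_network
from .love import fit_love

logger = logging.getLogger("rewirekit")


def derive_seed(master: int, *parts) -> int:
    """Deterministic stage seed from the master seed and a stage tag."""
    tag = "/".join(map(str, parts)).encode()
    return (int(master) * 2654435761 + zlib.crc32(tag)) % (2**31)


@dataclass
class RunManifest:
    """Stage-by-stage record of a run: parameters, seeds, output checksums."""

    stages: list = field(default_factory=list)

    def add(self, name: str, params: dict | None = None, seed: int | None = None,
            outputs: dict | None = None, warnings: list | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "params": params or {},
                "seed": seed,
                "outputs": outputs or {},
                "warnings": warnings or [],
            }
        )

    def checksum(self, path) -> str:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        return h

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.stages, indent=2, default=str))


def _prepare(X: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    """QC (optional) -> sparsity filter -> per-cell log normalization."""
    qc = config["qc"]
    if qc.get("enabled", True):
        X = pp.qc_filter_cells(
            X,
            min_genes=qc["min_genes"],
            max_genes=qc["max_genes"],
            max_mito_frac=qc["max_mito_frac"],
            mito_prefix=qc["mito_prefix"],
        )
    X = pp.sparsity_filter(
        X,
        gene_zero_max=config["sparsity"]["gene_zero_max"],
        cell_zero_max=config["sparsity"]["cell_zero_max"],
    )
    return pp.normalize_log(X, scale=config["normalize"]["scale"])


def run_unsupervised(
    X: ExpressionMatrix,
    interactome,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> tuple[dict, RunManifest]:
    """Per (cell type x condition) unsupervised chain; returns networks,
    marker tables and factor counts plus the run manifest."""
    config = config or PipelineConfig()
    manifest = RunManifest()
    manifest.add("config", params={"seed": config.seed})
    love_cfg = config["love"]
    net_cfg = config["networks"]
    results = {}
    for ct in np.unique(X.cell_type.astype(str)):
        ct_mask = X.cell_type.astype(str) == ct
        # both-condition normalized matrices for the median filter
        prepared = {}
        for cond in (0, 1):
            sub = X.subset_cells(ct_mask & (X.condition == cond))
            if sub.n_cells == 0:
                raise ValueError(f"no cells for cell type {ct!r}, condition {cond}")
            prepared[cond] = _prepare(sub, config)
        for cond in (0, 1):
            Xn = prepared[cond]
            seed = derive_seed(config.seed, "love", ct, cond)
            model = fit_love(
                Xn,
                delta_grid=tuple(love_cfg["delta_grid"]),
                lambda_grid=tuple(love_cfg["lambda_grid"]),
                seed=seed,
                n_repeats=love_cfg["n_repeats"],
                allow_singletons=love_cfg["allow_singletons"],
            )
            manifest.add(
                "love", params={"cell_type": ct, "condition": cond,
                                "delta": model.delta, "lambda": model.lam,
                                "K": model.K}, seed=seed,
            )
            g1, g2 = net.principal_split(model)
            nested = net.nested_love(
                Xn,
                {"principal1": g1, "principal2": g2},
                delta_grid=tuple(love_cfg["delta_grid"]),
                lambda_grid=tuple(love_cfg["lambda_grid"]),
                seed=derive_seed(config.seed, "nested", ct, cond),
                min_genes=net_cfg["nested_min_genes"],
            )
            markers: list = []
            for name, m in nested.items():
                for f, glist in net.top_features(m, k=net_cfg["top_k"]).items():
                    markers.extend(str(m.gene_ids[g]) for g in glist)
            markers = sorted(set(markers))
            both = set(map(str, prepared[0].gene_ids)) & set(map(str, prepared[1].gene_ids))
            kept = net.median_nonzero_filter(
                prepared[0], prepared[1],
                [g for g in markers if g in both],
                q=net_cfg["quantile"],
            )
            network = net.build_subnetwork(
                kept, interactome, logic=net_cfg["logic"], X_group=Xn
            ) if kept else net.build_subnetwork(markers, interactome,
                                                logic=net_cfg["logic"], X_group=Xn)
            outputs = {}
            if out_dir is not None:
                prefix = Path(out_dir) / "networks" / f"{ct}_cond{cond}"
                write_network(network, prefix)
                for ext in (".graphml", ".sif", ".nodes.tsv"):
                    f = str(prefix) + ext
                    outputs[f] = manifest.checksum(f)
            manifest.add(
                "network",
                params={"cell_type": ct, "condition": cond,
                        "n_markers": len(kept), "n_nodes": network.n_nodes,
                        "n_edges": network.n_edges},
                outputs=outputs,
            )
            results[(ct, cond)] = {
                "model": model,
                "nested": nested,
                "markers": kept,
                "network": network,
                "K": model.K,
            }
    if out_dir is not None:
        config.write_provenance(out_dir)
        manifest.to_json(Path(out_dir) / "manifest.json")
    return results, manifest


def run_supervised(
    datasets: dict,
    config: PipelineConfig | None = None,
    out_dir=None,
    cross_predict: bool = True,
) -> tuple[dict, RunManifest]:
    """Per cell type: pooled factor fit, multistage knockoff selection,
    interaction search, CV significance and member tables; then the
    cross-cell-type / cross-dataset gene-set transfer grid."""
    config = config or PipelineConfig()
    manifest = RunManifest()
    manifest.add("config", params={"seed": config.seed})
    love_cfg, slide_cfg, cp_cfg = config["love"], config["slide"], config["crosspred"]

    per_group: dict = {}
    gene_sets: dict = {}
    for tag, X in datasets.items():
        for ct in np.unique(X.cell_type.astype(str)):
            sub = X.subset_cells(X.cell_type.astype(str) == ct)
            Xn = _prepare(sub, config)
            seed = derive_seed(config.seed, "love", tag, ct)
            model = fit_love(
                Xn,
                delta_grid=tuple(love_cfg["delta_grid"]),
                lambda_grid=tuple(love_cfg["lambda_grid"]),
                seed=seed,
                n_repeats=love_cfg["n_repeats"],
                allow_singletons=love_cfg["allow_singletons"],
            )
            Z = sl.estimate_latent_scores(Xn, model)
            y = Xn.condition
            ms_seed = derive_seed(config.seed, "multistage", tag, ct)
            marginals, freq = sl.multistage_select(
                Z, y,
                iterations=slide_cfg["iterations"],
                spec=slide_cfg["spec"],
                fdr_level=slide_cfg["fdr_level"],
                seed=ms_seed,
                w_method=slide_cfg["w_method"],
            )
            int_seed = derive_seed(config.seed, "interaction", tag, ct)
            pairs, pair_freq = sl.interaction_search(
                Z, y, marginals,
                iterations=slide_cfg["iterations"],
                spec=slide_cfg["spec"],
                fdr_level=slide_cfg["fdr_level"],
                seed=int_seed,
                w_method=slide_cfg["w_method"],
            )
            manifest.add(
                "multistage",
                params={"dataset": tag, "cell_type": ct,
                        "marginals": marginals, "interactions": pairs},
                seed=ms_seed,
            )
            cv_table, perm_p = (None, None)
            members = None
            if marginals:
                inter_cols = (
                    np.column_stack([Z[:, j] * Z[:, k] for j, k in pairs])
                    if pairs else None
                )
                cv_table, perm_p = sl.cv_significance(
                    Z[:, marginals], y,
                    folds=slide_cfg["folds"],
                    replicates=slide_cfg["replicates"],
                    n_perm=slide_cfg["n_perm"],
                    seed=derive_seed(config.seed, "cv", tag, ct),
                    interactions=inter_cols,
                )
                members = sl.factor_member_table(model, Xn, y, marginals)
                assign = net.definitive_assignment(model.allocation)
                for f in marginals:
                    gidx = np.flatnonzero(assign == f)
                    gene_sets[(tag, ct, f)] = FactorGeneSet(
                        factor_id=f"{tag}:{ct}:F{f}",
                        genes=model.gene_ids[gidx],
                        weights=model.allocation[gidx, f],
                        source_dataset=tag,
                        source_cell_type=ct,
                    )
            selection = sl.SlideSelection(
                marginal_ids=marginals,
                marginal_freq=freq,
                interaction_pairs=pairs,
                interaction_freq=pair_freq,
                spec=slide_cfg["spec"],
                iterations=slide_cfg["iterations"],
                fdr_level=slide_cfg["fdr_level"],
                cv_auc=cv_table,
                permutation_p=perm_p,
            )
            per_group[(tag, ct)] = {
                "model": model,
                "scores": Z,
                "normalized": Xn,
                "selection": selection,
                "members": members,
            }

    transfers = []
    if cross_predict:
        if not gene_sets:
            manifest.add("crosspred", params={"status": "skipped: empty selection"})
            logger.warning("run_supervised: no selected factors; cross-prediction skipped")
        for (tag, ct, f), gs in gene_sets.items():
            for (tag2, ct2), group in per_group.items():
                if (tag2, ct2) == (tag, ct):
                    continue
                target = group["normalized"]
                try:
                    score, coverage = project_score(
                        gs, target, weighted=cp_cfg["weighted"]
                    )
                except ValueError as exc:
                    logger.warning("transfer %s -> (%s, %s) failed: %s",
                                   gs.factor_id, tag2, ct2, exc)
                    continue
                auc, p = predict_group(score, target.condition)
                transfers.append(
                    {
                        "source": gs.factor_id,
                        "target_dataset": tag2,
                        "target_cell_type": ct2,
                        "auc": auc,
                        "mann_whitney_p": p,
                        "coverage": coverage,
                    }
                )
        manifest.add("crosspred", params={"n_transfers": len(transfers)})
    if out_dir is not None:
        config.write_provenance(out_dir)
        manifest.to_json(Path(out_dir) / "manifest.json")
    return {"groups": per_group, "gene_sets": gene_sets, "transfers": transfers}, manifest
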