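"""Run configuration: every stage parameter with documented defaults.

A run's resolved configuration (defaults merged with user overrides) and
its master seed are written next to the outputs so stochastic stages —
in particular the knockoff iterations — are exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("rewirekit")


def _default_stages() -> dict:
    return {
        "qc": {
            "min_genes": 200,
            "max_genes": 3000,
            "max_mito_frac": 0.25,
            "mito_prefix": "mt-",
            "enabled": True,
        },
        "normalize": {"scale": 1e4},
        "sparsity": {"gene_zero_max": 0.995, "cell_zero_max": 0.90},
        "de": {"p_max": 0.05, "lnfc_min": 0.1},
        "enrichment": {"fdr_max": 0.10},
        "love": {
            "delta_grid": [0.02, 0.05, 0.08, 0.12, 0.16, 0.20],
            "lambda_grid": [0.0, 0.01, 0.05, 0.1],
            "n_repeats": 5,
            "allow_singletons": False,
        },
        "networks": {
            "top_k": 50,
            "quantile": 0.25,
            "logic": "OR",
            "nested_min_genes": 10,
        },
        "slide": {
            "iterations": 300,
            "spec": 0.2,
            "fdr_level": 0.1,
            "folds": 10,
            "replicates": 20,
            "n_perm": 100,
            "w_method": "lasso",
        },
        "crosspred": {"correlation_cutoff": 0.1, "weighted": True},
    }


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: dict = field(default_factory=_default_stages)

    def __post_init__(self) -> None:
        defaults = _default_stages()
        for stage, params in defaults.items():
            mine = self.stages.setdefault(stage, {})
            for key, value in params.items():
                mine.setdefault(key, value)

    def __getitem__(self, stage: str) -> dict:
        return self.stages[stage]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(seed=int(raw.get("seed", 0)), stages=raw.get("stages", {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def write_provenance(self, out_dir) -> None:
        """Record the resolved configuration and seed beside the outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_yaml(out / "resolved_config.yaml")
        (out / "seed.json").write_text(json.dumps({"master_seed": self.seed}))
        logger.info("run configured with master seed %d", self.seed)
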