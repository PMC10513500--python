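"""Run configuration: one document holding every stage's parameters.

All randomness flows from a single root seed; each stage derives its own
seed as ``root_seed + stage_offset`` so stages stay reproducible when run
in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "STAGE_SEED_OFFSETS"]

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "integrate": 11,
    "select": 23,
    "balance": 37,
    "split": 41,
    "train": 53,
    "explain": 67,
    "survival": 79,
}


@dataclass
class RunConfig:
    """Workflow parameters with the package defaults."""

    # synthetic cohort
    class_counts: dict = field(
        default_factory=lambda: {"WNT": 70, "SHH": 200, "Group3": 150, "Group4": 343}
    )
    n_probes: int = 1000
    n_informative: int = 100
    delta: float = 0.4
    noise_sd: float = 0.05
    n_genes: int = 200
    coupling: float = 0.8
    censor_rate: float = 0.3
    # integration
    k_neighbors: int = 51
    mu: float = 0.85
    iterations: int = 120
    clusters: int = 4
    # feature selection
    n_top: int = 5000
    n_select: int = 399
    # balancing
    smote_k: int = 5
    perc_over: int = 200
    oversample_before_split: bool = False
    # splitting / CV
    train_frac: float = 0.8
    k_folds: int = 10
    # models
    families: tuple = ("RF", "SVM", "KNN", "NB", "XGB", "LDA", "ANN")
    # network
    r_threshold: float = 0.6
    min_degree: int = 2
    # survival
    min_group_frac: float = 0.1
    # global
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS[stage]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config document; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if isinstance(cfg.families, list):
        cfg.families = tuple(cfg.families)
    return cfg


def dump_config(cfg: RunConfig) -> str:
    data = asdict(cfg)
    data["families"] = list(data["families"])
    return yaml.safe_dump(data, sort_keys=True)
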