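"""Pipeline configuration: one YAML document drives every stage.

The defaults encode the study's published thresholds: stratification at
p < 0.05 with 10,000 resamples, edgewise FDR at 0.05 with 5,000
permutations, Bonferroni over 37 comparisons, robust-regression feature
selection at p < 0.001, 1,000 scrambled-label draws for the accuracy
null.  Every stochastic stage has an explicit seed derived from the
single top-level seed, so a config fully determines a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    # data sources: either synthetic generation or paths to input files
    synthetic: bool = True
    cohort_params: dict = field(default_factory=dict)
    ratings_csv: str | None = None
    visits_csv: str | None = None
    questionnaires_csv: str | None = None
    volumes_csv: str | None = None
    matrices_dir: str | None = None
    node_mask: str | None = None
    # thresholds (published defaults)
    stratify_alpha: float = 0.05
    stratify_n_perm: int = 10_000
    fdr_alpha: float = 0.05
    edgewise_n_perm: int = 5_000
    bonferroni_m: int = 37
    feature_p_thresh: float = 0.001
    null_label_draws: int = 1_000
    # community detection
    louvain_reps: int = 100
    louvain_resolution: float = 1.0
    agree_threshold: float = 0.5
    # cross-validation
    inner_folds: int = 10
    consensus_report_threshold: float = 0.84
    # stage toggles (prediction stages are the expensive ones)
    stages: list[str] = field(
        default_factory=lambda: ["stratify", "screen", "network", "volumes"]
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("stratify_alpha", "fdr_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable digest of the full config; changes iff the config does."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
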