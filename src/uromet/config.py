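"""Pipeline configuration: every tunable threshold in one place.

Defaults mirror the study protocol: QC CV cutoff 30%, KNN k = 10% of the
group size, the VIP>1 / p<0.05 / FC<0.8-or->1.25 screen, 200 permutations,
200 resampling iterations, 10 key metabolites, 7-fold cross-validation and
a 70/30 resampling split. A YAML file with any subset of these keys
overrides the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .io import DEFAULT_SEED


@dataclass
class PipelineConfig:
    cv_threshold: float = 0.30
    knn_fraction: float = 0.10
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    fc_low: float = 0.8
    fc_high: float = 1.25
    n_permutations: int = 200
    n_resamples: int = 200
    n_key_metabolites: int = 10
    cv_folds: int = 7
    test_fraction: float = 0.30
    n_ortho: int = 1
    log_transform: bool = True
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0 < self.knn_fraction <= 1:
            raise ValueError("knn_fraction must be in (0, 1]")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.fc_low >= self.fc_high:
            raise ValueError("fc_low must be below fc_high")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
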