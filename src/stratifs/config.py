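"""Run configuration and seed management.

A single master seed deterministically spawns per-stage child seeds
(simulation, hold-out split, mitigation, bootstraps, CV, model fits) so
each stage is individually reproducible and two runs with the same
config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .criteria import CRITERIA
from .info import BinScheme

MODELS = ("LR", "AdaBoost", "XGBoost", "RF", "KNN", "DT", "NB")

#: stable stage identifiers for child-seed derivation
_STAGES = {
    "simulate": 1,
    "holdout": 2,
    "mitigation": 3,
    "bootstrap": 4,
    "cv": 5,
    "model": 6,
    "permute": 7,
}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    ss = np.random.SeedSequence([int(master_seed), _STAGES[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on besides the data."""

    bin_scheme: BinScheme = field(default_factory=BinScheme)
    B: int = 100  # bootstrap resamples per criterion
    K: int = 10  # top features retained per bootstrap
    feature_grid: tuple = (1, 10, 20, 30, 40, 50, 60, 70, "all")
    criteria: tuple = CRITERIA
    models: tuple = MODELS
    outer_folds: int = 5
    inner_folds: int = 2
    holdout_frac: float = 0.2
    master_seed: int = 0
    mifs_beta: float = 1.0
    mitigation_mode: str = "joint"
    include_no_fs_arm: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.holdout_frac < 1:
            raise ValueError("holdout_frac must be in (0, 1)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("CV folds must be >= 2")
        bad = [c for c in self.criteria if c not in CRITERIA]
        if bad:
            raise ValueError(f"unknown criteria {bad}")
        bad = [m for m in self.models if m not in MODELS]
        if bad:
            raise ValueError(f"unknown models {bad}")
        for n in self.feature_grid:
            if n != "all" and (not isinstance(n, int) or n < 1):
                raise ValueError(f"feature_grid entries must be positive ints or 'all', got {n!r}")

    def resolve_feature_grid(self, p: int) -> list[int]:
        """Concrete feature counts for a p-feature dataset (deduplicated, sorted)."""
        out = sorted({p if n == "all" else n for n in self.feature_grid if n == "all" or n <= p})
        if not out:
            raise ValueError("feature grid empty after clipping to p")
        return out

    def seed(self, stage: str, index: int = 0) -> int:
        return stage_seed(self.master_seed, stage, index)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bin_scheme"] = {
            "dosage_cutpoint": self.bin_scheme.dosage_cutpoint,
            "pc_cutpoint": self.bin_scheme.pc_cutpoint,
            "aao_edges": list(self.bin_scheme.aao_edges),
        }
        d["feature_grid"] = list(self.feature_grid)
        d["criteria"] = list(self.criteria)
        d["models"] = list(self.models)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "bin_scheme" in d:
            bs = d["bin_scheme"]
            d["bin_scheme"] = BinScheme(
                dosage_cutpoint=bs.get("dosage_cutpoint", 1.0),
                pc_cutpoint=bs.get("pc_cutpoint", 0.0),
                aao_edges=tuple(bs.get("aao_edges", (20.0, 40.0, 60.0, 80.0, 100.0))),
            )
        for key in ("feature_grid", "criteria", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
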