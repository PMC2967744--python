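"""Run configuration: every numeric knob of the pipeline in one place.

Defaults are the published operating point of the workflow the package
implements: anchor gene lists at |rho| >= 0.4, per-dataset co-expression
graphs at |rho| >= 0.75, summary-graph edges supported by at least 4
datasets, dense modules at connectivity ratio r > 0.4, clinical edges at
Spearman rho >= 0.95 with at least 20 non-null pairs, categorical binning
capped at 8 bins, 20% sample holdout, and alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["RunConfig"]

_DOMAINS = {
    "anchor_rho": (0.0, 1.0),
    "graph_rho": (0.0, 1.0),
    "clinical_rho": (-1.0, 1.0),
    "holdout": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "min_r": (0.0, 1.0),
    "min_coherence": (0.0, 1.0),
}


@dataclass
class RunConfig:
    # correlation thresholds
    anchor_rho: float = 0.4
    graph_rho: float = 0.75
    clinical_rho: float = 0.95
    # graph mining
    min_support: int = 4
    min_r: float = 0.4
    min_size: int = 3
    min_coherence: float = 0.5
    # clinical binning / pairing
    min_pairs: int = 20
    max_cats: int = 8
    # phenotype association
    holdout: float = 0.2
    alpha: float = 0.05
    n_repeats: int = 50
    # constructive induction
    granularity_delta: int = 1
    max_intermediates: int = 1
    map_min_score: float = 0.2
    # randomness
    seed: int = 0
    # paths
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _DOMAINS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside its domain [{lo}, {hi}]")
        for name in ("min_support", "min_size", "min_pairs", "max_cats",
                     "n_repeats", "granularity_delta", "max_intermediates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
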