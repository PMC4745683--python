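"""Run configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclasses.dataclass
class AnalysisConfig:
    """All tunable thresholds, optimizer settings and seeds in one place.

    Defaults follow the study design: strict >1.5-fold up-regulation with a
    10% floor relative to time zero for the modelled set, inclusive
    >=1.5-fold for the down-regulated set, 2-fold census thresholds, Ward
    clustering into five activities, Pearson threshold 0.8 for the
    down-regulation waves, and the top 2000 differential genes as the
    ordination gradient.
    """

    # gene filters
    range_min: float = 1.5          # intensity units (non-log scale)
    up_fold: float = 1.5            # strict: "up-regulated by >50%"
    floor_frac: float = 0.1         # min x(t) >= floor_frac * x(0)
    down_fold: float = 1.5          # inclusive: "at least 1.5 fold"
    census_fold: float = 2.0        # expression census, strict
    decay_fold: float = 1.5         # degradation census, strict

    # affine error model sd = sd_a + sd_b * intensity
    sd_a: float = 1.0
    sd_b: float = 0.1

    # degradation-array normalization
    stable_frac: float = 0.25
    norm_tol: float = 1e-3
    norm_max_iter: int = 50

    # pair-fit optimizer
    n_starts: int = 3
    d_min: float = 1e-3             # 1/h; D = 0 makes the expression system singular
    d_max: float = 5.0              # 1/h
    bound_scale: float = 10.0       # B, S, x_d0 upper bound = scale * max intensity
    max_nfev: int = 600
    fit_tol: float = 1e-12

    # clustering
    k_clusters: int = 5
    ward_variant: str = "lw"        # "lw" (Lance-Williams on d) or "d"
    r_threshold: float = 0.8
    wave_min_size: int = 5
    wave_mode: str = "average"      # or "components"
    g_norm: str = "minmax"          # or "zscore"

    # constrained ordination
    cca_top_n: int = 2000
    contrib_top_m: int = 1000
    env_mode: str = "logratio"      # or "t"
    prior_df: float | None = None   # force d0 (None = estimate; inf = pooled)

    # plumbing
    seed: int = 0
    log2_input: bool = False

    def __post_init__(self) -> None:
        for name in (
            "range_min", "up_fold", "floor_frac", "down_fold",
            "census_fold", "decay_fold", "stable_frac", "norm_tol",
            "d_min", "d_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
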