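"""Gene-selection rules and fold-change censuses.

The modelled ("up-regulated") set requires all three of: expression range at
least ``range_min`` intensity units, up-regulation strictly above
``up_fold`` relative to time zero at some point, and never dropping below
``floor_frac`` of the time-zero value.  The down-regulated set uses an
inclusive >= ``down_fold`` drop.  Thresholds follow the wording: strict ">"
for up-regulation, inclusive for "at least"-style down-regulation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_ import TimeCourseMatrix

logger = logging.getLogger("txkinetics")

__all__ = [
    "FilterReport",
    "expression_range",
    "select_upregulated",
    "select_downregulated",
    "fold_change_census",
]


@dataclasses.dataclass
class FilterReport:
    selected: list[str]
    excluded: dict[str, list[str]]    # gene -> reasons
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        overlap = set(self.selected) & set(self.excluded)
        if overlap:
            raise ValueError(f"genes both selected and excluded: {sorted(overlap)[:3]}")


def expression_range(series: np.ndarray) -> float:
    """Range statistic R = max - min of an intensity series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.max() - x.min())


def select_upregulated(
    expr: TimeCourseMatrix,
    range_min: float = 1.5,
    up_fold: float = 1.5,
    floor_frac: float = 0.1,
) -> FilterReport:
    """Select the modelled set of up-regulated genes (three rules, all strict
    ">" for the fold rule, ">=" for range and floor)."""
    selected: list[str] = []
    excluded: dict[str, list[str]] = {}
    for g, x in zip(expr.gene_ids, expr.values):
        reasons = []
        if x[0] <= 0:
            reasons.append("nonpositive_baseline")
        else:
            if expression_range(x) < range_min:
                reasons.append("range")
            if not (x.max() / x[0] > up_fold):
                reasons.append("up_fold")
            if not (x.min() >= floor_frac * x[0]):
                reasons.append("floor")
        if reasons:
            excluded[g] = reasons
        else:
            selected.append(g)
    return FilterReport(
        selected, excluded,
        {"range_min": range_min, "up_fold": up_fold, "floor_frac": floor_frac},
    )


def select_downregulated(expr: TimeCourseMatrix, down_fold: float = 1.5) -> FilterReport:
    """Select genes down-regulated by at least ``down_fold`` at some point
    (inclusive: a dip to exactly x(0)/down_fold qualifies)."""
    selected: list[str] = []
    excluded: dict[str, list[str]] = {}
    for g, x in zip(expr.gene_ids, expr.values):
        if x[0] <= 0:
            excluded[g] = ["nonpositive_baseline"]
        elif x.min() / x[0] <= 1.0 / down_fold:
            selected.append(g)
        else:
            excluded[g] = ["down_fold"]
    return FilterReport(selected, excluded, {"down_fold": down_fold})


def fold_change_census(expr: TimeCourseMatrix, fold: float = 2.0) -> dict[str, np.ndarray]:
    """Per-time counts of genes changed more than ``fold`` (strict).

    Four count vectors: up/down, each vs time zero and vs the previous time
    point.  Genes with a zero anywhere are excluded with a warning.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    ok = np.all(expr.values > 0, axis=1)
    if not ok.all():
        logger.warning("fold_change_census: excluding %d genes with zero values",
                       int((~ok).sum()))
    X = expr.values[ok]
    n_t = len(expr.grid)
    out = {
        "times": expr.grid.array,
        "up_vs_t0": np.zeros(n_t, dtype=int),
        "down_vs_t0": np.zeros(n_t, dtype=int),
        "up_vs_prev": np.zeros(n_t, dtype=int),
        "down_vs_prev": np.zeros(n_t, dtype=int),
        "n_genes": int(X.shape[0]),
    }
    if X.shape[0]:
        out["up_vs_t0"] = (X / X[:, [0]] > fold).sum(axis=0)
        out["down_vs_t0"] = (X[:, [0]] / X > fold).sum(axis=0)
        out["up_vs_prev"][1:] = (X[:, 1:] / X[:, :-1] > fold).sum(axis=0)
        out["down_vs_prev"][1:] = (X[:, :-1] / X[:, 1:] > fold).sum(axis=0)
    return out
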