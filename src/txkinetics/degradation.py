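"""Normalization and empirical decay-rate estimation for shutoff arrays.

After actinomycin D arrests transcription, total RNA falls, so per-array
total-intensity normalization would bias decay rates toward zero.  Instead,
arrays are rescaled iteratively against the quartile of slowest-decaying
transcripts: scale, refit per-gene log-linear decay, redefine the stable
quartile, and re-center each array so the stable set's median log-ratio to
the t = 0 array is zero, until the factors stop moving.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_ import TimeCourseMatrix, TimeGrid

logger = logging.getLogger("txkinetics")

__all__ = [
    "NormalizationResult",
    "DecayEstimate",
    "normalize_degradation_arrays",
    "estimate_decay_rate",
    "estimate_decay_table",
    "decay_census",
]


@dataclasses.dataclass
class NormalizationResult:
    normalized: TimeCourseMatrix
    scale_factors: np.ndarray     # per-array multiplier; factor for t=0 is 1
    stable_set: list[str]         # gene ids used as the stability reference
    iterations: int
    converged: bool


@dataclasses.dataclass
class DecayEstimate:
    gene_id: str
    d_hat: float                  # 1/h, clamped at 0
    r2: float                     # fit quality in log space
    ok: bool = True


def _loglinear_rates(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vectorized OLS slope of log(x) on t; rows with non-positive x -> nan."""
    ok = np.all(values > 0, axis=1)
    slopes = np.full(values.shape[0], np.nan)
    if ok.any():
        y = np.log(values[ok])
        tc = t - t.mean()
        slopes[ok] = (y * tc).sum(axis=1) / (tc * tc).sum()
    return slopes


def normalize_degradation_arrays(
    raw: TimeCourseMatrix,
    *,
    stable_frac: float = 0.25,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> NormalizationResult:
    """Iterative stable-quartile median-ratio normalization.

    Deterministic given the input; invariant to gene order and to a global
    rescaling of all arrays by one constant (the t = 0 factor is pinned to 1).
    """
    if len(raw.grid) < 2:
        raise ValueError("need at least 2 arrays to normalize")
    if raw.n_genes < 20:
        raise ValueError("need at least 20 genes to define a stable set")
    keep = ~np.all(raw.values == 0, axis=1)
    if not keep.all():
        dropped = [g for g, k in zip(raw.gene_ids, keep) if not k]
        logger.warning("dropping %d all-zero gene rows: %s", len(dropped), dropped[:5])
    ids = [g for g, k in zip(raw.gene_ids, keep) if k]
    X = raw.values[keep]
    sd = raw.sd[keep]
    t = raw.grid.array
    n_arrays = len(raw.grid)

    factors = np.ones(n_arrays)
    converged = False
    iterations = 0
    stable_ids: list[str] = []
    positive = np.all(X > 0, axis=1)
    if not positive.any():
        raise ValueError("no genes with all-positive values; cannot normalize")
    for iterations in range(1, max_iter + 1):
        Xs = X * factors
        slopes = _loglinear_rates(Xs, t)
        d_hat = np.maximum(0.0, -slopes)
        order = np.argsort(d_hat, kind="stable")
        order = order[positive[order]]
        n_stable = max(1, int(round(stable_frac * len(order))))
        stable = order[:n_stable]
        stable_ids = sorted(ids[i] for i in stable)
        log_ratio = np.log(Xs[stable, 0:1]) - np.log(Xs[stable, :])
        update = np.exp(np.median(log_ratio, axis=0))
        factors = factors * update
        factors = factors / factors[0]
        if np.max(np.abs(update - 1.0)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("degradation normalization did not converge in %d iterations",
                       max_iter)
    normalized = TimeCourseMatrix(ids, X * factors, sd * factors, raw.grid)
    return NormalizationResult(normalized, factors, stable_ids, iterations, converged)


def estimate_decay_rate(series: np.ndarray, grid: TimeGrid,
                        gene_id: str = "") -> DecayEstimate:
    """Log-linear OLS decay rate; ``d_hat = max(0, -slope)``.

    Closed-form and robust at four points; used for initialization and QC
    (pair fitting re-estimates D).  Genes with any non-positive value are
    flagged rather than fitted.
    """
    x = np.asarray(series, dtype=float)
    t = grid.array
    if np.any(x <= 0):
        return DecayEstimate(gene_id, np.nan, np.nan, ok=False)
    y = np.log(x)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sstot = float(((y - y.mean()) ** 2).sum())
    ssres = float((resid**2).sum())
    r2 = 1.0 if sstot < 1e-30 else max(0.0, 1.0 - ssres / sstot)
    return DecayEstimate(gene_id, max(0.0, -float(slope)), r2)


def estimate_decay_table(deg: TimeCourseMatrix) -> dict[str, DecayEstimate]:
    """Per-gene decay estimates for a whole matrix."""
    return {
        g: estimate_decay_rate(deg.values[i], deg.grid, g)
        for i, g in enumerate(deg.gene_ids)
    }


def decay_census(deg: TimeCourseMatrix, fold: float = 1.5) -> dict[str, np.ndarray]:
    """Count transcripts decayed more than ``fold`` at each chase time.

    Returns, per time point, the number of genes with ``x(0)/x(t) > fold``
    (vs-baseline) and with ``x(t_prev)/x(t) > fold`` (transitions).  Genes
    with a zero anywhere are excluded with a warning.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    ok = np.all(deg.values > 0, axis=1)
    if not ok.all():
        logger.warning("decay_census: excluding %d genes with zero values",
                       int((~ok).sum()))
    X = deg.values[ok]
    n_t = len(deg.grid)
    vs_t0 = np.zeros(n_t, dtype=int)
    vs_prev = np.zeros(n_t, dtype=int)
    if X.shape[0]:
        vs_t0 = (X[:, [0]] / X > fold).sum(axis=0)
        vs_prev[1:] = (X[:, :-1] / X[:, 1:] > fold).sum(axis=0)
    return {"times": deg.grid.array, "vs_t0": np.asarray(vs_t0),
            "vs_prev": vs_prev, "n_genes": int(X.shape[0])}
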