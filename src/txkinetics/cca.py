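"""Staging samples along a differentiation gradient by constrained ordination.

Two reference populations (e.g. the start and end states of a
differentiation step, each with replicate profiles) define a per-gene
"environmental" variable — the log-ratio of the end to the start state over
the top differentially expressed genes, ranked by empirical-Bayes moderated
t p-values.  Experimental time-course samples are then scored by canonical
correspondence analysis: the gene x sample intensity table is treated as a
contingency table, standardized in the chi-square metric, projected (with
row-mass weights) onto the single gradient variable, and decomposed by SVD.
The constrained axis-1 column scores order the samples along the gradient;
the constrained inertia measures how much of the table's weighted variance
the gradient explains.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_ import TimeCourseMatrix

logger = logging.getLogger("txkinetics")

__all__ = [
    "ReferenceSet",
    "CCAGradient",
    "CCAScores",
    "moderated_t",
    "build_gradient",
    "cca_scores",
    "top_contributors",
]


@dataclasses.dataclass
class ReferenceSet:
    """Two labelled groups of replicate intensity profiles, shared genes."""

    gene_ids: list[str]
    start: np.ndarray          # genes x replicates, linear intensities > 0
    end: np.ndarray
    start_label: str = "start"
    end_label: str = "end"

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        n = len(self.gene_ids)
        if self.start.shape[0] != n or self.end.shape[0] != n:
            raise ValueError("reference groups must share the gene universe")
        if self.start_label == self.end_label:
            raise ValueError("group labels must be distinct")
        if np.any(self.start <= 0) or np.any(self.end <= 0):
            raise ValueError("reference intensities must be positive")


@dataclasses.dataclass
class CCAGradient:
    gene_ids: list[str]        # top-N genes, best p first
    values: np.ndarray         # per-gene environmental value (end - start log2)
    n: int


@dataclasses.dataclass
class CCAScores:
    sample_scores: np.ndarray      # constrained axis-1 score per sample
    total_inertia: float
    constrained_inertia: float
    gene_ids: list[str]
    gene_contributions: np.ndarray  # |row score| * row mass, constrained axis


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on the distribution of log sample variances.

    If z = log(s^2), then E[z] = log(s0^2) + psi(df/2) - log(df/2) -
    (psi(d0/2) - log(d0/2)) and Var[z] = psi'(df/2) + psi'(d0/2); solving
    the variance equation inverts the trigamma function.
    """
    ok = s2 > 1e-300
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1e-8
    z = np.log(s2[ok])
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        d0 = np.inf
        s02 = float(np.exp(np.mean(z) - special.polygamma(0, df / 2)
                           + np.log(df / 2)))
    else:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s02 = float(np.exp(
            np.mean(z)
            - special.polygamma(0, df / 2) + np.log(df / 2)
            + special.polygamma(0, half_d0) - np.log(half_d0)
        ))
    return d0, s02


def moderated_t(
    ref: ReferenceSet, prior_df: float | None = None
) -> dict[str, np.ndarray | float]:
    """Two-group moderated t with empirical-Bayes variance shrinkage.

    Works on log2 intensities.  The posterior variance is
    ``(d0*s0^2 + dg*s_g^2) / (d0 + dg)`` with the prior (d0, s0^2) estimated
    by moment matching on the log sample variances; p-values use the t
    distribution with d0 + dg degrees of freedom and are Benjamini-Hochberg
    adjusted.  ``prior_df`` overrides d0 (``inf`` collapses every gene's
    variance to the pooled prior s0^2).
    """
    n1, n2 = ref.start.shape[1], ref.end.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each reference group needs at least 2 replicates")
    a = np.log2(ref.start)
    b = np.log2(ref.end)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, s02 = _fit_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m2 - m1) / denom, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return {
        "gene_ids": list(ref.gene_ids),
        "log_fc": m2 - m1,
        "t": t,
        "p": p,
        "p_adj": p_adj,
        "d0": d0,
        "s02": s02,
        "df_total": df_total,
    }


def build_gradient(
    ref: ReferenceSet, top_n: int = 2000, env_mode: str = "logratio",
    prior_df: float | None = None,
) -> CCAGradient:
    """Top-N differential genes with their gradient (environmental) values.

    Ranked by adjusted p (ties broken by |t| then gene id); the value is the
    end-minus-start mean log2 intensity (positive = higher in the end
    state), or the moderated t itself with ``env_mode="t"``.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    res = moderated_t(ref, prior_df=prior_df)
    genes = res["gene_ids"]
    if top_n > len(genes):
        logger.warning("top_n=%d exceeds %d genes; using all", top_n, len(genes))
        top_n = len(genes)
    order = sorted(
        range(len(genes)),
        key=lambda i: (res["p_adj"][i], res["p"][i], -abs(res["t"][i]), genes[i]),
    )[:top_n]
    if env_mode == "logratio":
        vals = res["log_fc"][order]
    elif env_mode == "t":
        vals = res["t"][order]
    else:
        raise ValueError(f"unknown env_mode {env_mode!r}")
    return CCAGradient([genes[i] for i in order], np.asarray(vals, float), top_n)


def cca_scores(expr: TimeCourseMatrix, gradient: CCAGradient) -> CCAScores:
    """Score samples on the constrained axis of a one-variable CCA.

    The gene x sample table (restricted to gradient genes) is normalized to
    a probability table P with row/column masses r, c; the chi-square
    standardized residuals ``Q = Dr^-1/2 (P - r c') Dc^-1/2`` are projected
    onto the (row-mass weighted, centred) gradient variable and the
    projection is decomposed by SVD.  Sample scores are the axis-1 column
    principal coordinates, oriented so the last sample scores at least as
    high as the first; inertias are sums of squared standardized residuals.
    """
    present = [g for g in gradient.gene_ids if g in set(expr.gene_ids)]
    if len(present) < 2:
        raise ValueError("fewer than 2 gradient genes present in the matrix")
    if len(present) < len(gradient.gene_ids):
        logger.warning("cca_scores: %d/%d gradient genes present",
                       len(present), len(gradient.gene_ids))
    env = dict(zip(gradient.gene_ids, gradient.values))
    sub = expr.subset(present)
    X = sub.values
    keep = X.sum(axis=1) > 0
    if not keep.all():
        logger.warning("cca_scores: dropping %d zero-sum gene rows",
                       int((~keep).sum()))
    ids = [g for g, k in zip(present, keep) if k]
    X = X[keep]
    if np.any(X.sum(axis=0) <= 0):
        raise ValueError("every sample column must have positive total")
    z = np.array([env[g] for g in ids], dtype=float)

    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((Q**2).sum())

    zc = z - float(r @ z)          # row-mass weighted centring (sum r = 1)
    if np.allclose(zc, 0.0):
        raise ValueError("gradient variable is constant; cannot constrain")
    u = np.sqrt(r) * zc
    uu = float(u @ u)
    q = (u @ Q) / np.sqrt(uu)      # rank-1 projection: Qfit = (u/||u||) q'
    s1 = float(np.linalg.norm(q))
    constrained = s1**2

    if s1 < 1e-12 * max(1.0, np.sqrt(total_inertia)):
        scores = np.zeros(X.shape[1])
        contrib = np.zeros(len(ids))
    else:
        v = q / s1                          # unit right singular vector
        scores = s1 * v / np.sqrt(c)        # column principal coordinates
        if scores[-1] < scores[0]:
            scores = -scores
        row_score = (zc / np.sqrt(uu)) * s1  # Dr^-1/2 U S on the constrained axis
        contrib = np.abs(row_score) * r
    return CCAScores(scores, total_inertia, constrained, ids, contrib)


def top_contributors(scores: CCAScores, m: int = 1000) -> list[str]:
    """Gene ids contributing most to the constrained axis (|score| * mass)."""
    order = sorted(
        range(len(scores.gene_ids)),
        key=lambda i: (-scores.gene_contributions[i], scores.gene_ids[i]),
    )
    return [scores.gene_ids[i] for i in order[: max(0, m)]]
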