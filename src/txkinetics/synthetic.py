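"""Ground-truth synthetic datasets emulating the study design.

The generator emulates a synchronized differentiation time course: 7
expression arrays at 0-21 h (3.5 h apart), 4 transcription-shutoff arrays
at 0/1/2/5.5 h after an arrest applied at 10 h, heterogeneous per-gene
decay rates (half-lives 0.5-20 h), up-regulated genes driven by five shared
activity profiles through the production/degradation kinetic model,
down-regulated genes declining in three sigmoid waves, multiplicative
log-normal measurement noise, and two reference populations with planted
differential expression resembling start/end differentiation states.

Degradation series are generated by continuous-time integration of
``dx/dt = B + S f(t) - D x`` (so pair fitting is tested against data the
discrete model only approximates); ``model_exact=True`` instead generates
from the discrete equation, for zero-residual tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cca import ReferenceSet
from .io_ import (DEGRADATION_GRID, EXPRESSION_GRID, TimeCourseMatrix,
                  TimeGrid, default_sd)
from .kinetics import (KineticParams, build_derivative_operator,
                       normalize_activity, predict_expression)

__all__ = [
    "GeneratorConfig",
    "make_activity_profiles",
    "ACTIVITY_NAMES",
    "simulate_dataset",
    "simulate_reference_populations",
    "simulate_trajectory",
]

ACTIVITY_NAMES = (
    "early_maintained",
    "early_short",
    "early_intermediate",
    "late_continuous",
    "late_short",
)

#: Sigmoid midpoints (hours) of the three down-regulation waves.
WAVE_MIDPOINTS = (3.5, 10.5, 17.5)

#: Time (hours after the stimulus) at which transcription is arrested.
SHUTOFF_TIME = 10.0


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    60 up-regulated genes across the five activities, 30 down-regulated
    across three waves, 30 unchanged; 10% multiplicative noise; decay
    half-lives log-uniform on 0.5-20 h; baselines log-uniform on 50-500
    intensity units.
    """

    n_up: int = 60
    n_down: int = 30
    n_flat: int = 30
    noise_cv: float = 0.10
    half_life_range: tuple[float, float] = (0.5, 20.0)
    baseline_range: tuple[float, float] = (50.0, 500.0)
    s_over_b_range: tuple[float, float] = (1.5, 5.0)
    loss_factors: tuple[float, ...] | None = None   # per-degradation-array loss
    model_exact: bool = False
    sd_a: float = 1.0
    sd_b: float = 0.1
    # reference populations
    ref_genes: int = 2000
    ref_reps: int = 3
    de_fraction: float = 0.05
    effect_sd: float = 3.0          # planted shift in units of replicate sd
    rep_sd_log2: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_up, self.n_down, self.n_flat) < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.ref_reps < 2:
            raise ValueError("reference populations need >= 2 replicates")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")


def make_activity_profiles(grid: TimeGrid = EXPRESSION_GRID) -> np.ndarray:
    """The five shared activity shapes, rows normalized to f(0)=0, max 1.

    1 early maintained: fast rise by 3.5 h then plateau; 2 early short:
    fast rise then decay below 0.2 by 14 h; 3 early intermediate: fast rise
    then decay to ~0.5; 4 late continuous: slow monotone rise peaking at
    21 h; 5 late short: late rise peaking near 17.5 h then declining.
    """
    t = grid.array
    rise = 1.0 - np.exp(-t / 1.2)
    shapes = np.vstack([
        rise,
        rise * np.exp(-np.maximum(0.0, t - 3.5) / 3.5),
        rise * (0.5 + 0.5 * np.exp(-np.maximum(0.0, t - 3.5) / 4.0)),
        (t / t[-1]) ** 2,
        np.exp(-((t - 16.5) / 4.0) ** 2),
    ])
    out = np.empty_like(shapes)
    for i, s in enumerate(shapes):
        s = s - s[0]
        s = np.clip(s, 0.0, None)
        f, scale = normalize_activity(s)
        if scale <= 0:
            raise RuntimeError("degenerate activity shape")
        out[i] = f
    return out


def _interp_activity(f_grid: np.ndarray, grid: TimeGrid, t: np.ndarray) -> np.ndarray:
    return np.interp(t, grid.array, f_grid)


def _integrate_to_shutoff(
    B: np.ndarray, S: np.ndarray, D: np.ndarray, f_of_t, t_end: float,
    dt: float = 0.005,
) -> np.ndarray:
    """Vectorized RK4 for dx/dt = B + S f(t) - D x from x(0)=B/D to t_end."""
    n_steps = int(round(t_end / dt))
    x = B / D

    def rhs(t: float, xv: np.ndarray) -> np.ndarray:
        return B + S * f_of_t(t) - D * xv

    for k in range(n_steps):
        t0 = k * dt
        k1 = rhs(t0, x)
        k2 = rhs(t0 + dt / 2, x + dt / 2 * k1)
        k3 = rhs(t0 + dt / 2, x + dt / 2 * k2)
        k4 = rhs(t0 + dt, x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def _wave_profile(t: np.ndarray, x0: float, floor: float, mid: float,
                  width: float) -> np.ndarray:
    """Declining sigmoid from ~x0 to floor*x0 with midpoint ``mid``."""
    sig = 1.0 / (1.0 + np.exp((t - mid) / width))
    sig0 = 1.0 / (1.0 + np.exp(-mid / width))
    sig = sig / sig0
    return x0 * (floor + (1.0 - floor) * sig)


def simulate_dataset(
    cfg: GeneratorConfig,
    seed: int,
    grid: TimeGrid = EXPRESSION_GRID,
    deg_grid: TimeGrid = DEGRADATION_GRID,
) -> tuple[TimeCourseMatrix, TimeCourseMatrix, pd.DataFrame]:
    """Generate expression + degradation matrices and the truth table.

    Up-regulated genes are rejection-sampled (deterministically, from the
    gene's own stream) until their noise-free profile satisfies the three
    selection rules of the modelled set, so at zero noise the up-regulated
    filter recovers exactly the planted set.
    """
    rng = np.random.default_rng(seed)
    op = build_derivative_operator(grid)
    activities = make_activity_profiles(grid)
    t = grid.array
    tau = deg_grid.array
    lh = np.log(cfg.half_life_range)
    lb = np.log(cfg.baseline_range)
    lu = np.log(cfg.s_over_b_range)

    gene_ids: list[str] = []
    expr_rows: list[np.ndarray] = []
    deg_rows: list[np.ndarray] = []
    truth: list[dict] = []

    # up-regulated genes, round-robin over the five activities
    for i in range(cfg.n_up):
        act = i % len(activities)
        f = activities[act]
        g_rng = np.random.default_rng(rng.integers(2**31))
        for _ in range(200):
            x0 = float(np.exp(g_rng.uniform(*lb)))
            half = float(np.exp(g_rng.uniform(*lh)))
            D = np.log(2.0) / half
            u = float(np.exp(g_rng.uniform(*lu)))
            B = D * x0
            S = u * B
            params = KineticParams(B, S, D, 0.0)
            x = predict_expression(params, f, op)
            if (x.max() / x[0] > 1.6 and x.min() >= 0.1 * x[0]
                    and x.max() - x.min() >= 1.5 and np.all(x > 0)):
                break
        else:
            raise RuntimeError("could not sample an up-regulated gene "
                               "satisfying the selection rules")
        if cfg.model_exact:
            xd0 = float(np.interp(SHUTOFF_TIME, t, x))
        else:
            xd0 = float(_integrate_to_shutoff(
                np.array([B]), np.array([S]), np.array([D]),
                lambda tt: np.interp(tt, t, f), SHUTOFF_TIME)[0])
        deg = xd0 * np.exp(-D * tau)
        gene_ids.append(f"UP{i:03d}")
        expr_rows.append(x)
        deg_rows.append(deg)
        truth.append(dict(gene_id=gene_ids[-1], kind="up", activity=act + 1,
                          wave=-1, B=B, S=S, D=D, x0=x0, x_d0=xd0))

    # down-regulated genes in three sigmoid waves
    for i in range(cfg.n_down):
        wave = i % len(WAVE_MIDPOINTS)
        g_rng = np.random.default_rng(rng.integers(2**31))
        x0 = float(np.exp(g_rng.uniform(*lb)))
        floor = float(g_rng.uniform(0.2, 0.5))
        width = float(g_rng.uniform(1.0, 2.0))
        half = float(np.exp(g_rng.uniform(*lh)))
        D = np.log(2.0) / half
        x = _wave_profile(t, x0, floor, WAVE_MIDPOINTS[wave], width)
        xd0 = float(_wave_profile(np.array([SHUTOFF_TIME]), x0, floor,
                                  WAVE_MIDPOINTS[wave], width)[0])
        deg = xd0 * np.exp(-D * tau)
        gene_ids.append(f"DN{i:03d}")
        expr_rows.append(x)
        deg_rows.append(deg)
        truth.append(dict(gene_id=gene_ids[-1], kind="down", activity=-1,
                          wave=wave + 1, B=D * x0, S=0.0, D=D, x0=x0, x_d0=xd0))

    # unchanged genes
    for i in range(cfg.n_flat):
        g_rng = np.random.default_rng(rng.integers(2**31))
        x0 = float(np.exp(g_rng.uniform(*lb)))
        half = float(np.exp(g_rng.uniform(*lh)))
        D = np.log(2.0) / half
        x = np.full(len(t), x0)
        deg = x0 * np.exp(-D * tau)
        gene_ids.append(f"NC{i:03d}")
        expr_rows.append(x)
        deg_rows.append(deg)
        truth.append(dict(gene_id=gene_ids[-1], kind="flat", activity=-1,
                          wave=-1, B=D * x0, S=0.0, D=D, x0=x0, x_d0=x0))

    expr = np.vstack(expr_rows)
    deg = np.vstack(deg_rows)
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        expr = expr * np.exp(rng.normal(0, sigma, expr.shape) - sigma**2 / 2)
        deg = deg * np.exp(rng.normal(0, sigma, deg.shape) - sigma**2 / 2)
    if cfg.loss_factors is not None:
        loss = np.asarray(cfg.loss_factors, dtype=float)
        if loss.shape != (len(deg_grid),):
            raise ValueError("loss_factors length must match degradation grid")
        deg = deg * loss

    expr_tcm = TimeCourseMatrix(gene_ids, expr,
                                default_sd(expr, cfg.sd_a, cfg.sd_b), grid)
    deg_tcm = TimeCourseMatrix(list(gene_ids), deg,
                               default_sd(deg, cfg.sd_a, cfg.sd_b), deg_grid)
    truth_df = pd.DataFrame(truth).set_index("gene_id")
    truth_df.attrs["seed"] = int(seed)
    return expr_tcm, deg_tcm, truth_df


def simulate_reference_populations(
    cfg: GeneratorConfig, seed: int
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Two reference populations with planted differential expression.

    The start group draws per-gene baseline log2 means; the end group
    shifts a planted fraction of genes by ``effect_sd`` replicate standard
    deviations (random sign); replicate noise is log-normal.
    """
    rng = np.random.default_rng(seed)
    n = cfg.ref_genes
    genes = [f"G{i:05d}" for i in range(n)]
    mu = rng.uniform(5.6, 11.5, n)          # log2 intensity baselines
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    shift = np.zeros(n)
    shift[de_idx] = (cfg.effect_sd * cfg.rep_sd_log2
                     * rng.choice([-1.0, 1.0], size=n_de))
    start = 2.0 ** (mu[:, None] + rng.normal(0, cfg.rep_sd_log2, (n, cfg.ref_reps)))
    end = 2.0 ** ((mu + shift)[:, None]
                  + rng.normal(0, cfg.rep_sd_log2, (n, cfg.ref_reps)))
    flags = pd.DataFrame({"gene_id": genes, "is_de": shift != 0.0,
                          "shift_log2": shift}).set_index("gene_id")
    return ReferenceSet(genes, start, end, "start", "end"), flags


def simulate_trajectory(
    ref: ReferenceSet, times: np.ndarray, seed: int, noise_cv: float = 0.05
) -> TimeCourseMatrix:
    """Samples moving geometrically from the start to the end state.

    Sample at time t is ``exp((1-w) log start_mean + w log end_mean)`` with
    ``w = t / t_max``, plus multiplicative log-normal noise — the simplest
    trajectory whose ordination score should increase monotonically with
    time.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    w = times / times[-1]
    ls = np.log(ref.start.mean(axis=1))
    le = np.log(ref.end.mean(axis=1))
    X = np.exp(ls[:, None] * (1 - w) + le[:, None] * w)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        X = X * np.exp(rng.normal(0, sigma, X.shape) - sigma**2 / 2)
    grid = TimeGrid(tuple(times), "expression")
    return TimeCourseMatrix(list(ref.gene_ids), X, default_sd(X), grid)
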