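"""Discrete kinetic model of transcript production and decay.

Each transcript obeys ``dx/dt = B + S * f(t) - D * x`` where ``B`` is basal
production, ``S`` the sensitivity to a shared, hidden regulator activity
``f`` (dimensionless, f(0)=0, max 1), and ``D`` the first-order degradation
rate.  On the sampled time grid the derivative is approximated by a linear
operator ``A`` built from Lagrange-interpolation stencils, so the model
solution is the linear system ``(A + D*I) x = B*1 + S*f``.  After a
transcription shutoff, production ceases and the level decays as
``x_d0 * exp(-D*t)``.

The first row of ``A`` is zero: the net rate of change of every transcript
is taken to be nil at the moment the stimulus is applied, which pins
``x(0) = B/D``.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import numpy as np

from .io_ import TimeGrid, EXPRESSION_GRID

__all__ = [
    "DerivativeOperator",
    "KineticParams",
    "seven_point_stencil_fractions",
    "build_derivative_operator",
    "validate_activity",
    "normalize_activity",
    "predict_expression",
    "predict_degradation",
    "compound_production",
]


@dataclasses.dataclass(frozen=True)
class DerivativeOperator:
    """Square matrix estimating d/dt from values sampled on ``grid``."""

    matrix: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.grid)
        if m.shape != (n, n):
            raise ValueError("operator must be square and match the grid")
        object.__setattr__(self, "matrix", m)
        if np.max(np.abs(m.sum(axis=1))) >= 1e-12:
            raise ValueError("operator rows must sum to zero")
        if np.any(m[0] != 0.0):
            raise ValueError("first operator row must be zero")


@dataclasses.dataclass
class KineticParams:
    """Per-transcript kinetic parameters.

    B: basal production (intensity/h); S: sensitivity to the shared activity
    (intensity/h); D: degradation rate (1/h); x_d0: fitted initial level of
    the shutoff series (intensity).
    """

    B: float
    S: float
    D: float
    x_d0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("B", "S", "D", "x_d0"):
            v = float(getattr(self, name))
            setattr(self, name, v)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


def seven_point_stencil_fractions() -> list[list[Fraction]]:
    """The exact rational derivative operator for seven points 3.5 h apart.

    Row 1 is zero; rows 4, 5 and 7 are the standard five-point central and
    three-point backward difference stencils for spacing 3.5 h; rows 2, 3
    and 6 are smoothed early/late-time estimators kept verbatim (rows 2-3
    are not exact for linear trends; rows 4-7 are).
    """
    F = Fraction
    return [
        [F(0)] * 7,
        [F(-17, 63), F(1, 7), F(1, 7), F(-1, 63), F(0), F(0), F(0)],
        [F(31, 252), F(-8, 21), F(1, 7), F(8, 63), F(-1, 84), F(0), F(0)],
        [F(0), F(1, 42), F(-4, 21), F(0), F(4, 21), F(-1, 42), F(0)],
        [F(0), F(0), F(1, 42), F(-4, 21), F(0), F(4, 21), F(-1, 42)],
        [F(0), F(0), F(0), F(1, 21), F(-2, 7), F(1, 7), F(2, 21)],
        [F(0), F(0), F(0), F(0), F(1, 7), F(-4, 7), F(3, 7)],
    ]


def _lagrange_weights(nodes: np.ndarray, x: float) -> np.ndarray:
    """Derivative at ``x`` of the Lagrange interpolant through ``nodes``."""
    n = len(nodes)
    w = np.zeros(n)
    for j in range(n):
        others = [nodes[m] for m in range(n) if m != j]
        denom = np.prod([nodes[j] - xm for xm in others])
        total = 0.0
        for k, xk in enumerate(others):
            prod = 1.0
            for m, xm in enumerate(others):
                if m != k:
                    prod *= x - xm
            total += prod
        w[j] = total / denom
    return w


def build_derivative_operator(grid: TimeGrid) -> DerivativeOperator:
    """Construct the derivative operator for a time grid.

    For seven equally spaced points the exact rational stencil above is used
    (scaled if the spacing is not 3.5 h).  Other grids get three-point
    Lagrange derivative stencils over the local nodes (central in the
    interior, backward at the end).  The first row is always zero.
    """
    t = grid.array
    n = len(t)
    if n < 3:
        raise ValueError("derivative operator needs at least 3 time points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if n == 7 and np.allclose(dt, dt[0]):
        scale = 3.5 / dt[0]
        frac = seven_point_stencil_fractions()
        m = np.array([[float(v) for v in row] for row in frac]) * scale
        return DerivativeOperator(m, grid)

    m = np.zeros((n, n))
    for i in range(1, n):
        lo = max(0, min(i - 1, n - 3))
        nodes = t[lo : lo + 3]
        m[i, lo : lo + 3] = _lagrange_weights(nodes, t[i])
    return DerivativeOperator(m, grid)


def validate_activity(f: np.ndarray, *, atol: float = 1e-9) -> np.ndarray:
    """Check the shared-activity invariants: f(0)=0, max=1, finite, >=0."""
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("activity must be finite")
    if abs(f[0]) > atol:
        raise ValueError("activity must start at 0")
    if np.any(f < -atol):
        raise ValueError("activity must be non-negative")
    if abs(f.max() - 1.0) > atol:
        raise ValueError("activity must have max 1")
    return f


def normalize_activity(f: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale so max(f) = 1; returns (normalized f, scale absorbed)."""
    f = np.asarray(f, dtype=float).copy()
    f[0] = 0.0
    m = float(f.max())
    if m <= 0:
        return f, 0.0
    return f / m, m


def predict_expression(
    params: KineticParams, f: np.ndarray, op: DerivativeOperator
) -> np.ndarray:
    """Solve ``(A + D*I) x = B*1 + S*f`` on the expression grid.

    Because the first row of ``A`` is zero, the solution satisfies
    ``x(0) = B/D`` exactly (for ``D > 0``; ``D = 0`` leaves the system
    singular since ``A`` annihilates constants).
    """
    f = np.asarray(f, dtype=float)
    n = len(op.grid)
    if f.shape != (n,):
        raise ValueError("activity length must match operator grid")
    if params.D <= 0:
        raise ValueError("predict_expression requires D > 0 (D = 0 is singular)")
    lhs = op.matrix + params.D * np.eye(n)
    rhs = params.B + params.S * f
    return np.linalg.solve(lhs, rhs)


def predict_degradation(params: KineticParams, grid: TimeGrid) -> np.ndarray:
    """Closed-form decay after transcription arrest: ``x_d0 * exp(-D*t)``."""
    if params.D < 0:
        raise ValueError("D must be non-negative")
    return params.x_d0 * np.exp(-params.D * grid.array)


def compound_production(
    x: np.ndarray, D: float, op: DerivativeOperator
) -> np.ndarray:
    """Compound production ``G = dx/dt + D*x ~ A x + D x``.

    Under the model, G equals ``B + S*f``, i.e. an affine transform of the
    hidden regulator activity; for a constant series ``x = c`` it is ``D*c``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(op.grid),):
        raise ValueError("series length must match operator grid")
    if D < 0:
        raise ValueError("D must be non-negative")
    return op.matrix @ x + D * x
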