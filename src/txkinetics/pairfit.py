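"""Joint kinetic fitting of transcript pairs under one shared activity.

For a pair of transcripts, the model predicts both genes' stimulation time
courses through ``(A + D*I) x = B*1 + S*f`` and both shutoff chases through
``x_d0 * exp(-D*t)``, with the hidden activity ``f`` shared and everything
else gene-specific.  The 22 residuals (7 + 4 per gene), each divided by the
data point's standard deviation, are minimized by bounded least squares
(trust-region reflective, the bound-respecting relative of
Levenberg-Marquardt) from several deterministic starts.  The minimized
residual sum of squares (RSS) is small when one activity can drive both
genes — the dissimilarity used downstream for clustering.

Identifiability: f's scale is degenerate with S and its offset with B; the
convention f(0) = 0, max f = 1 (renormalized after convergence, with the
scale absorbed into S) makes G = B + S*f well-defined per gene.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import least_squares

from .config import AnalysisConfig
from .degradation import estimate_decay_rate
from .io_ import TimeCourseMatrix, TimeGrid
from .kinetics import DerivativeOperator, KineticParams, normalize_activity

logger = logging.getLogger("txkinetics")

__all__ = [
    "PairData",
    "PairFit",
    "RSSMatrix",
    "pair_residual",
    "fit_pair",
    "rss_matrix",
    "pair_count",
]


@dataclasses.dataclass
class PairData:
    """Two genes' expression and shutoff series with uncertainties."""

    gene_a: str
    gene_b: str
    expr_a: np.ndarray
    sd_expr_a: np.ndarray
    expr_b: np.ndarray
    sd_expr_b: np.ndarray
    deg_a: np.ndarray
    sd_deg_a: np.ndarray
    deg_b: np.ndarray
    sd_deg_b: np.ndarray
    expr_grid: TimeGrid
    deg_grid: TimeGrid

    def __post_init__(self) -> None:
        ne, nd = len(self.expr_grid), len(self.deg_grid)
        for name in ("expr_a", "sd_expr_a", "expr_b", "sd_expr_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (ne,):
                raise ValueError(f"{name} must have length {ne}")
        for name in ("deg_a", "sd_deg_a", "deg_b", "sd_deg_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (nd,):
                raise ValueError(f"{name} must have length {nd}")
        for name in ("sd_expr_a", "sd_expr_b", "sd_deg_a", "sd_deg_b"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_matrices(
        cls, expr: TimeCourseMatrix, deg: TimeCourseMatrix, gene_a: str, gene_b: str
    ) -> "PairData":
        ea, sa = expr.row(gene_a)
        eb, sb = expr.row(gene_b)
        da, dsa = deg.row(gene_a)
        db, dsb = deg.row(gene_b)
        return cls(gene_a, gene_b, ea, sa, eb, sb, da, dsa, db, dsb,
                   expr.grid, deg.grid)

    def swapped(self) -> "PairData":
        return PairData(
            self.gene_b, self.gene_a,
            self.expr_b, self.sd_expr_b, self.expr_a, self.sd_expr_a,
            self.deg_b, self.sd_deg_b, self.deg_a, self.sd_deg_a,
            self.expr_grid, self.deg_grid,
        )


@dataclasses.dataclass
class PairFit:
    rss: float
    params_a: KineticParams
    params_b: KineticParams
    f: np.ndarray                 # shared activity, f(0)=0, max 1 (if non-flat)
    converged: bool
    n_starts_used: int
    best_start_rss: float = np.inf   # rss of the best initialization evaluated


@dataclasses.dataclass
class RSSMatrix:
    gene_ids: list[str]
    matrix: np.ndarray
    seed: int
    config_hash: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.gene_ids),) * 2:
            raise ValueError("matrix shape must match gene ids")
        if not np.allclose(m, m.T):
            raise ValueError("RSS matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("RSS matrix diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("RSS entries must be finite and non-negative")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.matrix[iu]


def pair_count(n_genes: int) -> int:
    """Number of unordered pairs, n(n-1)/2."""
    if n_genes < 0:
        raise ValueError("gene count must be non-negative")
    return n_genes * (n_genes - 1) // 2


def pair_seed(gene_a: str, gene_b: str, global_seed: int) -> int:
    """Deterministic per-pair seed from the sorted id pair + global seed."""
    a, b = sorted((gene_a, gene_b))
    digest = hashlib.sha256(f"{a}|{b}|{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _residual_core(p: np.ndarray, A: np.ndarray, eye: np.ndarray,
                   tau: np.ndarray, data: PairData) -> np.ndarray:
    n = A.shape[0]
    f = np.empty(n)
    f[0] = 0.0
    f[1:] = p[8:]
    out = np.empty(2 * (n + len(tau)))
    pos = 0
    for (B, S, D, xd0), xe, se, xd, sdd in (
        (p[0:4], data.expr_a, data.sd_expr_a, data.deg_a, data.sd_deg_a),
        (p[4:8], data.expr_b, data.sd_expr_b, data.deg_b, data.sd_deg_b),
    ):
        x_pred = np.linalg.solve(A + D * eye, B + S * f)
        out[pos:pos + n] = (x_pred - xe) / se
        pos += n
        d_pred = xd0 * np.exp(-D * tau)
        out[pos:pos + len(tau)] = (d_pred - xd) / sdd
        pos += len(tau)
    return out


def pair_residual(
    params_a: KineticParams,
    params_b: KineticParams,
    f: np.ndarray,
    data: PairData,
    op: DerivativeOperator,
) -> np.ndarray:
    """Concatenated weighted residuals (gene A expr, A deg, B expr, B deg).

    Each component is (predicted - observed) / sd; the RSS is the squared
    norm of this vector.
    """
    f = np.asarray(f, dtype=float)
    n = len(op.grid)
    if f.shape != (n,):
        raise ValueError("activity length must match expression grid")
    p = np.concatenate([
        [params_a.B, params_a.S, params_a.D, params_a.x_d0],
        [params_b.B, params_b.S, params_b.D, params_b.x_d0],
        f[1:],
    ])
    return _residual_core(p, op.matrix, np.eye(n), data.deg_grid.array, data)


def _initial_points(
    data: PairData, op: DerivativeOperator, cfg: AnalysisConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    n = len(op.grid)
    d_init = []
    for series in (data.deg_a, data.deg_b):
        est = estimate_decay_rate(series, data.deg_grid)
        d = est.d_hat if est.ok and np.isfinite(est.d_hat) else 0.3
        d_init.append(float(np.clip(d, cfg.d_min * 2, cfg.d_max * 0.9)))
    base = np.empty(8 + n - 1)
    for k, (xe, xd, d) in enumerate(
        ((data.expr_a, data.deg_a, d_init[0]), (data.expr_b, data.deg_b, d_init[1]))
    ):
        B = max(d * xe[0], 1e-6)
        g = op.matrix @ xe + d * xe       # compound production of this gene
        S = max(float(g.max() - g[0]), 1e-3)
        base[4 * k: 4 * k + 4] = (B, S, d, max(xd[0], 1e-6))
    # shared-activity starts from each gene's normalized compound production
    f_inits = []
    for xe, d in ((data.expr_a, d_init[0]), (data.expr_b, d_init[1])):
        g = op.matrix @ xe + d * xe
        f0 = np.clip(g - g[0], 0.0, None)
        f0, scale = normalize_activity(f0)
        if scale <= 0:
            f0 = np.linspace(0, 1, n)
        f_inits.append(np.clip(f0[1:], 1e-6, 2.0))

    starts = []
    for k in range(max(1, cfg.n_starts)):
        p = base.copy()
        if k < len(f_inits):
            p[8:] = f_inits[k]
        else:
            p[:8] *= np.exp(rng.normal(0, 0.4, 8))
            p[8:] = np.clip(
                f_inits[k % 2] * np.exp(rng.normal(0, 0.4, n - 1)), 1e-6, 2.0
            )
        starts.append(p)
    return starts


def fit_pair(
    data: PairData,
    op: DerivativeOperator,
    cfg: AnalysisConfig,
    seed: int | None = None,
) -> PairFit:
    """Fit the joint pair model by multi-start bounded least squares.

    The pair is canonicalized to lexicographic gene order internally so the
    result is exactly symmetric under swapping; the reported parameters are
    mapped back to the caller's order.
    """
    swap = data.gene_b < data.gene_a
    work = data.swapped() if swap else data
    if seed is None:
        seed = pair_seed(work.gene_a, work.gene_b, cfg.seed)
    rng = np.random.default_rng(seed)
    n = len(op.grid)
    eye = np.eye(n)
    tau = work.deg_grid.array
    max_int = float(
        max(work.expr_a.max(), work.expr_b.max(), work.deg_a.max(),
            work.deg_b.max(), 1.0)
    )
    hi = cfg.bound_scale * max_int
    lb = np.concatenate([[0.0, 0.0, cfg.d_min, 0.0] * 2, np.zeros(n - 1)])
    ub = np.concatenate([[hi, hi, cfg.d_max, hi] * 2, np.full(n - 1, 2.0)])
    x_scale = np.concatenate([[max_int, max_int, 1.0, max_int] * 2, np.ones(n - 1)])

    def fun(p: np.ndarray) -> np.ndarray:
        return _residual_core(p, op.matrix, eye, tau, work)

    best = None
    best_cost = np.inf
    best_start_rss = np.inf
    n_used = 0
    for start in _initial_points(work, op, cfg, rng):
        p0 = np.clip(start, lb, ub)
        p0[2] = np.clip(p0[2], cfg.d_min, cfg.d_max)
        p0[6] = np.clip(p0[6], cfg.d_min, cfg.d_max)
        r0 = fun(p0)
        best_start_rss = min(best_start_rss, float(r0 @ r0))
        try:
            res = least_squares(
                fun, p0, bounds=(lb, ub), method="trf", x_scale=x_scale,
                ftol=cfg.fit_tol, xtol=cfg.fit_tol, gtol=cfg.fit_tol,
                max_nfev=cfg.max_nfev,
            )
        except Exception as exc:   # singular systems, overflow in a bad corner
            logger.debug("pair fit start failed (%s/%s): %s",
                         work.gene_a, work.gene_b, exc)
            continue
        n_used += 1
        if res.cost < best_cost:
            best_cost = res.cost
            best = res
    if best is None:
        logger.warning("all fit starts failed for pair (%s, %s)",
                       work.gene_a, work.gene_b)
        nanp = KineticParams(0, 0, cfg.d_min, 0)
        return PairFit(np.inf, nanp, nanp, np.zeros(n), False, 0)

    p = best.x
    f = np.empty(n)
    f[0] = 0.0
    f[1:] = p[8:]
    f, scale = normalize_activity(f)
    s_a, s_b = p[1], p[5]
    if scale > 0:
        s_a, s_b = s_a * scale, s_b * scale
    pa = KineticParams(p[0], s_a, p[2], p[3])
    pb = KineticParams(p[4], s_b, p[6], p[7])
    rss = float(2.0 * best.cost)
    if swap:
        pa, pb = pb, pa
    return PairFit(rss, pa, pb, f, True, n_used, min(best_start_rss, rss))


def _fit_one(expr: TimeCourseMatrix, deg: TimeCourseMatrix,
             op: DerivativeOperator, cfg: AnalysisConfig,
             a: str, b: str) -> tuple[str, str, float]:
    data = PairData.from_matrices(expr, deg, a, b)
    fit = fit_pair(data, op, cfg)
    return a, b, fit.rss


def rss_matrix(
    expr: TimeCourseMatrix,
    deg: TimeCourseMatrix,
    op: DerivativeOperator,
    cfg: AnalysisConfig,
    gene_ids: Sequence[str] | None = None,
    checkpoint: str | Path | None = None,
    n_jobs: int = 1,
) -> RSSMatrix:
    """Fit all unordered gene pairs and assemble the symmetric RSS matrix.

    Per-pair seeds derive from the sorted id pair and the global seed, so
    the result is independent of execution order, chunking and thread
    count.  With ``checkpoint`` set, finished pairs are appended to a TSV
    and a rerun resumes from it (refusing on a config-hash mismatch).
    """
    ids = sorted(gene_ids if gene_ids is not None else expr.gene_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 genes")
    cfg_hash = cfg.config_hash()
    done: dict[tuple[str, str], float] = {}
    ckpt_fh = None
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        if checkpoint.exists():
            with checkpoint.open() as fh:
                header = fh.readline().strip()
                expected = f"# config_hash={cfg_hash}\tseed={cfg.seed}"
                if header != expected:
                    raise ValueError(
                        f"checkpoint {checkpoint} was written under a different "
                        f"config/seed; refusing to resume"
                    )
                for line in fh:
                    a, b, v = line.rstrip("\n").split("\t")
                    done[(a, b)] = float(v)
        else:
            checkpoint.write_text(f"# config_hash={cfg_hash}\tseed={cfg.seed}\n")
        ckpt_fh = checkpoint.open("a")

    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    todo = [(a, b) for a, b in pairs if (a, b) not in done]
    logger.info("rss_matrix: %d genes, %d pairs (%d cached)",
                len(ids), len(pairs), len(done))
    try:
        if n_jobs != 1:
            results = Parallel(n_jobs=n_jobs, batch_size=64)(
                delayed(_fit_one)(expr, deg, op, cfg, a, b) for a, b in todo
            )
        else:
            results = []
            for k, (a, b) in enumerate(todo):
                results.append(_fit_one(expr, deg, op, cfg, a, b))
                if ckpt_fh is not None:
                    a_, b_, v = results[-1]
                    ckpt_fh.write(f"{a_}\t{b_}\t{v:.17g}\n")
                    if k % 200 == 0:
                        ckpt_fh.flush()
        if n_jobs != 1 and ckpt_fh is not None:
            for a_, b_, v in results:
                ckpt_fh.write(f"{a_}\t{b_}\t{v:.17g}\n")
        for a_, b_, v in results:
            done[(a_, b_)] = v
    finally:
        if ckpt_fh is not None:
            ckpt_fh.close()

    index = {g: i for i, g in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for (a, b), v in done.items():
        if a in index and b in index:
            m[index[a], index[b]] = m[index[b], index[a]] = v
    return RSSMatrix(ids, m, cfg.seed, cfg_hash)


def write_rss_matrix(rss: RSSMatrix, path: str | Path) -> None:
    """Persist as (gene_i, gene_j, rss) triples with a metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={rss.config_hash}\tseed={rss.seed}\n")
        fh.write("gene_i\tgene_j\trss\n")
        for i, a in enumerate(rss.gene_ids):
            for j in range(i + 1, len(rss.gene_ids)):
                fh.write(f"{a}\t{rss.gene_ids[j]}\t{rss.matrix[i, j]:.17g}\n")


def read_rss_matrix(path: str | Path) -> RSSMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split("\t"))
        fh.readline()  # column header
        triples = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    ids = sorted({t[0] for t in triples} | {t[1] for t in triples})
    index = {g: i for i, g in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for a, b, v in triples:
        m[index[a], index[b]] = m[index[b], index[a]] = float(v)
    return RSSMatrix(ids, m, int(meta.get("seed", 0)), meta.get("config_hash", ""))
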