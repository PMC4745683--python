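"""Shared data model and tab-separated I/O.

The whole pipeline exchanges gene x time matrices of *non-log* normalized
intensities (arbitrary units).  The kinetic model is linear in concentration,
not log-concentration, so any log-scale input must be flagged explicitly and
is exponentiated on load.  Gene identifiers are opaque strings; no
probe-to-gene collapsing is performed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("txkinetics")

__all__ = [
    "TimeGrid",
    "TimeCourseMatrix",
    "EXPRESSION_GRID",
    "DEGRADATION_GRID",
    "default_sd",
    "read_time_course",
    "write_time_course",
    "write_cluster_table",
    "write_metadata_sidecar",
]


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Ordered observation times in hours, starting at 0.

    ``label`` distinguishes the stimulation time course ("expression") from
    the transcription-shutoff chase ("degradation"); times in the latter are
    measured from the moment transcription is arrested.
    """

    times: tuple[float, ...]
    label: str = "expression"

    def __post_init__(self) -> None:
        if self.label not in ("expression", "degradation"):
            raise ValueError(f"unknown grid label {self.label!r}")
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if len(t) < 2:
            raise ValueError("a time grid needs at least 2 points")
        if t[0] != 0.0:
            raise ValueError("time grids must start at 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


#: 0-21 h sampled every 3.5 h after the differentiation stimulus.
EXPRESSION_GRID = TimeGrid((0.0, 3.5, 7.0, 10.5, 14.0, 17.5, 21.0), "expression")
#: 0/1/2/5.5 h after actinomycin-D transcription arrest.
DEGRADATION_GRID = TimeGrid((0.0, 1.0, 2.0, 5.5), "degradation")


def default_sd(values: np.ndarray, a: float = 1.0, b: float = 0.1) -> np.ndarray:
    """Affine error model ``sd = a + b * intensity``.

    Used whenever replicate standard deviations are unavailable; ``b`` acts
    as a coefficient-of-variation floor at high intensity and ``a`` keeps
    weights finite near zero.
    """
    if a <= 0 and b <= 0:
        raise ValueError("error model needs a > 0 or b > 0")
    return a + b * np.asarray(values, dtype=float)


@dataclasses.dataclass
class TimeCourseMatrix:
    """Genes x time points of non-log intensities with per-entry sd."""

    gene_ids: list[str]
    values: np.ndarray
    sd: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float).reshape(
            len(self.gene_ids), len(self.grid)
        )
        self.sd = np.asarray(self.sd, dtype=float).reshape(self.values.shape)
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g!r}")
            seen.add(g)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if not np.all(np.isfinite(self.sd)) or np.any(self.sd <= 0):
            raise ValueError("sd must be finite and strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def _index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self._index()[gene_id]
        return self.values[i], self.sd[i]

    def subset(self, gene_ids: Sequence[str]) -> "TimeCourseMatrix":
        idx = self._index()
        rows = [idx[g] for g in gene_ids]
        return TimeCourseMatrix(
            list(gene_ids), self.values[rows], self.sd[rows], self.grid
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.grid.times)


def read_time_course(
    path: str | Path,
    grid: TimeGrid,
    *,
    sd_path: str | Path | None = None,
    error_model: tuple[float, float] = (1.0, 0.1),
    log2_input: bool = False,
) -> TimeCourseMatrix:
    """Read a tab-separated gene x time matrix.

    The header row holds the observation times, the first column the gene
    id.  When no companion sd matrix is given, per-entry uncertainties come
    from the affine error model.  ``log2_input=True`` exponentiates a
    log2-scale matrix on load (the model works on linear intensities).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] != len(grid):
        raise ValueError(
            f"{path}: {df.shape[1]} data columns but grid has {len(grid)} points"
        )
    try:
        times = [float(c) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: header must be numeric times: {exc}") from exc
    if not np.allclose(times, grid.array, atol=1e-6):
        raise ValueError(f"{path}: header times {times} do not match grid {grid.times}")

    gene_ids = [str(g) for g in df.index]
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate gene id: {dupes[0]!r}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at gene {gene!r}, column {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing value at gene {gene!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)

    if log2_input:
        values = np.exp2(values)

    if sd_path is not None:
        sd_mat = read_time_course(sd_path, grid, error_model=error_model)
        if sd_mat.gene_ids != gene_ids:
            raise ValueError("sd matrix gene ids do not match value matrix")
        sd = sd_mat.values
        if np.any(sd <= 0):
            raise ValueError("sd matrix must be strictly positive")
    else:
        sd = default_sd(values, *error_model)
    return TimeCourseMatrix(gene_ids, values, sd, grid)


def write_time_course(matrix: TimeCourseMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, re-readable by :func:`read_time_course`.

    Row order is preserved; values are written with 17 significant digits so
    the round trip is the identity well below 1e-12.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(f"{t:g}" for t in matrix.grid.times) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def write_cluster_table(assignments: Mapping[str, object], path: str | Path) -> None:
    """Write a gene -> cluster table, genes sorted lexicographically."""
    path = Path(path)
    genes = sorted(assignments)
    with path.open("w") as fh:
        fh.write("gene_id\tcluster\n")
        for g in genes:
            fh.write(f"{g}\t{assignments[g]}\n")
    sizes: dict[str, int] = {}
    for g in genes:
        lab = str(assignments[g])
        sizes[lab] = sizes.get(lab, 0) + 1
    logger.info("wrote %s: %d genes, cluster sizes %s", path, len(genes), sizes)


def write_metadata_sidecar(
    path: str | Path, config_hash: str, seed: int, **extra: object
) -> None:
    """Record provenance (config hash + seed) next to a pipeline output."""
    meta = {"config_hash": config_hash, "seed": int(seed), **extra}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")
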