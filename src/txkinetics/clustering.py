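"""Clustering of transcripts by shared activity, and down-regulation waves.

Up-regulated genes are grouped by Ward's minimum-variance agglomeration on
the pairwise dissimilarity d = sqrt(RSS) from the joint kinetic fits; the
dendrogram is cut into k principal activities (and the two-branch top split
is reported).  Down-regulated genes are grouped by Pearson correlation of
their expression profiles (average linkage on 1 - r, cut at 1 - threshold).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .io_ import TimeCourseMatrix
from .kinetics import DerivativeOperator, compound_production

logger = logging.getLogger("txkinetics")

__all__ = [
    "ClusterAssignment",
    "WaveAssignment",
    "ward_cluster",
    "cluster_g_profiles",
    "order_clusters_by_g",
    "pearson_cluster_downregulated",
    "intersect_tfs",
    "linkage_to_newick",
]


@dataclasses.dataclass
class ClusterAssignment:
    labels: dict[str, int]          # gene -> 1..k
    linkage: np.ndarray             # scipy linkage matrix (merge topology/heights)
    k: int
    top_split: dict[str, int]       # gene -> 1 or 2 (two major responses)

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, lab in self.labels.items():
            out.setdefault(lab, []).append(g)
        return {lab: sorted(gs) for lab, gs in out.items()}


@dataclasses.dataclass
class WaveAssignment:
    labels: dict[str, int]          # gene -> 1..n_waves, 0 = unassigned
    mean_profiles: dict[int, np.ndarray]   # per-wave mean min-max-normalized profile
    times: np.ndarray


def _relabel_deterministic(ids: Sequence[str], flat: np.ndarray) -> dict[str, int]:
    """Renumber clusters 1..k in order of first (lexicographic) member."""
    first: dict[int, str] = {}
    for g, lab in zip(ids, flat):
        if lab not in first or g < first[lab]:
            first[lab] = g
    order = sorted(first, key=lambda lab: first[lab])
    remap = {old: new + 1 for new, old in enumerate(order)}
    return {g: remap[lab] for g, lab in zip(ids, flat)}


def ward_cluster(rss, k: int, variant: str = "lw") -> ClusterAssignment:
    """Ward agglomeration on d = sqrt(RSS), cut into k clusters.

    ``variant="lw"`` applies the Lance-Williams Ward update to the provided
    distances (hclust ward.D2 semantics on sqrt(RSS)); ``variant="d"``
    applies the update to the distances as if they were already squared
    (ward.D semantics).  Genes are sorted lexicographically first so
    tie-breaking is deterministic.
    """
    ids = list(rss.gene_ids)
    if sorted(ids) != ids:
        raise ValueError("RSSMatrix gene ids must be sorted")
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    cond = rss.condensed()
    if not np.all(np.isfinite(cond)):
        raise ValueError("RSS matrix contains non-finite entries")
    d = np.sqrt(cond)
    if variant == "lw":
        Z = hierarchy.linkage(d, method="ward")
    elif variant == "d":
        Z = hierarchy.linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    flat = hierarchy.fcluster(Z, k, criterion="maxclust")
    top2 = hierarchy.fcluster(Z, 2, criterion="maxclust")
    return ClusterAssignment(
        labels=_relabel_deterministic(ids, flat),
        linkage=Z,
        k=int(len(set(flat))),
        top_split=_relabel_deterministic(ids, top2),
    )


def cluster_g_profiles(
    assignment: ClusterAssignment,
    expr: TimeCourseMatrix,
    d_by_gene: Mapping[str, float],
    op: DerivativeOperator,
    norm: str = "minmax",
) -> dict[int, np.ndarray]:
    """Per-cluster mean normalized compound-production (G) profile.

    G = A x + D x per gene, min-max normalized to [0, 1] (or z-scored), then
    averaged within each cluster.  Genes with no decay rate or a degenerate
    (zero-range) profile are skipped with a warning.
    """
    profiles: dict[int, list[np.ndarray]] = {}
    for g, lab in assignment.labels.items():
        if g not in d_by_gene or not np.isfinite(d_by_gene[g]):
            logger.warning("cluster_g_profiles: no decay rate for %s; skipped", g)
            continue
        x, _ = expr.row(g)
        prof = compound_production(x, max(0.0, float(d_by_gene[g])), op)
        degenerate = 1e-12 * max(1.0, float(np.max(np.abs(prof))))
        if norm == "minmax":
            rng = prof.max() - prof.min()
            if rng <= degenerate:
                logger.warning("cluster_g_profiles: degenerate G range for %s; skipped", g)
                continue
            prof = (prof - prof.min()) / rng
        elif norm == "zscore":
            s = prof.std()
            if s <= degenerate:
                logger.warning("cluster_g_profiles: degenerate G range for %s; skipped", g)
                continue
            prof = (prof - prof.mean()) / s
        else:
            raise ValueError(f"unknown normalization {norm!r}")
        profiles.setdefault(lab, []).append(prof)
    return {lab: np.mean(np.vstack(ps), axis=0) for lab, ps in sorted(profiles.items())}


def _half_max_time(profile: np.ndarray, times: np.ndarray) -> float:
    """First time the profile reaches half of its maximum (linear interp)."""
    p = np.asarray(profile, dtype=float)
    half = p.min() + 0.5 * (p.max() - p.min())
    for i in range(1, len(p)):
        if p[i] >= half:
            if p[i] == p[i - 1]:
                return float(times[i])
            w = (half - p[i - 1]) / (p[i] - p[i - 1])
            return float(times[i - 1] + w * (times[i] - times[i - 1]))
    return float(times[-1])


def order_clusters_by_g(
    assignment: ClusterAssignment,
    mean_g: Mapping[int, np.ndarray],
    times: np.ndarray,
) -> tuple[ClusterAssignment, dict[int, np.ndarray]]:
    """Renumber clusters so label 1 has the earliest G half-maximum time."""
    order = sorted(mean_g, key=lambda lab: (_half_max_time(mean_g[lab], times), lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {g: remap.get(lab, lab) for g, lab in assignment.labels.items()}
    new_mean = {remap[lab]: prof for lab, prof in mean_g.items()}
    return (
        ClusterAssignment(labels, assignment.linkage, assignment.k,
                          assignment.top_split),
        new_mean,
    )


def pearson_cluster_downregulated(
    expr: TimeCourseMatrix,
    r_threshold: float = 0.8,
    min_size: int = 5,
    mode: str = "average",
) -> WaveAssignment:
    """Group down-regulated genes into waves by profile correlation.

    ``mode="average"``: average-linkage clustering on 1 - r, cut at height
    1 - r_threshold.  ``mode="components"``: connected components of the
    r >= threshold graph.  Waves are numbered by the time of steepest mean
    decline (earliest = 1); clusters below ``min_size`` stay unassigned (0).
    """
    ids = list(expr.gene_ids)
    X = expr.values
    var_ok = X.std(axis=1) > 0
    if not var_ok.all():
        logger.warning("pearson waves: excluding %d zero-variance genes",
                       int((~var_ok).sum()))
    ids = [g for g, ok in zip(ids, var_ok) if ok]
    X = X[var_ok]
    if len(ids) < 2:
        raise ValueError("need at least 2 genes with non-zero variance")
    order = np.argsort(ids, kind="stable")
    ids = [ids[i] for i in order]
    X = X[order]
    R = np.corrcoef(X)
    if mode == "average":
        dist = np.clip(1.0 - R, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        iu = np.triu_indices(len(ids), k=1)
        Z = hierarchy.linkage(dist[iu], method="average")
        flat = hierarchy.fcluster(Z, 1.0 - r_threshold, criterion="distance")
    elif mode == "components":
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components
        adj = sp.csr_matrix(R >= r_threshold)
        _, flat = connected_components(adj, directed=False)
    else:
        raise ValueError(f"unknown wave mode {mode!r}")

    sizes: dict[int, int] = {}
    for lab in flat:
        sizes[lab] = sizes.get(lab, 0) + 1
    big = sorted(lab for lab, s in sizes.items() if s >= min_size)

    # mean min-max-normalized profile per retained cluster
    t = expr.grid.array
    prof_by_lab: dict[int, np.ndarray] = {}
    for lab in big:
        rows = X[flat == lab]
        rng = rows.max(axis=1, keepdims=True) - rows.min(axis=1, keepdims=True)
        rng[rng == 0] = 1.0
        prof_by_lab[lab] = ((rows - rows.min(axis=1, keepdims=True)) / rng).mean(axis=0)

    def steepest_decline(p: np.ndarray) -> float:
        slopes = np.diff(p) / np.diff(t)
        i = int(np.argmin(slopes))
        return float(0.5 * (t[i] + t[i + 1]))

    ordered = sorted(big, key=lambda lab: (steepest_decline(prof_by_lab[lab]), lab))
    remap = {old: new + 1 for new, old in enumerate(ordered)}
    labels = {g: remap.get(lab, 0) for g, lab in zip(ids, flat)}
    mean_profiles = {remap[lab]: prof_by_lab[lab] for lab in ordered}
    return WaveAssignment(labels, mean_profiles, t)


def intersect_tfs(
    genes: Iterable[str],
    tf_list: Iterable[str],
    clusters: Mapping[str, int] | None = None,
) -> tuple[set[str], dict[int, int]]:
    """Case-insensitive intersection with a transcription-factor list.

    Returns the matching gene ids (original casing from ``genes``) and, when
    a cluster map is supplied, per-cluster match counts.
    """
    tf_lower = {t.lower() for t in tf_list}
    matched = {g for g in genes if g.lower() in tf_lower}
    counts: dict[int, int] = {}
    if clusters is not None:
        for g in matched:
            if g in clusters:
                lab = clusters[g]
                counts[lab] = counts.get(lab, 0) + 1
    return matched, counts


def linkage_to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    """Export a scipy linkage as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
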