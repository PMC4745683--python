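"""Ward clustering (vs an independent Lance-Williams oracle), G profiles,
Pearson waves, and TF intersection."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

import txkinetics as tk
from txkinetics.clustering import (
    cluster_g_profiles,
    intersect_tfs,
    linkage_to_newick,
    order_clusters_by_g,
    pearson_cluster_downregulated,
    ward_cluster,
)
from txkinetics.io_ import EXPRESSION_GRID, TimeCourseMatrix, default_sd
from txkinetics.kinetics import KineticParams, predict_expression
from txkinetics.pairfit import RSSMatrix
from txkinetics.synthetic import GeneratorConfig, make_activity_profiles, simulate_dataset


def rss_from_distance(ids, d):
    return RSSMatrix(ids, d**2, 0, "test")


def blob_distance(sizes, within=1.0, between=100.0, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            base = within if labels[i] == labels[j] else between
            d[i, j] = base + rng.uniform(0, 0.01)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d, labels


def bruteforce_ward(d):
    """Independent Lance-Williams Ward agglomeration on a distance matrix.

    Returns the merge sequence as (frozenset_a, frozenset_b, height) using
    the recurrence on squared distances:
    d(k, i+j)^2 = ((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2) / (n_i+n_j+n_k)
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {frozenset([i, j]): d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((d2[frozenset([a, b])], a, b) for i, a in enumerate(keys)
             for b in keys[i + 1:]),
        )
        h2, a, b = best
        merges.append((clusters[a], clusters[b], np.sqrt(h2)))
        for k in keys:
            if k in (a, b):
                continue
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            new = ((na + nk) * d2[frozenset([a, k])]
                   + (nb + nk) * d2[frozenset([b, k])]
                   - nk * h2) / (na + nb + nk)
            d2[frozenset([next_id, k])] = new
        clusters[next_id] = clusters[a] | clusters[b]
        sizes[next_id] = sizes[a] + sizes[b]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        next_id += 1
    return merges


class TestWardCluster:
    def test_separated_blobs_recovered(self):
        d, labels = blob_distance([6, 6])
        ids = [f"g{i:02d}" for i in range(12)]
        assign = ward_cluster(rss_from_distance(ids, d), k=2)
        got = np.array([assign.labels[g] for g in ids])
        assert adjusted_rand_score(labels, got) == 1.0

    def test_k_equals_n_singletons(self):
        d, _ = blob_distance([3, 3])
        ids = [f"g{i}" for i in range(6)]
        assign = ward_cluster(rss_from_distance(ids, d), k=6)
        assert len(set(assign.labels.values())) == 6

    def test_matches_bruteforce_lance_williams(self):
        # 30-point planted 3-cluster dissimilarity; identical merge sequence
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(c, 1.0, (10, 2)) for c in (0, 8, 16)])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"g{i:02d}" for i in range(30)]
        assign = ward_cluster(rss_from_distance(ids, d), k=3)
        oracle = bruteforce_ward(d)
        Z = assign.linkage
        # replay scipy's merge sequence into member sets
        members = {i: frozenset([i]) for i in range(30)}
        for step, (left, right, height, _) in enumerate(Z):
            a, b = members[int(left)], members[int(right)]
            oa, ob, oh = oracle[step]
            assert {a, b} == {oa, ob}
            assert height == pytest.approx(oh, rel=1e-9)
            members[30 + step] = a | b

    def test_merge_heights_monotone(self, fitted_rss):
        rss, _ = fitted_rss
        assign = ward_cluster(rss, k=5)
        assert np.all(np.diff(assign.linkage[:, 2]) >= -1e-9)

    def test_top_split_is_two_groups(self):
        d, _ = blob_distance([5, 5, 5])
        ids = [f"g{i:02d}" for i in range(15)]
        assign = ward_cluster(rss_from_distance(ids, d), k=3)
        assert set(assign.top_split.values()) == {1, 2}

    def test_nonfinite_rejected(self):
        rss = rss_from_distance(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        rss.matrix[0, 1] = rss.matrix[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            ward_cluster(rss, 2)


class TestGProfiles:
    def test_identical_genes_mean_is_member(self, expr_op):
        f = make_activity_profiles()[0]
        x = predict_expression(KineticParams(5, 20, 0.5), f, expr_op)
        vals = np.vstack([x, x, x])
        expr = TimeCourseMatrix(["a", "b", "c"], vals, default_sd(vals),
                                EXPRESSION_GRID)
        assign = ward_cluster(
            rss_from_distance(["a", "b", "c"], np.ones((3, 3)) - np.eye(3)), 2)
        mean_g = cluster_g_profiles(assign, expr, {"a": 0.5, "b": 0.5, "c": 0.5},
                                    expr_op)
        from txkinetics.kinetics import compound_production
        g = compound_production(x, 0.5, expr_op)
        g_norm = (g - g.min()) / (g.max() - g.min())
        for prof in mean_g.values():
            np.testing.assert_allclose(prof, g_norm, atol=1e-12)

    def test_constant_series_skipped(self, expr_op):
        vals = np.vstack([np.full(7, 4.0), np.arange(1.0, 8.0)])
        expr = TimeCourseMatrix(["a", "b"], vals, default_sd(vals), EXPRESSION_GRID)
        assign = ward_cluster(
            rss_from_distance(["a", "b"], np.array([[0, 1.0], [1.0, 0]])), 2)
        mean_g = cluster_g_profiles(assign, expr, {"a": 0.0, "b": 0.0}, expr_op)
        # constant series with D=0 has zero-range G and is dropped
        labs_with_profiles = set(mean_g)
        assert assign.labels["a"] not in labs_with_profiles or \
            assign.labels["a"] == assign.labels["b"]
        assert assign.labels["b"] in labs_with_profiles

    def test_mean_g_tracks_generating_activity(self, fitted_rss, noisy_cohort,
                                               expr_op):
        expr, deg, _ = noisy_cohort
        rss, truth = fitted_rss
        assign = ward_cluster(rss, k=5)
        d_by_gene = dict(truth["D"])
        mean_g, profiles = cluster_g_profiles(assign, expr, d_by_gene, expr_op), \
            make_activity_profiles()
        assign2, mean_g = order_clusters_by_g(assign, mean_g, expr.grid.array)
        # each cluster's mean G correlates strongly with one generating shape
        for lab, prof in mean_g.items():
            best = max(float(np.corrcoef(prof, p)[0, 1]) for p in profiles)
            assert best > 0.9

    def test_order_clusters_by_half_max(self, expr_op):
        t = EXPRESSION_GRID.array
        early = np.clip(t / 3.5, 0, 1)
        late = np.clip((t - 10.5) / 7.0, 0, 1)
        d, _ = blob_distance([2, 2])
        ids = ["g0", "g1", "g2", "g3"]
        assign = ward_cluster(rss_from_distance(ids, d), 2)
        lab_first = assign.labels["g0"]
        lab_second = 3 - lab_first
        mean_g = {lab_first: late, lab_second: early}
        relabeled, new_mean = order_clusters_by_g(assign, mean_g, t)
        np.testing.assert_array_equal(new_mean[1], early)
        np.testing.assert_array_equal(new_mean[2], late)


class TestPearsonWaves:
    def test_affine_family_single_cluster(self):
        base = np.array([10, 10, 8, 5, 3, 2, 2.0])
        vals = np.vstack([a * base + b for a, b in ((1, 0), (2, 1), (0.5, 3),
                                                    (3, 2), (1.5, 0.5))])
        expr = TimeCourseMatrix([f"g{i}" for i in range(5)], vals,
                                default_sd(vals), EXPRESSION_GRID)
        waves = pearson_cluster_downregulated(expr, min_size=2)
        assert set(waves.labels.values()) == {1}

    def test_anticorrelated_families_split(self):
        up = np.array([1, 2, 4, 6, 8, 9, 10.0])
        down = up[::-1].copy()
        vals = np.vstack([up, up * 2, up + 1, down, down * 3, down + 2])
        expr = TimeCourseMatrix([f"g{i}" for i in range(6)], vals,
                                default_sd(vals), EXPRESSION_GRID)
        waves = pearson_cluster_downregulated(expr, r_threshold=0.8, min_size=2)
        labs = [waves.labels[f"g{i}"] for i in range(6)]
        assert labs[0] == labs[1] == labs[2]
        assert labs[3] == labs[4] == labs[5]
        assert labs[0] != labs[3]

    def test_three_wave_recovery(self, noisy_cohort):
        expr, _, truth = noisy_cohort
        down_ids = sorted(truth[truth.kind == "down"].index)
        waves = pearson_cluster_downregulated(expr.subset(down_ids))
        got = [waves.labels[g] for g in down_ids]
        planted = truth.loc[down_ids, "wave"].to_numpy()
        assert adjusted_rand_score(planted, got) >= 0.8
        # waves numbered by declining order of their midpoints
        assert set(waves.mean_profiles) == {1, 2, 3}

    def test_zero_variance_gene_excluded(self):
        vals = np.vstack([np.full(7, 5.0), [9, 8, 7, 6, 5, 4, 3.0],
                          [10, 9, 8, 7, 6, 5, 4.0]])
        expr = TimeCourseMatrix(["flat", "g1", "g2"], vals, default_sd(vals),
                                EXPRESSION_GRID)
        waves = pearson_cluster_downregulated(expr, min_size=2)
        assert "flat" not in waves.labels


class TestIntersectTFs:
    def test_case_insensitive_match(self):
        matched, _ = intersect_tfs({"a", "b", "c"}, {"B", "d"})
        assert matched == {"b"}

    def test_empty_tf_list(self):
        matched, counts = intersect_tfs({"a", "b"}, set())
        assert matched == set() and counts == {}

    def test_per_cluster_counts_conserve_total(self):
        genes = {"a", "b", "c", "d"}
        clusters = {"a": 1, "b": 1, "c": 2, "d": 3}
        matched, counts = intersect_tfs(genes, {"A", "C", "D"}, clusters)
        assert sum(counts.values()) == len(matched) == 3


def test_newick_export_parses(fitted_rss):
    rss, _ = fitted_rss
    assign = ward_cluster(rss, 5)
    nwk = linkage_to_newick(assign.linkage, rss.gene_ids)
    assert nwk.endswith(";") and nwk.count("(") == len(rss.gene_ids) - 1
    for g in rss.gene_ids:
        assert g in nwk
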