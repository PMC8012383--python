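import itertools

import numpy as np
import pandas as pd
import pytest

from howlid import (
    agnes_cluster,
    count_individuals,
    cut_dendrogram,
    cut_to_k,
    evaluate_identification,
)
from howlid.clustering import calibrate_cut_height
from howlid.exceptions import HowlIdError


def frame(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and points.shape[1] > 1 and points.ndim == 2:
        pass
    ids = ids or [f"h{i}" for i in range(len(points))]
    return pd.DataFrame(points, index=ids)


def brute_force_agnes(X, linkage="average", metric="manhattan"):
    """Naive agglomeration recomputing all cluster distances each step."""

    def dist(a, b):
        d = np.abs(X[a] - X[b]).sum() if metric == "manhattan" else np.sqrt(((X[a] - X[b]) ** 2).sum())
        return d

    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            pair = [dist(a, b) for a in clusters[i] for b in clusters[j]]
            if linkage == "average":
                d = float(np.mean(pair))
            elif linkage == "single":
                d = float(np.min(pair))
            else:
                d = float(np.max(pair))
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)


class TestAgnes:
    def test_two_points_merge_at_their_distance(self):
        for linkage in ("average", "single", "complete"):
            d = agnes_cluster(frame([[0, 0], [1, 2]]), linkage=linkage)
            assert d.heights[0] == pytest.approx(3.0)  # L1 distance

    def test_three_collinear_points_average_linkage(self):
        """Points 0, 1, 10: pair joins first, then merges at (10+9)/2."""
        d = agnes_cluster(frame([[0.0], [1.0], [10.0]]))
        np.testing.assert_allclose(d.heights, [1.0, 9.5])
        a, b, _ = d.merges[0]
        assert {a, b} == {0, 1}

    def test_duplicate_points_merge_at_zero(self):
        d = agnes_cluster(frame([[1.0], [1.0], [5.0]]))
        assert d.heights[0] == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(HowlIdError):
            agnes_cluster(frame([[0.0]]))

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    def test_brute_force_oracle_small_datasets(self, rng, linkage):
        """Merge heights match naive agglomeration on 200 random draws."""
        for _ in range(200):
            n = int(rng.integers(2, 7))
            X = rng.standard_normal((n, 2)) * 3
            d = agnes_cluster(frame(X), linkage=linkage)
            want = brute_force_agnes(X, linkage=linkage)
            np.testing.assert_allclose(np.sort(d.heights), np.sort(want), atol=1e-9)

    def test_matches_scipy_linkage_heights(self, rng):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        X = rng.standard_normal((15, 2)) * 4
        d = agnes_cluster(frame(X))
        Z = scipy_linkage(X, method="average", metric="cityblock")
        np.testing.assert_allclose(np.sort(d.heights), np.sort(Z[:, 2]), atol=1e-9)

    def test_heights_non_decreasing(self, rng):
        X = rng.standard_normal((20, 3))
        d = agnes_cluster(frame(X))
        assert np.all(np.diff(d.heights) >= -1e-12)

    def test_row_order_permutation_invariance(self, rng):
        X = rng.standard_normal((10, 2))
        ids = [f"h{i}" for i in range(10)]
        d1 = agnes_cluster(frame(X, ids))
        perm = rng.permutation(10)
        d2 = agnes_cluster(frame(X[perm], [ids[i] for i in perm]))
        np.testing.assert_allclose(np.sort(d1.heights), np.sort(d2.heights), atol=1e-12)
        # the flat clustering is identical too
        a1 = cut_dendrogram(d1, 2.0).as_series().sort_index()
        a2 = cut_dendrogram(d2, 2.0).as_series().sort_index()
        # cluster indices may differ; compare the induced partitions
        part1 = a1.groupby(a1).groups
        part2 = a2.groupby(a2).groups
        assert sorted(map(sorted, part1.values())) == sorted(map(sorted, part2.values()))

    def test_mad_scale_is_batch_invariant(self, rng):
        X = rng.standard_normal((12, 2))
        d1 = agnes_cluster(frame(X), height_scale="mad")
        d2 = agnes_cluster(frame(7.5 * X), height_scale="mad")
        np.testing.assert_allclose(d1.heights, d2.heights, atol=1e-9)

    def test_nn_scale_is_batch_invariant(self, rng):
        X = rng.standard_normal((12, 2))
        d1 = agnes_cluster(frame(X), height_scale="nn")
        d2 = agnes_cluster(frame(7.5 * X), height_scale="nn")
        np.testing.assert_allclose(d1.heights, d2.heights, atol=1e-9)


class TestCut:
    def dend(self):
        return agnes_cluster(frame([[0.0], [1.0], [10.0]]))

    def test_zero_height_gives_singletons(self):
        a = cut_dendrogram(self.dend(), 0.0)
        assert a.n_clusters == 3

    def test_cut_above_root_gives_one_cluster(self):
        a = cut_dendrogram(self.dend(), 100.0)
        assert a.n_clusters == 1

    def test_mid_cut_separates_far_point(self):
        a = cut_dendrogram(self.dend(), 5.0)
        s = a.as_series()
        assert s["h0"] == s["h1"] != s["h2"]

    def test_negative_height_rejected(self):
        with pytest.raises(HowlIdError):
            cut_dendrogram(self.dend(), -1.0)

    def test_cluster_count_monotone_in_height(self, rng):
        X = rng.standard_normal((15, 2))
        d = agnes_cluster(frame(X))
        ks = [cut_dendrogram(d, h).n_clusters for h in np.linspace(0, d.heights[-1] + 1, 30)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_cut_to_k(self, rng):
        X = rng.standard_normal((15, 2))
        d = agnes_cluster(frame(X))
        for k in (1, 3, 15):
            assert cut_to_k(d, k).n_clusters == k

    def test_clusters_numbered_by_first_leaf(self):
        a = cut_dendrogram(self.dend(), 5.0)
        assert a.as_series()["h0"] == 1


class TestEvaluate:
    def test_perfect_clustering_is_diagonal(self):
        d = agnes_cluster(frame([[0.0], [0.1], [10.0], [10.1], [20.0], [20.1]]))
        a = cut_dendrogram(d, 1.0)
        labels = dict(zip(a.howl_ids, ["A", "A", "B", "B", "C", "C"]))
        cm = evaluate_identification(a, labels)
        assert cm.accuracy == 1.0
        assert (cm.counts.to_numpy() == 2 * np.eye(3)).all()

    def test_published_confusion_counts_give_75_percent(self):
        """The printed test-batch confusion: 15 of 20 howls correct."""
        table = {
            "BMT.A": [2, 1, 1, 0],
            "BMT.SA2": [0, 4, 0, 0],
            "CG2.A2": [0, 0, 7, 0],
            "NU.A": [0, 1, 2, 2],
        }
        howl_ids, clusters, labels = [], [], {}
        i = 0
        for ind, row in table.items():
            for cluster, count in enumerate(row, start=1):
                for _ in range(count):
                    hid = f"h{i}"
                    howl_ids.append(hid)
                    clusters.append(cluster)
                    labels[hid] = ind
                    i += 1
        from howlid import ClusterAssignment

        a = ClusterAssignment(tuple(howl_ids), np.array(clusters))
        cm = evaluate_identification(a, labels)
        assert cm.accuracy == pytest.approx(0.75)
        assert cm.n_correct == 15
        assert cm.total == 20
        # row percentages for the diagonal
        assert cm.row_percent.loc["BMT.A", "BMT.A"] == pytest.approx(50.0)
        assert cm.row_percent.loc["NU.A", "NU.A"] == pytest.approx(40.0)

    def test_plurality_mapping(self):
        from howlid import ClusterAssignment

        a = ClusterAssignment(("h0", "h1", "h2"), np.array([1, 1, 1]))
        cm = evaluate_identification(a, {"h0": "A", "h1": "A", "h2": "B"})
        assert cm.cluster_map[1] == "A"
        assert cm.accuracy == pytest.approx(2 / 3)

    def test_one_to_one_penalises_split_clusters(self):
        from howlid import ClusterAssignment

        a = ClusterAssignment(("h0", "h1", "h2", "h3"), np.array([1, 2, 3, 3]))
        labels = {"h0": "A", "h1": "A", "h2": "B", "h3": "B"}
        plur = evaluate_identification(a, labels)
        strict = evaluate_identification(a, labels, one_to_one=True)
        assert plur.accuracy == 1.0
        assert strict.accuracy == pytest.approx(0.75)

    def test_missing_label_rejected(self):
        from howlid import ClusterAssignment

        a = ClusterAssignment(("h0", "h1"), np.array([1, 2]))
        with pytest.raises(HowlIdError):
            evaluate_identification(a, {"h0": "A"})


class TestCountAndCalibration:
    def test_count_individuals(self):
        d = agnes_cluster(frame([[0.0], [0.2], [9.0], [9.3]]))
        assert count_individuals(cut_dendrogram(d, 1.0)) == 2
        assert count_individuals(cut_dendrogram(d, 0.0)) == 4

    def test_calibrated_cut_recovers_known_grouping(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        X = np.vstack([c + 0.5 * rng.standard_normal((5, 2)) for c in centers])
        ids = [f"h{i}" for i in range(20)]
        labels = {f"h{i}": f"W{i // 5}" for i in range(20)}
        d = agnes_cluster(frame(X, ids))
        cut = calibrate_cut_height(d, labels)
        a = cut_dendrogram(d, cut)
        assert a.n_clusters == 4
        assert evaluate_identification(a, labels).accuracy == 1.0


class TestNewick:
    def test_newick_parses_with_dendropy(self, rng):
        import dendropy

        X = rng.standard_normal((8, 2))
        ids = [f"howl {i}" for i in range(8)]
        d = agnes_cluster(frame(X, ids))
        tree = dendropy.Tree.get(data=d.to_newick(), schema="newick")
        # newick reads unquoted underscores back as spaces
        taxa = sorted(t.label for t in tree.taxon_namespace)
        assert taxa == sorted(ids)
        # root height is reproduced by the leaf depths
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert max(depths) == pytest.approx(d.heights[-1], abs=1e-6)

    def test_linkage_matrix_shape(self, rng):
        X = rng.standard_normal((6, 2))
        Z = agnes_cluster(frame(X)).to_linkage()
        assert Z.shape == (5, 4)
        assert Z[-1, 3] == 6
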