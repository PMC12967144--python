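import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vemmorph.spatial_stats import (
    build_network,
    com_distance,
    displacement_from_center,
    distance_matrix,
    gmm_cluster,
    kmeans_silhouette,
    nn_within_clusters,
    radial_ranking,
)
from vemmorph.volio import Point3D


def _pts(coords):
    return {i + 1: Point3D(*c) for i, c in enumerate(coords)}


class TestDistances:
    def test_three_four_five(self):
        assert com_distance(Point3D(0, 0, 0), Point3D(3, 4, 0)) == 5.0

    def test_self_distance_zero(self):
        p = Point3D(1.5, -2.5, 7.0)
        assert com_distance(p, p) == 0.0

    def test_random_pairs_match_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.uniform(-1e4, 1e4, (2, 3))
            expect = np.sqrt(((a - b) ** 2).sum())
            assert com_distance(Point3D(*a), Point3D(*b)) == pytest.approx(expect)

    def test_displacement_units(self):
        assert displacement_from_center(Point3D(0, 0, 0), Point3D(0, 0, 0)) == 0.0
        assert displacement_from_center(Point3D(2500, 0, 0), Point3D(0, 0, 0)) == 2.5


class TestDistanceMatrix:
    def test_two_objects(self):
        dm = distance_matrix(_pts([(0, 0, 0), (0, 0, 10)]))
        assert dm.matrix.shape == (2, 2)
        assert dm.matrix[0, 1] == 10.0

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 1e4, (10, 3))
        dm = distance_matrix(_pts(coords))
        for i, j in itertools.product(range(10), repeat=2):
            brute = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            assert dm.matrix[i, j] == pytest.approx(brute)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_relabelling_equivariance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 1e4, (6, 3))
        dm = distance_matrix(_pts(coords))
        perm = [3, 1, 5, 0, 4, 2]
        permuted = {i + 10: Point3D(*coords[p]) for i, p in enumerate(perm)}
        dm2 = distance_matrix(permuted)
        assert np.allclose(dm2.matrix, dm.matrix[np.ix_(perm, perm)])

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            distance_matrix(_pts([(0, 0, 0)]))


class TestRadialRanking:
    def test_decreasing_volumes_keep_order(self):
        df = pd.DataFrame(
            {
                "object_id": [1, 2, 3],
                "volume": [9.0, 5.0, 2.0],
                "com_x_nm": [0, 1000, 2000],
                "com_y_nm": [0, 0, 0],
                "com_z_nm": [0, 0, 0],
            }
        )
        out = radial_ranking(df, Point3D(0, 0, 0))
        assert out["object_id"].tolist() == [1, 2, 3]
        assert out["rank"].tolist() == [1, 2, 3]
        assert out["distance_um"].tolist() == [0.0, 1.0, 2.0]

    def test_single_chromosome(self):
        df = pd.DataFrame(
            {"object_id": [7], "volume": [1.0], "com_x_nm": [500], "com_y_nm": [0], "com_z_nm": [0]}
        )
        out = radial_ranking(df, Point3D(0, 0, 0))
        assert len(out) == 1 and out.loc[0, "rank"] == 1


def _mutual_knn_bruteforce(mat, k):
    n = len(mat)
    knn = []
    for i in range(n):
        order = sorted((mat[i, j], j) for j in range(n) if j != i)
        knn.append({j for _, j in order[:k]})
    return {(i, j) for i in range(n) for j in range(i + 1, n) if j in knn[i] and i in knn[j]}


class TestNetwork:
    def test_two_nodes_single_edge(self):
        dm = distance_matrix(_pts([(0, 0, 0), (5, 0, 0)]))
        g = build_network(dm, k=1)
        assert set(g.edges) == {(1, 2)}

    def test_collinear_equidistant_mutual_nn(self):
        # middle point's single NN is ambiguous; stable tie-break picks the
        # lower index, so only one adjacent pair is mutual
        dm = distance_matrix(_pts([(0, 0, 0), (10, 0, 0), (20, 0, 0)]))
        g = build_network(dm, k=1)
        edges = {tuple(sorted(e)) for e in g.edges}
        brute = {(a + 1, b + 1) for a, b in _mutual_knn_bruteforce(dm.matrix, 1)}
        # brute-force with the same tie-break: NN of middle = index 0
        assert edges == {(1, 2)} == brute

    @pytest.mark.parametrize("n,k", [(5, 2), (8, 3), (10, 4)])
    def test_matches_exhaustive_enumeration(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        coords = rng.uniform(0, 1e4, (n, 3))
        dm = distance_matrix(_pts(coords))
        g = build_network(dm, k=k)
        edges = {tuple(sorted((a - 1, b - 1))) for a, b in g.edges}
        assert edges == _mutual_knn_bruteforce(dm.matrix, k)
        assert max(dict(g.degree).values()) <= k

    def test_edges_monotone_in_k(self):
        rng = np.random.default_rng(3)
        dm = distance_matrix(_pts(rng.uniform(0, 1e4, (9, 3))))
        prev = set()
        for k in range(1, 8):
            edges = {tuple(sorted(e)) for e in build_network(dm, k=k).edges}
            assert prev <= edges
            prev = edges

    def test_k_too_large_errors(self):
        dm = distance_matrix(_pts([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))
        with pytest.raises(ValueError):
            build_network(dm, k=3)

    def test_threshold_rule(self):
        dm = distance_matrix(_pts([(0, 0, 0), (5, 0, 0), (100, 0, 0)]))
        g = build_network(dm, rule="threshold", threshold_nm=10)
        assert set(g.edges) == {(1, 2)}


def _blobs(k, n_per, sigma=100.0, seed=0):
    base = {
        2: np.array([[0, 0, 0], [1, 0, 0]]),
        3: np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]),
        4: np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                     [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]]),
    }[k]
    rng = np.random.default_rng(seed)
    centers = base * 10 * sigma  # pairwise separation exactly 10 sigma
    pts = np.vstack([c + rng.normal(0, sigma, (n_per, 3)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


class TestKmeansSilhouette:
    def test_three_blobs_recovered_with_pure_labels(self):
        pts, truth = _blobs(3, 20, seed=1)
        cr = kmeans_silhouette(pts, range(2, 7), seed=1)
        assert cr.k == 3
        # label purity: every found cluster maps to one planted blob
        for lab in range(3):
            members = truth[cr.labels == lab]
            assert len(np.unique(members)) == 1

    def test_two_blobs(self):
        pts, _ = _blobs(2, 20, seed=2)
        assert kmeans_silhouette(pts, range(2, 6), seed=2).k == 2

    def test_determinism_for_fixed_seed(self):
        pts, _ = _blobs(3, 15, seed=4)
        a = kmeans_silhouette(pts, range(2, 6), seed=42)
        b = kmeans_silhouette(pts, range(2, 6), seed=42)
        assert a.k == b.k and np.array_equal(a.labels, b.labels)
        assert a.scores == b.scores

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            kmeans_silhouette(np.zeros((2, 3)), seed=0)

    def test_degenerate_configuration_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_silhouette(np.ones((10, 3)), seed=0)


class TestGmm:
    def test_two_separated_blobs_by_bic(self):
        pts, _ = _blobs(2, 60, seed=3)
        cr = gmm_cluster(pts, max_components=5, seed=3)
        assert cr.k == 2

    def test_single_component_trivial(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 100, (20, 3))
        cr = gmm_cluster(pts, max_components=1, seed=0)
        assert cr.k == 1 and len(np.unique(cr.labels)) == 1

    def test_sex_cluster_membership_reported(self):
        pts, truth = _blobs(2, 30, seed=5)
        ids = list(range(1, len(pts) + 1))
        cr = gmm_cluster(pts, max_components=4, seed=5, sex_labels={1: "X"}, object_ids=ids)
        members = cr.sex_cluster_members["X"]
        # co-members of X's cluster are the members of X's planted blob
        assert set(members) == {i for i, t in zip(ids, truth) if t == truth[0]}


class TestNnWithin:
    def test_pair_shares_distance(self):
        d, flags = nn_within_clusters(np.array([[0, 0, 0], [3000, 0, 0]]), [0, 0])
        assert d.tolist() == [3.0, 3.0]
        assert not flags.any()

    def test_singleton_flagged(self):
        d, flags = nn_within_clusters(np.array([[0, 0, 0], [1, 1, 1]]), [0, 1])
        assert np.isnan(d).all() and flags.all()

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1e4, (15, 3))
        labels = rng.integers(0, 3, 15)
        d, flags = nn_within_clusters(pts, labels)
        for i in range(15):
            same = [j for j in range(15) if labels[j] == labels[i] and j != i]
            if not same:
                assert flags[i] and np.isnan(d[i])
            else:
                brute = min(np.sqrt(((pts[i] - pts[j]) ** 2).sum()) for j in same) / 1000
                assert d[i] == pytest.approx(brute)
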