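import numpy as np
import pytest
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from epibin.cluster import (
    ClusteringParams,
    agglomerative_cluster,
    butina_cluster,
    dbscan_cluster,
    greedy_cluster,
    run_pipeline,
)
from epibin.evaluate import adjusted_rand_index
from epibin.synthetic import SceneParams, generate_scene

from conftest import labels_to_sets, make_dm, partition_sets, random_dm


def scipy_threshold_clustering(matrix, threshold, method):
    """Independent hierarchical-clustering oracle cut at a distance threshold."""
    Z = linkage(squareform(matrix, checks=False), method=method)
    labels = fcluster(Z, t=threshold, criterion="distance")
    return labels_to_sets(labels)


def eps_graph_components(matrix, eps):
    """DBSCAN(min_samples=2) reference: connected components of the eps-graph."""
    n = matrix.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] <= eps:
                g.add_edge(i, j)
    return frozenset(frozenset(c) for c in nx.connected_components(g))


TRIPLE = make_dm([[0.0, 1.0, 1.2], [1.0, 0.0, 1.4], [1.2, 1.4, 0.0]])


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError, match="algorithm"):
            ClusteringParams(algorithm="kmeans")
        with pytest.raises(ValueError, match="threshold"):
            ClusteringParams(rmsd_threshold=0.0)
        with pytest.raises(ValueError, match="linkage"):
            ClusteringParams(linkage="ward")
        with pytest.raises(ValueError, match="min_samples"):
            ClusteringParams(min_samples=1)


class TestGreedy:
    def test_all_far_gives_singletons(self):
        dm = make_dm(np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]]))
        assert partition_sets(greedy_cluster(dm, 1.25)) == frozenset(
            {frozenset({0}), frozenset({1}), frozenset({2})})

    def test_hand_trace_order_123(self):
        assert partition_sets(greedy_cluster(TRIPLE, 1.25)) == frozenset({frozenset({0, 1, 2})})

    def test_hand_trace_order_312_shows_order_dependence(self):
        # same distances presented with member 3 first
        reordered = make_dm([[0.0, 1.2, 1.4], [1.2, 0.0, 1.0], [1.4, 1.0, 0.0]])
        assert partition_sets(greedy_cluster(reordered, 1.25)) == frozenset(
            {frozenset({0, 1}), frozenset({2})})

    def test_threshold_is_strict(self):
        dm = make_dm([[0.0, 1.25], [1.25, 0.0]])
        assert partition_sets(greedy_cluster(dm, 1.25)) == frozenset(
            {frozenset({0}), frozenset({1})})

    def test_center_radius_property(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            dm = random_dm(rng, int(rng.integers(2, 20)))
            for cluster in greedy_cluster(dm, 1.25):
                center = cluster[0]
                assert all(dm.rmsd[center, m] < 1.25 for m in cluster[1:])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            greedy_cluster(TRIPLE, 0.0)


class TestAgglomerative:
    def test_boundary_distance_merges(self):
        dm = make_dm([[0.0, 1.25], [1.25, 0.0]])
        assert partition_sets(agglomerative_cluster(dm, 1.25, "complete")) == frozenset(
            {frozenset({0, 1})})

    def test_hand_trace_complete(self):
        assert partition_sets(agglomerative_cluster(TRIPLE, 1.25, "complete")) == frozenset(
            {frozenset({0, 1}), frozenset({2})})

    def test_hand_trace_single(self):
        assert partition_sets(agglomerative_cluster(TRIPLE, 1.25, "single")) == frozenset(
            {frozenset({0, 1, 2})})

    def test_unknown_linkage_errors(self):
        with pytest.raises(ValueError, match="linkage"):
            agglomerative_cluster(TRIPLE, 1.25, "ward")

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_matches_scipy_oracle(self, method):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 20))
            dm = random_dm(rng, n)
            for t in (0.75, 1.25, 2.0):
                ours = partition_sets(agglomerative_cluster(dm, t, method))
                assert ours == scipy_threshold_clustering(dm.rmsd, t, method)

    def test_complete_linkage_radius_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            dm = random_dm(rng, int(rng.integers(2, 25)))
            for cluster in agglomerative_cluster(dm, 1.25, "complete"):
                idx = np.array(cluster)
                assert dm.rmsd[np.ix_(idx, idx)].max() <= 1.25 + 1e-12


class TestDbscan:
    def test_chain_merges_through_density(self):
        dm = make_dm([[0.0, 1.0, 1.9], [1.0, 0.0, 1.0], [1.9, 1.0, 0.0]])
        assert partition_sets(dbscan_cluster(dm, 1.25, 2)) == frozenset({frozenset({0, 1, 2})})

    def test_all_far_gives_singletons(self):
        dm = make_dm(np.array([[0, 2.0, 3.0], [2.0, 0, 2.5], [3.0, 2.5, 0]]))
        assert len(dbscan_cluster(dm, 1.0, 2)) == 3

    def test_planted_two_blobs(self):
        m = np.full((6, 6), 5.0)
        for blk in (range(0, 3), range(3, 6)):
            for i in blk:
                for j in blk:
                    m[i, j] = 0.0 if i == j else 0.5
        assert partition_sets(dbscan_cluster(make_dm(m), 1.0, 2)) == frozenset(
            {frozenset({0, 1, 2}), frozenset({3, 4, 5})})

    def test_min_samples_two_equals_graph_components(self):
        rng = np.random.default_rng(3)
        for n in range(2, 13):
            for _ in range(5):
                dm = random_dm(rng, n, scale=2.5)
                ours = partition_sets(dbscan_cluster(dm, 1.0, 2))
                assert ours == eps_graph_components(dm.rmsd, 1.0)

    def test_higher_min_samples_marks_sparse_points_noise(self):
        # a pair is dense enough for min_samples=2 but not 3
        dm = make_dm([[0.0, 0.5], [0.5, 0.0]])
        assert len(dbscan_cluster(dm, 1.0, 3)) == 2

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            dbscan_cluster(TRIPLE, -1.0, 2)
        with pytest.raises(ValueError):
            dbscan_cluster(TRIPLE, 1.0, 1)


class TestButina:
    def test_singleton(self):
        assert butina_cluster(make_dm([[0.0]]), 1.0) == [[0]]

    def test_star_graph(self):
        m = np.full((5, 5), 2.0)
        np.fill_diagonal(m, 0.0)
        m[0, 1:] = m[1:, 0] = 0.5
        assert partition_sets(butina_cluster(make_dm(m), 1.0)) == frozenset(
            {frozenset({0, 1, 2, 3, 4})})

    def test_two_disjoint_stars(self):
        m = np.full((8, 8), 5.0)
        np.fill_diagonal(m, 0.0)
        for center, leaves in ((0, (1, 2, 3)), (4, (5, 6, 7))):
            for leaf in leaves:
                m[center, leaf] = m[leaf, center] = 0.5
        assert partition_sets(butina_cluster(make_dm(m), 1.0)) == frozenset(
            {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})})

    def test_reorder_recounts_after_exclusion(self):
        # round 1 assigns {0,1,2,3,4}; among the rest, 5 keeps a stale
        # neighbour count of 4 (neighbours mostly consumed) while a recount
        # makes 6 (two live neighbours) the better centroid
        m = np.full((8, 8), 9.0)
        np.fill_diagonal(m, 0.0)
        edges = [(0, 1), (0, 2), (0, 3), (0, 4),
                 (5, 1), (5, 2), (5, 3), (5, 6), (6, 7)]
        for i, j in edges:
            m[i, j] = m[j, i] = 0.5
        plain = partition_sets(butina_cluster(make_dm(m), 1.0, reorder=False))
        reordered = partition_sets(butina_cluster(make_dm(m), 1.0, reorder=True))
        assert plain == frozenset({frozenset({0, 1, 2, 3, 4}),
                                   frozenset({5, 6}), frozenset({7})})
        assert reordered == frozenset({frozenset({0, 1, 2, 3, 4}),
                                       frozenset({5, 6, 7})})


class TestPartitionAndDeterminism:
    @pytest.mark.parametrize("algorithm", ["greedy", "agglomerative", "dbscan", "butina"])
    def test_every_algorithm_returns_a_partition(self, algorithm):
        from epibin.cluster import cluster_matrix

        rng = np.random.default_rng(99)
        params = ClusteringParams(algorithm=algorithm, rmsd_threshold=1.0)
        for _ in range(20):
            dm = random_dm(rng, int(rng.integers(1, 25)), scale=2.0)
            clusters = cluster_matrix(dm, params)
            flat = sorted(i for c in clusters for i in c)
            assert flat == list(range(len(dm.group)))

    def test_monotone_coverage_single_linkage(self):
        # single-linkage multi-occupancy membership equals the non-isolated
        # vertices of the eps-graph, which grows with the threshold
        rng = np.random.default_rng(17)
        for _ in range(10):
            dm = random_dm(rng, 18, scale=2.5)
            covered = []
            for t in (0.25, 0.5, 1.0, 1.5, 2.0, 3.0):
                clusters = agglomerative_cluster(dm, t, "single")
                covered.append(sum(len(c) for c in clusters if len(c) > 1))
            assert covered == sorted(covered)

    def test_monotone_coverage_greedy_on_planted_fixture(self, default_scene):
        # greedy coverage is order-sensitive in general; on well-separated
        # planted matrices it grows with the threshold
        from epibin.geometry import build_length_groups, pairwise_rmsd_matrix

        models = {m.antibody_id: m for m in default_scene.models}
        group = build_length_groups(default_scene.models, default_scene.scheme)[0]
        dm = pairwise_rmsd_matrix(group, models, default_scene.scheme)
        covered = []
        for t in (0.1, 0.4, 0.75, 1.25, 3.0, 8.0):
            clusters = greedy_cluster(dm, t)
            covered.append(sum(len(c) for c in clusters if len(c) > 1))
        assert covered == sorted(covered)

    def test_identical_inputs_identical_output(self, default_scene):
        a1 = run_pipeline(default_scene.models, default_scene.scheme)
        a2 = run_pipeline(default_scene.models, default_scene.scheme)
        assert a1.assignments == a2.assignments


class TestPipeline:
    def test_empty_model_set(self, scheme):
        assignment = run_pipeline([], scheme)
        assert assignment.assignments == {}

    def test_default_configuration_recovers_planted_truth(self, default_scene):
        assignment = run_pipeline(default_scene.models, default_scene.scheme)
        ari = adjusted_rand_index(assignment.assignments, default_scene.truth)
        assert ari == pytest.approx(1.0)
        # cross-check our ARI against the sklearn implementation
        ids = sorted(assignment.assignments)
        ours = adjusted_rand_index(assignment.assignments, default_scene.truth)
        ref = adjusted_rand_score([default_scene.truth[i] for i in ids],
                                  [assignment.assignments[i] for i in ids])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_greedy_configuration_center_radius(self, default_scene):
        from epibin.geometry import build_length_groups, pairwise_rmsd_matrix

        params = ClusteringParams(algorithm="greedy", rmsd_threshold=0.75)
        assignment = run_pipeline(default_scene.models, default_scene.scheme, params)
        models = {m.antibody_id: m for m in default_scene.models}
        for group in build_length_groups(default_scene.models, default_scene.scheme):
            dm = pairwise_rmsd_matrix(group, models, default_scene.scheme)
            idx = {ab: i for i, ab in enumerate(group.members)}
            clusters = {}
            for ab in group.members:
                clusters.setdefault(assignment.assignments[ab], []).append(ab)
            for members in clusters.values():
                center = members[0]  # first member in input order is the center
                for m in members[1:]:
                    assert dm.rmsd[idx[center], idx[m]] < 0.75

    def test_cluster_ids_namespaced_by_group_key(self, scheme):
        keys = ((8, 7, 12, 9, 6, 8), (8, 7, 13, 9, 6, 8))
        scene = generate_scene(SceneParams(n_clusters=2, members_per_cluster=3,
                                           length_keys=keys, seed=5))
        assignment = run_pipeline(scene.models, scheme)
        for ab, cid in assignment.assignments.items():
            assert cid.startswith(assignment.group_keys[ab] + ":")
        assert len(assignment.clusters()) == 2

    def test_heavy_chain_mode_groups_by_heavy_lengths_only(self, scheme):
        # two length keys differing only in the light chain collapse in HC mode
        keys = ((8, 7, 12, 9, 6, 8), (8, 7, 12, 10, 6, 8))
        scene = generate_scene(SceneParams(n_clusters=2, members_per_cluster=3,
                                           min_between=5.0, length_keys=keys, seed=6))
        full = run_pipeline(scene.models, scheme)
        assert len(set(full.group_keys.values())) == 2
        hc = run_pipeline(scene.models, scheme, cdr_subset="heavy")
        assert len(set(hc.group_keys.values())) == 1
        # heavy CDRs were planted apart, so HC mode still separates the clusters
        assert adjusted_rand_index(hc.assignments, scene.truth) == pytest.approx(1.0)

    def test_paratope_mode_groups_by_flag_sets(self, default_scene):
        ids = [m.antibody_id for m in default_scene.models]
        flags = {ab: (("CDRH3", "CDRL3") if i % 2 == 0 else ("CDRH1", "CDRH3"))
                 for i, ab in enumerate(ids)}
        assignment = run_pipeline(default_scene.models, default_scene.scheme,
                                  cdr_subset="paratope", paratope_flags=flags)
        # antibodies with different paratope-CDR sets can never share a cluster
        for cid, members in assignment.clusters().items():
            assert len({flags[m] for m in members}) == 1

    def test_paratope_mode_requires_flags(self, default_scene):
        with pytest.raises(ValueError, match="paratope_flags"):
            run_pipeline(default_scene.models, default_scene.scheme, cdr_subset="paratope")

    def test_assignment_frame_columns(self, default_scene):
        assignment = run_pipeline(default_scene.models, default_scene.scheme)
        df = assignment.to_frame()
        assert list(df.columns) == ["id", "cluster_id", "cluster_size",
                                    "group_key", "algorithm", "threshold"]
        assert len(df) == len(default_scene.models)
        assert (df["cluster_size"] == 6).all()
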