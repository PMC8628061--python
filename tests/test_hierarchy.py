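import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from treekor.clustering import use_precomputed_labels
from treekor.hierarchy import (ClusterProfile, build_tree_agglomerative,
                               build_tree_hopach, cluster_profiles, export_newick,
                               mss, pam_brute_force, pam_partition)
from treekor.io import EventTable

from oracles import lance_williams_merges, mss_reference

LINKAGES = ["average", "ward", "single", "complete", "mcquitty"]


def profile_from_points(X):
    X = np.asarray(X, dtype=float)
    return ClusterProfile(
        medians_raw=X, medians_scaled=X,
        cluster_ids=[f"c{i}" for i in range(len(X))],
        marker_names=[f"M{j}" for j in range(X.shape[1])],
        cluster_sizes=np.ones(len(X), dtype=int),
        scaling_method="minmax")


class TestClusterProfiles:
    def test_even_count_median_and_minmax_endpoints(self):
        values = np.array([[1.0], [3.0], [6.0], [6.0]])
        events = EventTable(values=values, marker_names=["M"],
                            sample_ids=["s"] * 4, transformed=True)
        asg = use_precomputed_labels(events, ["a", "a", "b", "b"])
        prof = cluster_profiles(events, asg, scaling="minmax")
        np.testing.assert_allclose(prof.medians_raw[:, 0], [2.0, 6.0])
        np.testing.assert_allclose(prof.medians_scaled[:, 0], [0.0, 1.0])

    def test_constant_column_scales_to_half(self):
        values = np.array([[1.0, 2.0], [1.0, 5.0]])
        events = EventTable(values=values, marker_names=["M0", "M1"],
                            sample_ids=["s", "s"], transformed=True)
        asg = use_precomputed_labels(events, ["a", "b"])
        prof = cluster_profiles(events, asg)
        np.testing.assert_allclose(prof.medians_scaled[:, 0], [0.5, 0.5])

    def test_zscore_matches_direct_computation(self, rng):
        values = rng.normal(size=(50, 3))
        labels = rng.integers(0, 5, size=50).astype(str)
        labels[:5] = [str(i) for i in range(5)]  # all clusters non-empty
        events = EventTable(values=values, marker_names=["a", "b", "c"],
                            sample_ids=["s"] * 50, transformed=True)
        asg = use_precomputed_labels(events, labels)
        prof = cluster_profiles(events, asg, scaling="zscore")
        med = prof.medians_raw
        expected = (med - med.mean(0)) / med.std(0)
        np.testing.assert_allclose(prof.medians_scaled, expected, atol=1e-12)
        assert np.allclose(prof.medians_scaled.mean(0), 0, atol=1e-9)
        assert np.allclose(prof.medians_scaled.std(0), 1, atol=1e-9)


class TestAgglomerative:
    def test_three_points_average_linkage_by_hand(self):
        prof = profile_from_points([[0.0], [1.0], [10.0]])
        tree = build_tree_agglomerative(prof, "average")
        heights = sorted(tree.nodes[n].height for n in tree.internal())
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(9.5)  # mean of 9 and 10

    def test_two_clusters(self):
        prof = profile_from_points([[0.0, 0.0], [3.0, 4.0]])
        tree = build_tree_agglomerative(prof, "complete")
        assert len(tree.leaves()) == 2
        assert tree.nodes[tree.root].height == pytest.approx(5.0)

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_matches_lance_williams_oracle(self, rng, linkage):
        for trial in range(10):
            n = int(rng.integers(4, 11))
            X = rng.normal(size=(n, 3))
            tree = build_tree_agglomerative(profile_from_points(X), linkage)
            expected = lance_williams_merges(X, linkage)
            exp_heights = sorted(h for _, _, h in expected)
            got_heights = sorted(tree.nodes[m].height for m in tree.internal())
            np.testing.assert_allclose(got_heights, exp_heights, atol=1e-10)
            # topology: every oracle merge appears as a node's leaf set
            idx = {f"c{i}": i for i in range(n)}
            node_sets = {frozenset(idx[str(c)] for c in tree.leaf_clusters(m))
                         for m in tree.internal()}
            for a, b, _ in expected:
                assert (a | b) in node_sets

    def test_heights_monotone_nondecreasing(self, rng):
        X = rng.normal(size=(12, 4))
        for linkage in ["average", "complete", "ward", "mcquitty"]:
            tree = build_tree_agglomerative(profile_from_points(X), linkage)
            for nid in tree.internal():
                for c in tree.children(nid):
                    if not tree.is_leaf(c):
                        assert tree.nodes[c].height <= tree.nodes[nid].height + 1e-12

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_tree_agglomerative(profile_from_points([[1.0]]), "average")

    def test_binary_with_n_minus_one_internal_nodes(self, rng):
        X = rng.normal(size=(9, 2))
        tree = build_tree_agglomerative(profile_from_points(X), "ward")
        assert len(tree.internal()) == 8
        assert all(len(tree.children(n)) == 2 for n in tree.internal())


class TestPAM:
    def test_matches_exhaustive_search_small(self, rng):
        for trial in range(15):
            m = int(rng.integers(4, 8))
            k = int(rng.integers(2, m))
            D = squareform(pdist(rng.normal(size=(m, 2))))
            labels, medoids = pam_partition(D, k)
            _, _, best_cost = pam_brute_force(D, k)
            cost = D[np.arange(m), np.array(medoids)[labels]].sum()
            assert cost == pytest.approx(best_cost, abs=1e-10)

    def test_k_equals_m_minus_one_isolates_closest_pair(self, rng):
        X = rng.normal(size=(6, 2))
        D = squareform(pdist(X))
        labels, _ = pam_partition(D, 5)
        sizes = np.bincount(labels)
        assert sorted(sizes) == [1, 1, 1, 1, 2]
        pair = np.flatnonzero(labels == np.argmax(sizes))
        off = D + np.eye(6) * 1e9
        i, j = np.unravel_index(off.argmin(), off.shape)
        assert set(pair) == {i, j}

    def test_duplicates_cogrouped(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0], [9.0]])
        D = squareform(pdist(X))
        labels, _ = pam_partition(D, 3)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pam_partition(D, 2)  # k < m also violated, symmetric checked first


class TestMSS:
    def test_all_small_groups_score_zero(self):
        D = squareform(pdist(np.arange(4.0).reshape(-1, 1)))
        assert mss(D, np.array([0, 0, 1, 1])) == 0.0

    def test_heterogeneous_groups_score_high(self, rng):
        # two groups, each the union of two tight, far-apart sub-blobs
        blobs = [rng.normal(c, 0.01, size=(5, 2)) for c in
                 [(0, 0), (10, 0), (0, 10), (10, 10)]]
        X = np.vstack(blobs)
        D = squareform(pdist(X))
        part = np.array([0] * 10 + [1] * 10)
        assert mss(D, part, max_sub_k=3) > 0.9

    def test_matches_from_definition_reference(self, rng):
        for trial in range(8):
            m = int(rng.integers(6, 12))
            X = rng.normal(size=(m, 2))
            D = squareform(pdist(X))
            part = rng.integers(0, 2, size=m)
            part[:2] = [0, 1]
            got = mss(D, part, max_sub_k=4)
            want = mss_reference(D, part, max_sub_k=4)
            assert got == pytest.approx(want, abs=1e-12)

    def test_single_group_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            mss(D, np.zeros(3, dtype=int))


class TestHopach:
    def test_root_split_matches_brute_forced_mss_selection(self, rng):
        # 3 tight, mutually distant triplets; the root's child count and
        # composition must equal what exhaustive PAM + from-definition MSS
        # select over the admissible k range
        centers = np.array([[0, 0], [20, 0], [0, 20]], dtype=float)
        X = np.vstack([rng.normal(c, 0.05, size=(3, 2)) for c in centers])
        D = squareform(pdist(X))
        best_k, best_score, best_labels = None, np.inf, None
        for k in range(2, 6):
            labels, _, _ = pam_brute_force(D, k)
            score = mss_reference(D, labels, max_sub_k=5)
            if score < best_score - 1e-12:
                best_k, best_score, best_labels = k, score, labels
        tree = build_tree_hopach(profile_from_points(X), K=5)
        kids = tree.children(tree.root)
        assert len(kids) == best_k
        got = {frozenset(int(str(c)[1:]) for c in tree.leaf_clusters(ch))
               for ch in kids}
        want = {frozenset(np.flatnonzero(best_labels == g).tolist())
                for g in range(best_k)}
        assert got == want
        # children never straddle two triplets
        for ch in kids:
            blobs = {int(str(c)[1:]) // 3 for c in tree.leaf_clusters(ch)}
            assert len(blobs) == 1

    def test_two_items_forced_pair(self):
        tree = build_tree_hopach(profile_from_points([[0.0], [1.0]]), K=5)
        assert len(tree.children(tree.root)) == 2
        assert len(tree.leaves()) == 2

    def test_k2_gives_strictly_binary_tree(self, rng):
        X = rng.normal(size=(10, 3))
        tree = build_tree_hopach(profile_from_points(X), K=2)
        assert all(len(tree.children(n)) == 2 for n in tree.internal())

    def test_children_within_bounds(self, rng):
        X = rng.normal(size=(14, 3))
        tree = build_tree_hopach(profile_from_points(X), K=4)
        for n in tree.internal():
            assert 2 <= len(tree.children(n)) <= 4

    def test_deterministic(self, rng):
        X = rng.normal(size=(12, 3))
        t1 = build_tree_hopach(profile_from_points(X), K=5, seed=1)
        t2 = build_tree_hopach(profile_from_points(X), K=5, seed=1)
        assert t1.to_newick() == t2.to_newick()

    def test_depth1_partition_compatible_with_three_blobs(self, rng):
        # unequal blob spacing so the k=2 cut has a unique natural place;
        # depth-1 groups may merge whole blobs (K=2) or fragment within one
        # (K=5) but must never straddle a blob boundary partially
        centers = np.array([[0, 0], [10, 0], [50, 0]], dtype=float)
        X = np.vstack([rng.normal(c, 0.3, size=(5, 2)) for c in centers])
        blobs = [frozenset(f"c{i}" for i in range(b * 5, b * 5 + 5)) for b in range(3)]
        prof = profile_from_points(X)
        for K in (2, 5):
            tree = build_tree_hopach(prof, K=K)
            for child in tree.children(tree.root):
                group = frozenset(str(c) for c in tree.leaf_clusters(child))
                for blob in blobs:
                    inter = group & blob
                    assert inter in (frozenset(), blob, group)


class TestNewick:
    def test_two_leaf_form(self):
        prof = profile_from_points([[0.0], [2.0]])
        tree = build_tree_agglomerative(prof, "average")
        assert export_newick(tree) == "(c0:2,c1:2)N1;"

    def test_polytomy_preserved_in_newick(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]], dtype=float)
        X = np.vstack([rng.normal(c, 0.05, size=(3, 2)) for c in centers])
        tree = build_tree_hopach(profile_from_points(X), K=5)
        n_root_children = len(tree.children(tree.root))
        assert n_root_children > 2  # a multiway node exists on this fixture
        nwk = export_newick(tree)
        import dendropy
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(parsed.seed_node.child_nodes()) == n_root_children

    @pytest.mark.parametrize("builder", ["average", "hopach"])
    def test_round_trip_preserves_leaf_partitions(self, rng, builder):
        import dendropy

        X = rng.normal(size=(8, 3))
        prof = profile_from_points(X)
        if builder == "hopach":
            tree = build_tree_hopach(prof, K=3)
        else:
            tree = build_tree_agglomerative(prof, builder)
        parsed = dendropy.Tree.get(data=export_newick(tree), schema="newick")
        got = set()
        for node in parsed.preorder_node_iter():
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            got.add(leaves)
        want = {frozenset(str(c) for c in tree.leaf_clusters(n))
                for n in tree.depth_first()}
        assert got == want
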