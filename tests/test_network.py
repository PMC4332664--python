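"""Dendrogram sub-network identification and weighted graph metrics,
checked against hand-computed merges and brute-force triangle counts."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpsnet import (
    average_linkage,
    cut_to_groups,
    event_related_clustering,
    group_connectivity,
    node_distance_matrix,
    weighted_clustering_coefficient,
)
from lpsnet.containers import NetworkPartition


def brute_force_clustering(w: np.ndarray) -> np.ndarray:
    """Independent triangle-enumeration oracle for the weighted
    clustering coefficient (geometric-mean form, weights / max)."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        tot = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    tot += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        out[i] = tot / (k * (k - 1))
    return out


def _block_matrix(rng, sizes=(5, 5), within=0.8, between=0.1, noise=0.02):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    m = np.where(labels[:, None] == labels[None, :], within, between)
    m = m + noise * rng.standard_normal((n, n))
    m = np.clip((m + m.T) / 2, 0, 1)
    np.fill_diagonal(m, 0)
    return m, labels


class TestDistances:
    def test_identical_rows_have_zero_profile_distance(self):
        m = np.array(
            [
                [0.0, 0.5, 0.2, 0.7],
                [0.5, 0.0, 0.2, 0.7],
                [0.2, 0.2, 0.0, 0.1],
                [0.7, 0.7, 0.1, 0.0],
            ]
        )
        d = node_distance_matrix(m, method="profile_correlation")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_one_minus_connectivity_is_complement(self):
        m = np.array([[0.0, 0.3], [0.3, 0.0]])
        d = node_distance_matrix(m, method="one_minus_connectivity")
        assert d[0, 1] == pytest.approx(0.7)

    def test_planted_blocks_separate_within_from_between(self, rng):
        m, labels = _block_matrix(rng)
        d = node_distance_matrix(m, method="profile_correlation")
        within = [d[i, j] for i, j in itertools.combinations(range(10), 2)
                  if labels[i] == labels[j]]
        between = [d[i, j] for i, j in itertools.combinations(range(10), 2)
                   if labels[i] != labels[j]]
        assert max(within) < min(between)

    def test_constant_profile_guarded_with_unit_distance(self):
        m = np.zeros((4, 4))
        m[2, 3] = m[3, 2] = 0.5
        d = node_distance_matrix(m, method="profile_correlation")
        assert d[0, 1] == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            node_distance_matrix(np.zeros((3, 3)), method="euclid")


class TestAverageLinkage:
    def test_three_point_forced_merge_order(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        dend = average_linkage(d)
        assert dend.linkage[0, 2] == pytest.approx(1.0)
        assert dend.linkage[1, 2] == pytest.approx(5.0)
        assert set(dend.linkage[0, :2]) == {0.0, 1.0}

    def test_four_leaf_hand_computed_upgma(self):
        # d12=1, d34=2, all cross distances 10: merges (1,2)@1, (3,4)@2,
        # then the two pairs at the unweighted mean of member distances, 10
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 2.0
        dend = average_linkage(d)
        np.testing.assert_allclose(dend.linkage[:, 2], [1.0, 2.0, 10.0])

    def test_duplicate_leaf_merges_first_at_zero_height(self):
        d = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        dend = average_linkage(d)
        assert dend.linkage[0, 2] == 0.0
        assert set(dend.linkage[0, :2]) == {0.0, 1.0}

    def test_nan_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            average_linkage(d)

    def test_newick_export_contains_all_labels(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        dend = average_linkage(d, labels=["a", "b", "c"])
        nwk = dend.to_newick()
        assert nwk.endswith(";") and all(x in nwk for x in "abc")


class TestCutToGroups:
    def test_trivial_cuts(self, rng):
        m, _ = _block_matrix(rng)
        dend = average_linkage(node_distance_matrix(m))
        assert cut_to_groups(dend, 1).K == 1
        assert cut_to_groups(dend, 10).K == 10

    def test_planted_blocks_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m, labels = _block_matrix(rng, sizes=(6, 5, 7, 4))
        for method in ("profile_correlation", "one_minus_connectivity"):
            dend = average_linkage(node_distance_matrix(m, method=method))
            part = cut_to_groups(dend, 4)
            assert adjusted_rand_score(labels, part.labels) == 1.0

    def test_out_of_range_k_rejected(self, rng):
        m, _ = _block_matrix(rng)
        dend = average_linkage(node_distance_matrix(m))
        with pytest.raises(ValueError):
            cut_to_groups(dend, 0)
        with pytest.raises(ValueError):
            cut_to_groups(dend, 11)


class TestGroupConnectivity:
    def test_four_node_enumeration(self):
        w = np.zeros((4, 4))
        pairs = {(0, 1): 0.3, (0, 2): 0.1, (0, 3): 0.2, (1, 2): 0.4, (1, 3): 0.5, (2, 3): 0.6}
        for (i, j), v in pairs.items():
            w[i, j] = w[j, i] = v
        part = NetworkPartition(labels=np.array([0, 0, 1, 1]), K=2)
        stats = group_connectivity(w, part)
        assert stats.intra[0] == pytest.approx(0.3)
        assert stats.intra[1] == pytest.approx(0.6)
        assert stats.inter[(0, 1)] == pytest.approx(0.1 + 0.2 + 0.4 + 0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_conservation_identity_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = rng.integers(0, 4, size=n)
        labels[:4] = [0, 1, 2, 3]  # ensure all groups non-empty
        part = NetworkPartition(labels=labels, K=4)
        stats = group_connectivity(m, part)
        assert stats.total() == pytest.approx(np.triu(m, 1).sum(), abs=1e-10)


class TestClusteringCoefficient:
    def test_complete_triangle_equal_weights_is_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(weighted_clustering_coefficient(w), 1.0)

    def test_star_graph_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        assert not weighted_clustering_coefficient(w).any()

    def test_four_node_case_matches_brute_force(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.5
        w[0, 3] = w[3, 0] = 0.2
        np.testing.assert_allclose(
            weighted_clustering_coefficient(w), brute_force_clustering(w), atol=1e-12
        )

    def test_random_graphs_match_brute_force_and_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.random((10, 10)) * (rng.random((10, 10)) < 0.6)
            w = np.triu(w, 1)
            w = w + w.T
            ours = weighted_clustering_coefficient(w)
            np.testing.assert_allclose(ours, brute_force_clustering(w), atol=1e-10)
            g = nx.from_numpy_array(w)
            nxc = np.array([v for _, v in sorted(nx.clustering(g, weight="weight").items())])
            np.testing.assert_allclose(ours, nxc, atol=1e-10)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_global_rescaling(self, scale):
        rng = np.random.default_rng(7)
        w = rng.random((8, 8))
        w = np.triu(w, 1)
        w = w + w.T
        a = weighted_clustering_coefficient(w)
        b = weighted_clustering_coefficient(scale * w)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_all_zero_matrix_yields_zero_vector(self):
        assert not weighted_clustering_coefficient(np.zeros((5, 5))).any()


class TestEventRelatedClustering:
    def test_equal_vectors_give_zero(self):
        c = np.array([0.2, 0.4])
        assert not event_related_clustering(c, c).any()

    def test_fifty_percent_increase(self):
        base = np.array([0.2, 0.4])
        np.testing.assert_allclose(event_related_clustering(1.5 * base, base), 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            event_related_clustering(np.zeros(3), np.zeros(4))
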