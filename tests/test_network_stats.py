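import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcx.connectivity import FCMatrix
from fcx.network_stats import (
    EdgeSubset,
    cosine_distance,
    distance_variants,
    edge_vector,
    global_efficiency,
    mean_network_fc,
    modularity,
    network_subsets,
    pairing_dissimilarity,
    whole_brain_subset,
)


def fc_from(values):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return FCMatrix(v)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def modularity_oracle(w, labels):
    """Explicit double-sum over the Q definition."""
    w = np.asarray(w, dtype=float)
    two_m = w.sum()  # sum over ordered pairs
    k = w.sum(axis=1)
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += (w[i, j] - k[i] * k[j] / two_m) / two_m
    return q


def efficiency_oracle(w):
    """Exhaustive path enumeration over all simple paths (<= 6 nodes)."""
    n = w.shape[0]
    total = 0.0
    for i, j in itertools.permutations(range(n), 2):
        best = np.inf
        for k in range(n - 1):
            for mids in itertools.permutations([m for m in range(n) if m not in (i, j)], k):
                path = (i, *mids, j)
                length = 0.0
                ok = True
                for a, b in zip(path, path[1:]):
                    if w[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / w[a, b]
                if ok:
                    best = min(best, length)
        if np.isfinite(best):
            total += 1.0 / best
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# Edge subsets and vectorization
# ---------------------------------------------------------------------------


class TestEdgeSubsets:
    def test_whole_brain_length(self):
        fc = fc_from(np.full((4, 4), 0.5))
        assert len(edge_vector(fc, whole_brain_subset(4))) == 6

    def test_two_region_within_subset(self, toy_parcels):
        subsets = network_subsets(toy_parcels)
        assert len(subsets["within:visual"]) == 1
        assert len(subsets["between:visual"]) == 4

    def test_edge_participation_partition(self):
        """Every edge is in exactly one within subset or exactly two between
        subsets (one per endpoint network)."""
        from fcx.synthetic import make_parcel_table

        parcels = make_parcel_table(21)
        subsets = network_subsets(parcels)
        within_count = {}
        between_count = {}
        for name, subset in subsets.items():
            target = within_count if name.startswith("within:") else between_count
            for pair in subset.pairs:
                target[pair] = target.get(pair, 0) + 1
        all_edges = set(whole_brain_subset(21).pairs)
        assert set(within_count) | set(between_count) == all_edges
        assert all(v == 1 for v in within_count.values())
        assert all(v == 2 for v in between_count.values())
        assert not (set(within_count) & set(between_count))

    def test_empty_subset_rejected(self):
        fc = fc_from(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            edge_vector(fc, EdgeSubset("none", ()))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


class TestCosineDistance:
    def test_proportional_gives_zero(self, rng):
        a = rng.standard_normal(20)
        assert cosine_distance(a, 2 * a) == pytest.approx(0.0, abs=1e-15)

    def test_orthogonal_gives_one(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 2.0, -1.0])
        assert cosine_distance(a, b) == pytest.approx(1.0, abs=1e-15)

    def test_forty_five_degrees(self):
        assert cosine_distance([1.0, 1.0], [1.0, 0.0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-15
        )

    def test_antipodal_gives_two(self, rng):
        a = rng.standard_normal(10)
        assert cosine_distance(a, -a) == pytest.approx(2.0, abs=1e-15)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0.0, 0.0], [1.0, 2.0])

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import cosine as scipy_cosine

        a, b = rng.standard_normal((2, 50))
        assert cosine_distance(a, b) == pytest.approx(scipy_cosine(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_symmetry_and_scale_invariance(self, seed, c):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal((2, 12))
        d = cosine_distance(a, b)
        assert cosine_distance(b, a) == pytest.approx(d, abs=1e-12)
        assert cosine_distance(c * a, b) == pytest.approx(d, abs=1e-9)
        assert 0.0 <= d <= 2.0


class TestDistanceVariants:
    def test_identity(self, rng):
        a = rng.standard_normal(10)
        assert distance_variants(a, a, "euclidean") == 0.0
        assert distance_variants(a, a, "pearson_similarity") == pytest.approx(1.0)

    def test_three_four_five(self):
        assert distance_variants([0.0, 3.0], [4.0, 0.0], "euclidean") == pytest.approx(5.0)

    def test_matches_direct_formulas(self, rng):
        a, b = rng.standard_normal((2, 40))
        assert distance_variants(a, b, "euclidean") == pytest.approx(
            np.sqrt(((a - b) ** 2).sum()), abs=1e-12
        )
        am, bm = a - a.mean(), b - b.mean()
        r = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert distance_variants(a, b, "pearson_similarity") == pytest.approx(r, abs=1e-12)


class TestMeanNetworkFC:
    def test_uniform_edges(self):
        fc = fc_from(np.full((4, 4), 0.5))
        subset = whole_brain_subset(4)
        assert mean_network_fc(fc, subset, absolute=True) == pytest.approx(0.5)
        assert mean_network_fc(fc, subset, absolute=False) == pytest.approx(0.5)

    def test_sign_cancellation(self):
        v = np.array([
            [0.0, 0.5, -0.5, 0.5],
            [0.5, 0.0, 0.5, -0.5],
            [-0.5, 0.5, 0.0, -0.5],
            [0.5, -0.5, -0.5, 0.0],
        ])
        fc = fc_from(v)
        subset = whole_brain_subset(4)
        assert mean_network_fc(fc, subset, absolute=True) == pytest.approx(0.5)
        assert mean_network_fc(fc, subset, absolute=False) == pytest.approx(0.0)

    def test_toy_within_between_hand_computed(self, toy_parcels):
        # regions 0,1 visual; 2,3 somatomotor
        v = np.zeros((4, 4))
        vals = {(0, 1): 0.8, (0, 2): 0.1, (0, 3): 0.2, (1, 2): 0.3, (1, 3): 0.4,
                (2, 3): -0.6}
        for (i, j), x in vals.items():
            v[i, j] = v[j, i] = x
        fc = fc_from(v)
        subsets = network_subsets(toy_parcels)
        assert mean_network_fc(fc, subsets["within:visual"]) == pytest.approx(0.8)
        assert mean_network_fc(fc, subsets["within:somatomotor"]) == pytest.approx(0.6)
        assert mean_network_fc(fc, subsets["between:visual"]) == pytest.approx(0.25)
        assert mean_network_fc(fc, subsets["between:visual"], absolute=False) == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------


class TestGraphMetrics:
    def test_two_cliques_modularity_half(self):
        """Two equal disconnected 3-cliques under the clique partition: Q = 0.5."""
        v = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(grp, 2):
                v[i, j] = v[j, i] = 1.0
        fc = fc_from(v)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity(fc, labels) == pytest.approx(0.5, abs=1e-12)
        w = np.abs(v)
        assert modularity_oracle(w, labels) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_zero(self, rng):
        v = np.abs(rng.standard_normal((5, 5)))
        v = (v + v.T) / 2
        fc = fc_from(v)
        assert modularity(fc, np.zeros(5, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_planted_blocks_beat_random_partitions(self, rng):
        v = np.full((8, 8), 0.1)
        for grp in ([0, 1, 2, 3], [4, 5, 6, 7]):
            for i, j in itertools.combinations(grp, 2):
                v[i, j] = v[j, i] = 0.8
        fc = fc_from(v)
        planted = np.array([0] * 4 + [1] * 4)
        q_planted = modularity(fc, planted)
        wins = 0
        for _ in range(100):
            q_rand = modularity(fc, rng.integers(0, 2, 8))
            wins += q_planted >= q_rand
        assert wins == 100

    def test_complete_unit_graph_efficiency_one(self):
        fc = fc_from(np.ones((5, 5)))
        assert global_efficiency(fc) == pytest.approx(1.0, abs=1e-12)

    def test_edgeless_graph_efficiency_zero(self):
        assert global_efficiency(fc_from(np.zeros((4, 4)))) == 0.0

    def test_three_node_chain(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 1.0
        v[1, 2] = v[2, 1] = 1.0
        assert global_efficiency(fc_from(v)) == pytest.approx(5 / 6, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_agreement_small_graphs(self, seed):
        """Modularity and efficiency agree with explicit-enumeration oracles
        on random weighted graphs with <= 6 nodes."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 7))
        v = r.random((n, n)) * (r.random((n, n)) < 0.7)
        v = np.triu(v, 1)
        v = v + v.T
        fc = fc_from(v)
        labels = r.integers(0, 2, n)
        if v.max() == 0:
            return
        w = np.abs(v) / np.abs(v).max()
        assert modularity(fc, labels) == pytest.approx(
            modularity_oracle(w, labels), abs=1e-12
        )
        assert global_efficiency(fc) == pytest.approx(efficiency_oracle(w), abs=1e-12)


# ---------------------------------------------------------------------------
# Pairing dissimilarity
# ---------------------------------------------------------------------------


class TestPairingDissimilarity:
    def test_identical_inputs_all_zero(self, toy_parcels, rng):
        v = rng.standard_normal((4, 4))
        v = (v + v.T) / 2
        fc = fc_from(v)
        subsets = {name: s for name, s in network_subsets(toy_parcels).items()
                   if len(s) >= 2}
        d = pairing_dissimilarity(fc, fc, subsets)
        assert all(x == pytest.approx(0.0, abs=1e-12) for x in d.values())

    def test_subset_below_two_edges_rejected(self, toy_parcels, rng):
        v = rng.standard_normal((4, 4))
        fc = fc_from((v + v.T) / 2)
        one_edge = {"within:visual": network_subsets(toy_parcels)["within:visual"]}
        with pytest.raises(ValueError, match="fewer than 2"):
            pairing_dissimilarity(fc, fc, one_edge)

    def test_orthogonal_inputs_all_one(self, toy_parcels):
        # disjoint supports per subset make every subset's edge vectors
        # orthogonal (restricted to subsets with >= 2 edges)
        subsets = {name: s for name, s in network_subsets(toy_parcels).items()
                   if len(s) >= 2}
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        for subset in subsets.values():
            pairs = subset.pairs
            half = len(pairs) // 2
            for i, j in pairs[:half]:
                a[i, j] = a[j, i] = 1.0
            for i, j in pairs[half:]:
                b[i, j] = b[j, i] = 1.0
        assert not ((a != 0) & (b != 0)).any()
        d = pairing_dissimilarity(fc_from(a), fc_from(b), subsets)
        assert all(x == pytest.approx(1.0, abs=1e-12) for x in d.values())

    def test_null_cohort_type_one_rate(self, rng):
        """With no planted pairing differences, a paired test comparing
        d(VM,AV) with d(VV,AM) rejects at about the nominal 5% rate."""
        from fcx.inference import paired_ttest

        n_cohorts, n_sub, n_edges = 200, 12, 40
        rejections = 0
        for _ in range(n_cohorts):
            d_comp = np.empty(n_sub)
            d_incomp = np.empty(n_sub)
            for s in range(n_sub):
                base = rng.standard_normal(n_edges)
                mats = base + 0.5 * rng.standard_normal((4, n_edges))
                d_comp[s] = cosine_distance(mats[0], mats[1])
                d_incomp[s] = cosine_distance(mats[2], mats[3])
            res = paired_ttest(d_comp, d_incomp)
            rejections += res.p_value < 0.05
        assert 0.015 <= rejections / n_cohorts <= 0.10
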