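import heapq

import numpy as np
import pytest

from intseg import (
    ConnectivityMatrix,
    efficiency_levels,
    global_efficiency,
    normalized_efficiency,
    shortest_paths,
    shuffle_weights,
    weights_to_distances,
)

from conftest import random_symmetric_weights


def dijkstra_all_pairs(dist):
    """Per-source binary-heap Dijkstra; independent oracle for Floyd-Warshall."""
    n = dist.shape[0]
    out = np.full((n, n), np.inf)
    for src in range(n):
        best = np.full(n, np.inf)
        best[src] = 0.0
        heap = [(0.0, src)]
        done = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            for v in range(n):
                length = dist[u, v]
                if not np.isfinite(length) or v == u:
                    continue
                alt = d + length
                if alt < best[v]:
                    best[v] = alt
                    heapq.heappush(heap, (alt, v))
        out[src] = best
    return out


class TestWeightsToDistances:
    def test_closed_forms_and_removal(self):
        w = np.array(
            [
                [1.0, 1 / np.e, -0.4],
                [1 / np.e, 1.0, 0.5],
                [-0.4, 0.5, 1.0],
            ]
        )
        d = weights_to_distances(w)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[1, 2] == pytest.approx(np.log(2))
        assert np.isinf(d[0, 2])  # negative weight removed
        assert np.all(np.diag(d) == 0)

    def test_unit_weight_clipped(self):
        w = np.ones((2, 2))
        d = weights_to_distances(w)
        assert 0 < d[0, 1] < 1e-9


class TestShortestPaths:
    def test_relay_path(self):
        d = np.array(
            [[0.0, 1.0, np.inf], [1.0, 0.0, 1.0], [np.inf, 1.0, 0.0]]
        )
        spl = shortest_paths(d)
        assert spl[0, 2] == pytest.approx(2.0)

    def test_disconnected_stays_infinite(self):
        d = np.full((4, 4), np.inf)
        np.fill_diagonal(d, 0.0)
        spl = shortest_paths(d)
        assert np.all(np.isinf(spl[~np.eye(4, dtype=bool)]))

    def test_matches_dijkstra_on_random_graphs(self):
        """Floyd-Warshall closure equals per-source Dijkstra, exactly."""
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            w = random_symmetric_weights(rng, n, low=-0.5, high=0.95)
            # knock out extra edges to vary connectivity
            mask = rng.random((n, n)) < 0.3
            mask = mask | mask.T
            w[mask] = -1.0
            np.fill_diagonal(w, 1.0)
            d = weights_to_distances(w)
            # equality up to summation order (different addition orderings
            # of identical edge lengths differ by at most a few ulp)
            np.testing.assert_allclose(
                shortest_paths(d), dijkstra_all_pairs(d), rtol=1e-12, atol=0
            )


class TestGlobalEfficiency:
    def test_complete_uniform_graph_closed_form(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 1.0)
        spl = shortest_paths(weights_to_distances(w))
        assert global_efficiency(spl) == pytest.approx(1.0 / np.log(2))

    def test_edgeless_graph_zero(self):
        w = -np.ones((5, 5))
        np.fill_diagonal(w, 1.0)
        spl = shortest_paths(weights_to_distances(w))
        assert global_efficiency(spl) == 0.0

    def test_four_node_exhaustive_path_oracle(self):
        rng = np.random.default_rng(5)
        w = random_symmetric_weights(rng, 4, low=0.05, high=0.9)
        d = weights_to_distances(w)
        # enumerate every simple path between each pair
        import itertools

        n = 4
        best = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(n):
                if i == j:
                    best[i, j] = 0.0
                    continue
                others = [k for k in range(n) if k not in (i, j)]
                for r in range(len(others) + 1):
                    for mid in itertools.permutations(others, r):
                        path = (i, *mid, j)
                        length = sum(d[a, b] for a, b in zip(path, path[1:]))
                        best[i, j] = min(best[i, j], length)
        spl = shortest_paths(d)
        np.testing.assert_allclose(spl, best, atol=1e-12)
        assert global_efficiency(spl) == pytest.approx(
            np.mean(1.0 / best[~np.eye(n, dtype=bool)])
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))

    def test_monotone_under_edge_addition(self, rng):
        w = random_symmetric_weights(rng, 10, low=-0.8, high=0.9)
        spl = shortest_paths(weights_to_distances(w))
        before = global_efficiency(spl)
        w2 = w.copy()
        # add a strong edge where none existed
        missing = np.argwhere(np.triu(w2 < 0, k=1))
        i, j = missing[0]
        w2[i, j] = w2[j, i] = 0.9
        after = global_efficiency(shortest_paths(weights_to_distances(w2)))
        assert after >= before


class TestShuffleWeights:
    def test_multiset_preserved_and_deterministic(self, rng):
        w = random_symmetric_weights(rng, 9)
        s1 = shuffle_weights(w, np.random.default_rng(3))
        s2 = shuffle_weights(w, np.random.default_rng(3))
        np.testing.assert_array_equal(s1, s2)
        iu = np.triu_indices(9, 1)
        np.testing.assert_allclose(np.sort(s1[iu]), np.sort(w[iu]))
        np.testing.assert_allclose(s1, s1.T)

    def test_uniform_matrix_fixed_point(self):
        w = np.full((5, 5), 0.4)
        np.fill_diagonal(w, 1.0)
        out = shuffle_weights(w, np.random.default_rng(0))
        np.testing.assert_array_equal(out, w)


class TestNormalizedEfficiency:
    def test_uniform_graph_norm_is_one(self, rng):
        w = np.full((8, 8), 0.3)
        np.fill_diagonal(w, 1.0)
        res = normalized_efficiency(w, n_null=5, rng=rng)
        assert res.eg_norm == pytest.approx(1.0)

    def test_eg_independent_of_null_count(self, rng):
        w = random_symmetric_weights(rng, 10)
        r1 = normalized_efficiency(w, n_null=1, rng=np.random.default_rng(1))
        r2 = normalized_efficiency(w, n_null=50, rng=np.random.default_rng(2))
        assert r1.eg == pytest.approx(r2.eg)
        assert r1.eg_rand != pytest.approx(r2.eg_rand, abs=1e-12)

    def test_block_graph_directions(self):
        """Segregated blocks: within-set efficiency beats its null, between-set trails."""
        n = 20
        w = np.full((n, n), 0.1)
        w[:10, :10] = 0.7
        w[10:, 10:] = 0.7
        np.fill_diagonal(w, 1.0)
        rng = np.random.default_rng(8)
        within = normalized_efficiency(w, np.arange(10), n_null=40, rng=rng)
        between = normalized_efficiency(
            w, np.arange(10), np.arange(10, 20), n_null=40, rng=rng
        )
        assert between.eg_norm < 1.0
        assert within.eg_norm == pytest.approx(1.0, abs=0.05)

    def test_shuffled_graph_norm_near_one(self, rng):
        w = random_symmetric_weights(rng, 16, low=0.05, high=0.9)
        shuffled = shuffle_weights(w, rng)
        runs = [
            normalized_efficiency(shuffled, n_null=60, rng=np.random.default_rng(s))
            for s in range(3)
        ]
        norms = [r.eg_norm for r in runs]
        spread = np.std([r.eg_rand for r in runs])
        assert np.mean(norms) == pytest.approx(1.0, abs=max(3 * spread, 0.02))

    def test_between_requires_disjoint_sets(self, rng):
        w = random_symmetric_weights(rng, 6)
        with pytest.raises(ValueError):
            normalized_efficiency(w, np.array([0, 1, 2]), np.array([2, 3]), rng=rng)


class TestEfficiencyLevels:
    def test_matches_spec_by_spec_recomputation(self, small_partition, rng):
        """Level summary equals independently recomputed per-spec results."""
        from intseg.simulate import _stream

        w = random_symmetric_weights(rng, 28, low=-0.2, high=0.9)
        fc = ConnectivityMatrix(w, small_partition.roi_ids)
        summary = efficiency_levels(
            fc, small_partition, n_null=7, rng=np.random.default_rng(42)
        )
        # identical seeded stream -> identical null sequence -> exact equality
        rng2 = np.random.default_rng(42)
        whole = normalized_efficiency(w, n_null=7, rng=rng2).eg_norm
        assert summary.global_["whole_brain"] == whole
        nets = [small_partition.network_indices(n) for n in
                ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")]
        diag = []
        for i in range(7):
            diag.append(normalized_efficiency(w, nets[i], n_null=7, rng=rng2).eg_norm)
            for j in range(i + 1, 7):
                got = normalized_efficiency(w, nets[i], nets[j], n_null=7, rng=rng2)
                assert summary.network[i, j] == got.eg_norm
        np.testing.assert_allclose(np.diag(summary.network), diag)
        assert summary.global_["within_network"] == pytest.approx(np.mean(diag))

    def test_block_constant_symmetry(self, small_partition):
        w, b = 0.6, 0.2
        v = np.full((28, 28), b)
        for k in range(7):
            v[4 * k : 4 * k + 4, 4 * k : 4 * k + 4] = w
        np.fill_diagonal(v, 1.0)
        fc = ConnectivityMatrix(v, small_partition.roi_ids)
        s = efficiency_levels(fc, small_partition, n_null=10, rng=np.random.default_rng(1))
        off = s.network[np.triu_indices(7, 1)]
        assert np.std(off) < 0.05  # all 21 between-network values statistically equal
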