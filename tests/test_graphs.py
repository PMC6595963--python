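"""Binarization, degree centrality, hub calling and hub probability."""

import numpy as np
import pytest

from dynhub.connectivity import FCMatrix, SubjectTimeSeries, sliding_windows, \
    variance_stabilize
from dynhub.graphs import (GraphError, ThresholdSpec, binarize, binarize_stack,
                           call_hubs, degree, dynamic_hub_probability,
                           edge_budget, hub_probability, static_centrality,
                           zscore_degree)


def random_fc(rng, n):
    r = rng.uniform(-0.9, 0.9, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return r


def brute_force_absolute(values, threshold):
    n = values.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and values[i, j] > threshold:
                adj[i, j] = True
    return adj


def brute_force_proportional(values, sparsity):
    n = values.shape[0]
    pairs = [(values[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    # descending weight; lexicographically smaller pair wins ties
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    m = int(np.floor(sparsity * len(pairs) + 0.5))
    adj = np.zeros((n, n), dtype=bool)
    for _, i, j in pairs[:m]:
        adj[i, j] = adj[j, i] = True
    return adj


class TestBinarize:
    def test_absolute_threshold_is_strict_and_signed(self):
        v = np.eye(4)
        v[0, 1] = v[1, 0] = 0.30
        v[0, 2] = v[2, 0] = 0.25   # exactly at threshold: excluded
        v[1, 3] = v[3, 1] = -0.40  # strong negative: excluded
        g = binarize(FCMatrix(v), ThresholdSpec("absolute", 0.25))
        expected = np.zeros((4, 4), dtype=bool)
        expected[0, 1] = expected[1, 0] = True
        assert np.array_equal(g.adjacency, expected)

    def test_sparsity_point2_on_90_nodes_gives_801_edges(self, rng):
        v = random_fc(rng, 90)
        g = binarize(FCMatrix(v), ThresholdSpec("proportional", 0.2))
        assert g.adjacency.sum() // 2 == 801
        assert edge_budget(0.2, 90) == 801
        assert edge_budget(0.25, 90) == 1001  # round-half-up of 1001.25

    @pytest.mark.parametrize("mode, value", [
        ("absolute", 0.25), ("absolute", 0.2),
        ("proportional", 0.2), ("proportional", 0.25),
    ])
    def test_matches_brute_force_oracle(self, rng, mode, value):
        for _ in range(5):
            n = int(rng.integers(10, 40))
            v = random_fc(rng, n)
            g = binarize(FCMatrix(v), ThresholdSpec(mode, value))
            if mode == "absolute":
                expected = brute_force_absolute(v, value)
            else:
                expected = brute_force_proportional(v, value)
            assert np.array_equal(g.adjacency, expected)

    def test_proportional_tie_break_is_lexicographic(self):
        v = np.full((4, 4), 0.5)  # all six pairs tied
        np.fill_diagonal(v, 1.0)
        g = binarize(FCMatrix(v), ThresholdSpec("proportional", 0.5))
        # round(0.5 * 6) = 3 edges: the lexicographically first pairs
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4)
                if g.adjacency[i, j]}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_absolute_edge_count_monotone_in_threshold(self, rng):
        v = random_fc(rng, 30)
        counts = [binarize(FCMatrix(v), ThresholdSpec("absolute", t)).adjacency.sum()
                  for t in (-0.5, -0.2, 0.0, 0.2, 0.5, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_proportional_graph_invariant_under_variance_stabilization(self, rng):
        for _ in range(5):
            v = random_fc(rng, 25)
            raw = binarize(FCMatrix(v), ThresholdSpec("proportional", 0.2))
            vs = binarize(FCMatrix(v),
                          ThresholdSpec("proportional", 0.2, "variance_stabilized"))
            assert np.array_equal(raw.adjacency, vs.adjacency)

    def test_invalid_specs_rejected(self):
        with pytest.raises(GraphError):
            ThresholdSpec("absolute", 1.5)
        with pytest.raises(GraphError):
            ThresholdSpec("proportional", 0.0)
        with pytest.raises(GraphError):
            ThresholdSpec("nearest", 0.2)


class TestDegreeAndZscore:
    def test_complete_and_empty_graph_degrees(self):
        n = 90
        full = ~np.eye(n, dtype=bool)
        assert np.all(degree(full) == n - 1)
        assert np.all(degree(np.zeros((n, n), dtype=bool)) == 0)

    def test_degree_matches_neighbor_count_loop(self, rng):
        v = random_fc(rng, 20)
        adj = binarize(FCMatrix(v), ThresholdSpec("absolute", 0.2)).adjacency
        D = degree(adj)
        for i in range(20):
            assert D[i] == sum(adj[i, j] for j in range(20) if j != i)

    def test_hand_computed_zscores(self):
        Z = zscore_degree(np.array([10, 10, 10, 10, 20]))
        assert np.allclose(Z, [-0.5, -0.5, -0.5, -0.5, 2.0])

    def test_equal_degrees_give_zero_zscores_and_no_hubs(self):
        Z = zscore_degree(np.full(90, 13))
        assert np.all(Z == 0.0)
        assert not call_hubs(Z).any()

    def test_zscores_center_to_zero(self, rng):
        for _ in range(10):
            D = rng.integers(0, 89, size=90)
            assert abs(zscore_degree(D).mean()) < 1e-10

    def test_hub_call_is_strict_above_one(self):
        Z = np.array([-0.5, -0.5, -0.5, -0.5, 2.0])
        assert list(call_hubs(Z)) == [False, False, False, False, True]
        assert not call_hubs(np.array([1.0])).any()


@pytest.fixture(scope="module")
def windowed():
    rng = np.random.default_rng(7)
    ts = SubjectTimeSeries("h", rng.standard_normal((80, 30)))
    return sliding_windows(ts, window_length=20, step=4)


class TestHubProbability:
    def test_probabilities_are_window_fractions(self, windowed):
        spec = ThresholdSpec("absolute", 0.25)
        prof = hub_probability(windowed, spec)
        assert prof.n_windows == len(windowed)
        assert np.all((prof.prob >= 0) & (prof.prob <= 1))
        # prob * n_windows must be an integer count
        counts = prof.prob * prof.n_windows
        assert np.allclose(counts, np.rint(counts), atol=1e-9)

    def test_invariant_to_window_order(self, windowed, rng):
        spec = ThresholdSpec("absolute", 0.25)
        base = hub_probability(windowed, spec)
        shuffled = type(windowed)(
            windowed.values[rng.permutation(len(windowed))],
            windowed.window_length, windowed.step)
        assert np.array_equal(base.prob,
                              hub_probability(shuffled, spec).prob)

    def test_equals_per_window_composition(self, windowed):
        spec = ThresholdSpec("proportional", 0.2)
        prof = hub_probability(windowed, spec)
        manual = np.zeros(windowed.values.shape[1])
        for fc in windowed:
            hubs = call_hubs(zscore_degree(degree(binarize(fc, spec))))
            manual += hubs
        assert np.allclose(prof.prob, manual / len(windowed))

    def test_never_more_hubs_than_regions(self, windowed):
        adj = binarize_stack(windowed.values, ThresholdSpec("absolute", 0.2))
        hubs = call_hubs(zscore_degree(degree(adj)))
        assert hubs.sum(axis=1).max() < windowed.values.shape[1]


class TestStaticCentrality:
    def test_series_of_window_length_matches_single_window(self, rng):
        ts = SubjectTimeSeries("s", rng.standard_normal((25, 15)))
        spec = ThresholdSpec("absolute", 0.25)
        prof = static_centrality(ts, spec)
        dyn = dynamic_hub_probability(ts, spec, window_length=25)
        assert dyn.n_windows == 1
        assert np.array_equal(call_hubs(prof.zscore), dyn.prob == 1.0)

    def test_duplicated_columns_are_mutual_neighbors(self, toy5):
        fc_graph = binarize(
            FCMatrix(np.corrcoef(toy5.data, rowvar=False)),
            ThresholdSpec("absolute", 0.25))
        assert fc_graph.adjacency[0, 1]

    def test_equals_composed_public_stages(self, rng):
        ts = SubjectTimeSeries("c", rng.standard_normal((60, 20)))
        spec = ThresholdSpec("proportional", 0.25)
        prof = static_centrality(ts, spec)
        from dynhub.connectivity import pearson_fc
        adj = binarize(pearson_fc(ts), spec)
        D = degree(adj)
        assert np.array_equal(prof.degree, D)
        assert np.allclose(prof.zscore, zscore_degree(D))
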