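"""Connectivity matrices, circular-shift permutation null, map equation and
community detection."""

import networkx as nx
import numpy as np
import pytest

from socmap.errors import DegenerateDataError, SaturationError, ValidationError
from socmap.network import (CommunityPartition, build_graph, circular_shift,
                            detect_communities, group_mean_connectivity,
                            map_equation, permutation_threshold,
                            subject_connectivity, _circular_corr_tensor)
from socmap.synth import planted_partition_graph


class TestSubjectConnectivity:
    def test_identical_series_correlate_perfectly(self, rng):
        s = rng.standard_normal(50)
        r = subject_connectivity(np.vstack([s, s]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_sinusoids_are_uncorrelated(self):
        t = np.arange(200)
        r = subject_connectivity(np.vstack([np.sin(2 * np.pi * t / 50),
                                            np.cos(2 * np.pi * t / 50)]))
        assert abs(r[0, 1]) < 1e-10

    def test_matches_definitional_oracle(self, rng):
        x = rng.standard_normal((5, 60))
        r = subject_connectivity(x)
        for i in range(5):
            for j in range(5):
                a = x[i] - x[i].mean()
                b = x[j] - x[j].mean()
                expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert r[i, j] == pytest.approx(expected)

    def test_zero_variance_series_raises(self, rng):
        with pytest.raises(DegenerateDataError):
            subject_connectivity(np.vstack([np.ones(20),
                                            rng.standard_normal(20)]))


class TestGroupMeanConnectivity:
    def test_identical_subject_matrices_pass_through(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert np.allclose(group_mean_connectivity([r, r, r]), r)

    def test_closed_form_fisher_average(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.array([[1.0, 0.8], [0.8, 1.0]])
        out = group_mean_connectivity([a, b])
        expected = np.tanh((np.arctanh(0.5) + np.arctanh(0.8)) / 2)
        assert out[0, 1] == pytest.approx(expected)
        assert out[0, 1] == pytest.approx(0.6777, abs=5e-4)

    def test_antisymmetric_pair_averages_to_zero(self):
        a = np.array([[1.0, 0.6], [0.6, 1.0]])
        b = np.array([[1.0, -0.6], [-0.6, 1.0]])
        assert group_mean_connectivity([a, b])[0, 1] == pytest.approx(0.0)

    def test_mean_lies_between_subject_extremes(self, rng):
        mats = []
        for _ in range(5):
            r = rng.uniform(-0.8, 0.8)
            mats.append(np.array([[1.0, r], [r, 1.0]]))
        out = group_mean_connectivity(mats)
        vals = [m[0, 1] for m in mats]
        assert min(vals) <= out[0, 1] <= max(vals)

    def test_saturated_correlation_raises(self):
        bad = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SaturationError):
            group_mean_connectivity([bad])


class TestCircularShift:
    def test_shift_preserves_multiset(self, rng):
        s = rng.standard_normal(40)
        out = circular_shift(s, 13)
        assert np.array_equal(np.sort(out), np.sort(s))

    def test_shift_then_inverse_is_identity(self, rng):
        s = rng.standard_normal(40)
        assert np.array_equal(circular_shift(circular_shift(s, 13), 40 - 13),
                              s)

    def test_out_of_range_shift_rejected(self, rng):
        s = rng.standard_normal(40)
        with pytest.raises(ValidationError):
            circular_shift(s, 5, min_shift=10)
        with pytest.raises(ValidationError):
            circular_shift(s, 40, min_shift=10)

    def test_lag1_autocorrelation_nearly_preserved(self, rng):
        from scipy.signal import lfilter
        s = lfilter([1.0], [1.0, -0.5], rng.standard_normal(600))
        def lag1(x):
            x = x - x.mean()
            return (x[1:] @ x[:-1]) / (x @ x)
        assert abs(lag1(circular_shift(s, 100)) - lag1(s)) <= 2 / len(s) + 0.01


class TestPermutationThreshold:
    def test_fft_tensor_matches_direct_shifted_correlation(self, rng):
        x = rng.standard_normal((3, 40))
        C = _circular_corr_tensor(x)
        for seed_roi in range(3):
            for k in (0, 5, 17):
                shifted = np.roll(x[seed_roi], k)
                for target in range(3):
                    expected = np.corrcoef(shifted, x[target])[0, 1]
                    assert C[seed_roi, target, k] == pytest.approx(expected)

    def test_threshold_monotone_in_permutation_count(self, rng):
        series = [rng.standard_normal((4, 64)) for _ in range(3)]
        t_small, _ = permutation_threshold(series, n_perm=200, min_shift=5,
                                           seed=9)
        t_large, _ = permutation_threshold(series, n_perm=2000, min_shift=5,
                                           seed=9)
        assert t_large >= t_small

    def test_matches_bruteforce_loop(self, rng):
        series = [rng.standard_normal((3, 40)) for _ in range(2)]
        n_perm, min_shift, seed = 60, 5, 4
        threshold, _ = permutation_threshold(series, n_perm=n_perm,
                                             min_shift=min_shift, seed=seed)
        # literal re-implementation with the same draw streams
        S, (R, T) = len(series), series[0].shape
        ss = np.random.SeedSequence(seed).spawn(2)
        seeds = np.random.default_rng(ss[0]).integers(0, R, size=(n_perm, S))
        shifts = np.random.default_rng(ss[1]).integers(
            min_shift, T - min_shift + 1, size=(n_perm, S))
        best = 0.0
        for p in range(n_perm):
            for target in range(R):
                zs = []
                for i in range(S):
                    if seeds[p, i] == target:
                        continue
                    shifted = np.roll(series[i][seeds[p, i]], shifts[p, i])
                    zs.append(np.arctanh(
                        np.corrcoef(shifted, series[i][target])[0, 1]))
                if zs:
                    best = max(best, abs(np.tanh(np.mean(zs))))
        assert threshold == pytest.approx(best, abs=1e-12)

    def test_per_subject_pooling_exceeds_group_mean(self, rng):
        # per-subject |r| values are noisier than their Fisher-z group mean
        series = [rng.standard_normal((5, 256)) for _ in range(8)]
        t_group, _ = permutation_threshold(series, 500, min_shift=10, seed=0)
        t_subj, _ = permutation_threshold(series, 500, min_shift=10, seed=0,
                                          pooling="per_subject")
        assert t_subj > t_group

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValidationError):
            permutation_threshold([rng.standard_normal((3, 15))], 10,
                                  min_shift=10)


class TestBuildGraph:
    def test_threshold_above_max_gives_empty_graph(self, rng):
        r = np.clip(rng.uniform(-0.5, 0.5, (4, 4)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = build_graph(r, 0.99, list("abcd"))
        assert g.edges == []

    def test_zero_threshold_gives_complete_graph(self, rng):
        r = rng.uniform(0.1, 0.9, (4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = build_graph(r, 0.0, list("abcd"))
        assert len(g.edges) == 6
        assert all(d == 3 for d in g.degree.values())

    def test_edges_match_bruteforce_comparison(self, rng):
        n = 6
        r = rng.uniform(-1, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        names = [f"n{i}" for i in range(n)]
        g = build_graph(r, 0.3, names)
        expected = {(names[i], names[j])
                    for i in range(n) for j in range(i + 1, n)
                    if abs(r[i, j]) > 0.3}
        assert {(a, b) for a, b, _ in g.edges} == expected


class TestMapEquation:
    def test_single_module_star_graph_closed_form(self):
        g = nx.star_graph(3)  # hub + 3 leaves, unit weights
        nx.set_edge_attributes(g, 1.0, "weight")
        L = map_equation(g, {n: 0 for n in g.nodes()})
        # visit rates (1/2, 1/6, 1/6, 1/6); single module => entropy of visits
        expected = -(0.5 * np.log2(0.5) + 3 * (1 / 6) * np.log2(1 / 6))
        assert L == pytest.approx(expected)
        assert L == pytest.approx(1.7925, abs=1e-4)

    def test_two_cliques_prefer_two_modules(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(0, 4, weight=0.05)
        one = {n: 0 for n in g.nodes()}
        two = {n: (0 if n < 4 else 1) for n in g.nodes()}
        assert map_equation(g, two) < map_equation(g, one)

    def test_relabeling_modules_leaves_length_unchanged(self, rng):
        g, labels = planted_partition_graph(10, 2, 0.9, 0.2, seed=3)
        part = {n: int(labels[n]) for n in g.nodes()}
        relabeled = {n: 7 - m for n, m in part.items()}
        assert map_equation(g, part) == pytest.approx(
            map_equation(g, relabeled))

    def test_unassigned_node_rejected(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        with pytest.raises(ValidationError):
            map_equation(g, {0: 0, 1: 0})


class TestDetectCommunities:
    def test_disconnected_cliques_recovered_exactly(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j, weight=1.0)
        part = detect_communities(g, n_restarts=10, seed=0)
        groups = {}
        for node, m in part.assignment.items():
            groups.setdefault(m, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
        assert part.modal_fraction == 1.0

    def test_returned_length_is_minimal_over_restarts(self):
        g, _ = planted_partition_graph(12, 3, 0.9, 0.1, seed=1)
        part = detect_communities(g, n_restarts=20, seed=2)
        single = map_equation(g, {n: 0 for n in g.nodes()})
        assert part.description_length <= single + 1e-12

    def test_reproducible_for_fixed_seed(self):
        g, _ = planted_partition_graph(14, 4, 0.9, 0.05, seed=5,
                                       sizes=[5, 3, 3, 3])
        p1 = detect_communities(g, n_restarts=15, seed=11)
        p2 = detect_communities(g, n_restarts=15, seed=11)
        assert p1.assignment == p2.assignment
        assert p1.description_length == p2.description_length

    def test_matches_igraph_infomap_on_planted_graph(self):
        igraph = pytest.importorskip("igraph")
        g, labels = planted_partition_graph(14, 4, 0.9, 0.05, seed=5,
                                            sizes=[5, 3, 3, 3])
        part = detect_communities(g, n_restarts=50, seed=3)
        ig = igraph.Graph.TupleList(
            ((u, v, d["weight"]) for u, v, d in g.edges(data=True)),
            weights=True)
        ig_part = ig.community_infomap(edge_weights="weight", trials=20)
        ours = {}
        for node, m in part.assignment.items():
            ours.setdefault(m, frozenset()).union  # noqa: B018
            ours[m] = ours.get(m, frozenset()) | {node}
        theirs = {}
        for vid, m in enumerate(ig_part.membership):
            name = ig.vs[vid]["name"]
            theirs[m] = theirs.get(m, frozenset()) | {name}
        assert set(map(frozenset, ours.values())) == \
            set(map(frozenset, theirs.values()))


class TestPlantedPartition:
    def test_zero_out_probability_disconnects_modules(self):
        g, labels = planted_partition_graph(12, 3, 1.0, 0.0, seed=0)
        comps = list(nx.connected_components(g))
        expected = [set(np.flatnonzero(labels == m)) for m in range(3)]
        assert sorted(map(sorted, comps)) == sorted(map(sorted, expected))

    def test_single_module_gives_uniform_labels(self):
        _, labels = planted_partition_graph(6, 1, 0.9, 0.0, seed=0)
        assert len(set(labels)) == 1

    def test_p_in_not_exceeding_p_out_rejected(self):
        with pytest.raises(ValidationError):
            planted_partition_graph(10, 2, 0.3, 0.3)
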