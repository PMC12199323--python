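"""Network construction and random-walk-with-restart propagation."""

import numpy as np
import pandas as pd
import pytest

from driversig.ppi_propagation import (
    Network,
    filter_edges,
    largest_connected_component,
    make_seed_vector,
    normalize_columns,
    propagate,
    read_edge_list,
    write_scores,
)


def random_connected_network(rng, n_nodes, p=0.15):
    """Erdos-Renyi draw augmented to connectivity by chaining components."""
    adj = (rng.random((n_nodes, n_nodes)) < p).astype(float)
    adj = np.triu(adj, k=1)
    adj = adj + adj.T
    # chain every node to the next to guarantee connectivity
    for i in range(n_nodes - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    return Network([f"N{i:02d}" for i in range(n_nodes)], adj)


class TestFilterEdges:
    def test_source_count_threshold(self):
        records = [
            ("A", "B", "s1"),
            ("B", "A", "s2"),  # same unordered pair, second source
            ("A", "C", "s1"),  # only one source: excluded at min_sources=2
        ]
        net = filter_edges(records, min_sources=2)
        assert net.node_ids == ["A", "B"]
        assert net.n_edges == 1

    def test_counts_distinct_sources_not_records(self):
        # duplicated (pair, source) records collapse to one observation
        records = [("A", "B", "s1")] * 5
        with pytest.raises(ValueError, match="no edge"):
            filter_edges(records, min_sources=2)

    def test_edge_count_from_mixed_support(self):
        # distinct-source counts (1, 2, 2, 3, 1) -> 3 edges at min_sources=2
        pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "J")]
        counts = [1, 2, 2, 3, 1]
        records = [
            (a, b, f"s{k}") for (a, b), c in zip(pairs, counts) for k in range(c)
        ]
        net = filter_edges(records, min_sources=2)
        assert net.n_edges == 3

    def test_self_pairs_discarded(self):
        net = filter_edges([("A", "A", "s1"), ("A", "B", "s1"), ("A", "B", "s2")])
        assert net.n_edges == 1
        assert np.all(np.diag(net.adjacency) == 0)

    def test_malformed_record_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            filter_edges([("A", "B", "s1"), ("A", "B"), ("C", "D", "s2")])

    def test_empty_records_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_edges([])

    def test_whitespace_stripped(self):
        net = filter_edges([(" A ", "B", "s1"), ("A", " B", "s2")])
        assert net.node_ids == ["A", "B"]
        assert net.n_edges == 1


class TestLargestConnectedComponent:
    def test_connected_graph_unchanged(self, rng):
        net = random_connected_network(rng, 6)
        out = largest_connected_component(net)
        assert out.node_ids == net.node_ids
        assert np.array_equal(out.adjacency, net.adjacency)

    def test_picks_larger_component(self):
        # components {A..E} (path) and {X, Y, Z} (path)
        records = (
            [(a, b, s) for a, b in zip("ABCD", "BCDE") for s in ("s1", "s2")]
            + [(a, b, s) for a, b in [("X", "Y"), ("Y", "Z")] for s in ("s1", "s2")]
        )
        net = filter_edges(records)
        out = largest_connected_component(net)
        assert out.node_ids == list("ABCDE")

    def test_tie_broken_by_smallest_node_id(self):
        # two 2-node components; the one containing 'A' wins
        records = [(a, b, s) for a, b in [("X", "Y"), ("A", "B")] for s in ("s1", "s2")]
        net = filter_edges(records)
        out = largest_connected_component(net)
        assert out.node_ids == ["A", "B"]

    def test_node_order_preserved(self):
        records = [(a, b, s) for a, b in [("C", "A"), ("A", "D"), ("X", "Y")]
                   for s in ("s1", "s2")]
        net = filter_edges(records)
        out = largest_connected_component(net)
        assert out.node_ids == sorted(out.node_ids)  # induced order follows input


class TestNormalizeColumns:
    def test_path_graph_column(self):
        net = filter_edges(
            [(a, b, s) for a, b in [("A", "B"), ("B", "C")] for s in ("s1", "s2")]
        )
        T = normalize_columns(net)
        b = net.node_ids.index("B")
        assert np.allclose(T[:, b], [0.5, 0.0, 0.5])

    def test_regular_graph_uniform(self):
        # 4-cycle: every node degree 2 -> T = P / 2
        records = [(a, b, s) for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
                   for s in ("s1", "s2")]
        net = filter_edges(records)
        assert np.array_equal(normalize_columns(net), net.adjacency / 2.0)

    def test_random_graph_columns_stochastic(self, rng):
        net = random_connected_network(rng, 20)
        T = normalize_columns(net)
        assert np.allclose(T.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_degree_column_rejected(self):
        net = Network(["A", "B", "C"], np.array(
            [[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float))
        with pytest.raises(ValueError, match="zero-degree"):
            normalize_columns(net)


class TestSeedVector:
    def test_partial_mapping_uniform_mass(self, rng):
        net = random_connected_network(rng, 4)
        sv = make_seed_vector(net, {"N00", "N02", "ABSENT"})
        assert sv.n_mapped == 2 and sv.n_unmapped == 1
        assert sv.unmapped == ["ABSENT"]
        np.testing.assert_array_equal(sv.values, [0.5, 0.0, 0.5, 0.0])

    def test_no_seed_maps_error(self, rng):
        net = random_connected_network(rng, 4)
        with pytest.raises(ValueError, match="no seed"):
            make_seed_vector(net, {"Q1", "Q2"})

    def test_full_mapping_sums_to_one_exactly(self, rng):
        net = random_connected_network(rng, 10)
        sv = make_seed_vector(net, set(net.node_ids))
        assert sv.values.sum() == 1.0
        assert np.all(sv.values == 0.1)


class TestPropagate:
    def test_beta_one_returns_seed_distribution(self, rng):
        net = random_connected_network(rng, 8)
        T = normalize_columns(net)
        sv = make_seed_vector(net, {"N00"})
        res = propagate(T, sv, beta=1.0)
        assert res.iterations == 1 and res.converged
        np.testing.assert_array_equal(res.values, sv.values)

    def test_two_node_closed_form(self):
        net = filter_edges([("A", "B", "s1"), ("A", "B", "s2")])
        T = normalize_columns(net)
        sv = make_seed_vector(net, {"A"})
        res = propagate(T, sv, beta=0.9)
        assert res.converged
        np.testing.assert_allclose(res.values, [10 / 11, 1 / 11], atol=1e-10)

    def test_mass_conserved(self, rng):
        net = random_connected_network(rng, 25)
        res = propagate(normalize_columns(net), make_seed_vector(net, {"N03", "N11"}))
        assert abs(res.values.sum() - 1.0) < 1e-9
        assert np.all(res.values >= 0)

    def test_matches_linear_solve(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 51))
            net = random_connected_network(rng, n)
            T = normalize_columns(net)
            seeds = set(rng.choice(net.node_ids, size=max(1, n // 5), replace=False))
            sv = make_seed_vector(net, seeds)
            res = propagate(T, sv, beta=0.9, tol=1e-12)
            beta = 0.9
            exact = beta * np.linalg.solve(np.eye(n) - (1 - beta) * T, sv.values)
            assert np.max(np.abs(res.values - exact)) < 1e-8

    def test_monotone_along_path(self):
        # seed at one end of a path: score non-increasing with distance
        nodes = list("ABCDEFG")
        records = [(a, b, s) for a, b in zip(nodes, nodes[1:]) for s in ("s1", "s2")]
        net = filter_edges(records)
        res = propagate(normalize_columns(net), make_seed_vector(net, {"A"}))
        assert np.all(np.diff(res.values) <= 1e-15)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            propagate(np.array([[0.5, 0.2], [0.2, 0.5]]), np.array([1.0, 0.0]))

    def test_max_iter_flags_non_convergence(self, rng):
        net = random_connected_network(rng, 30)
        res = propagate(normalize_columns(net), make_seed_vector(net, {"N00"}),
                        beta=0.05, tol=1e-300, max_iter=3)
        assert not res.converged and res.iterations == 3

    def test_deterministic(self, rng):
        net = random_connected_network(rng, 15)
        T = normalize_columns(net)
        sv = make_seed_vector(net, {"N01", "N07"})
        a = propagate(T, sv).values
        b = propagate(T, sv).values
        assert np.array_equal(a, b)


def test_edge_list_and_score_io(tmp_path, rng):
    df = pd.DataFrame(
        {"geneA": ["A", "A", "B"], "geneB": ["B", "B", "C"],
         "source": ["s1", "s2", "s1"]}
    )
    path = tmp_path / "edges.tsv"
    df.to_csv(path, sep="\t", index=False)
    records = read_edge_list(path)
    assert records == [("A", "B", "s1"), ("A", "B", "s2"), ("B", "C", "s1")]
    net = filter_edges(records, min_sources=2)
    res = propagate(normalize_columns(net), make_seed_vector(net, {"A"}))
    out = tmp_path / "scores.tsv"
    write_scores(out, net, res)
    scores = pd.read_csv(out, sep="\t")
    assert list(scores.columns) == ["gene", "score"]
    assert np.all(np.diff(scores["score"]) <= 0)  # descending
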