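"""Binary graph metrics against brute-force shortest-path oracles."""

import itertools

import numpy as np
import pytest

from neuromass.connectome import AdjacencyGraph, StructuralConnectome, binarize
from neuromass.exploration import FittedParameters
from neuromass.graph_metrics import (
    average_betweenness_centrality,
    average_degree_centrality,
    global_efficiency,
    metrics_table,
)

INF = 10**9


def graph(a):
    a = np.asarray(a, dtype=int)
    return AdjacencyGraph(a=a, node_labels=[f"n{i}" for i in range(len(a))])


def complete(n):
    a = np.ones((n, n), dtype=int)
    np.fill_diagonal(a, 0)
    return graph(a)


def random_graph(rng, n, p=0.5):
    a = (rng.uniform(size=(n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return graph(a + a.T)


def floyd_warshall_with_counts(a):
    """Oracle: all-pairs shortest-path lengths and path counts."""
    n = len(a)
    d = [[0 if i == j else (1 if a[i][j] else INF) for j in range(n)]
         for i in range(n)]
    cnt = [[1 if a[i][j] else 0 for j in range(n)] for i in range(n)]
    for i in range(n):
        cnt[i][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
                    cnt[i][j] = cnt[i][k] * cnt[k][j]
                elif d[i][k] + d[k][j] == d[i][j] and d[i][j] < INF and k not in (i, j):
                    cnt[i][j] += cnt[i][k] * cnt[k][j]
    return d, cnt


def brute_betweenness(a):
    """Oracle: fractional shortest-path counting over unordered pairs,
    normalized by 2/((n-1)(n-2))."""
    n = len(a)
    d, cnt = floyd_warshall_with_counts(a)
    b = np.zeros(n)
    for i in range(n):
        for h, j in itertools.combinations(range(n), 2):
            if i in (h, j) or d[h][j] >= INF:
                continue
            through = (cnt[h][i] * cnt[i][j]
                       if d[h][i] + d[i][j] == d[h][j] else 0)
            b[i] += through / cnt[h][j]
    return b * 2.0 / ((n - 1) * (n - 2))


def brute_efficiency(a):
    n = len(a)
    d, _ = floyd_warshall_with_counts(a)
    e = np.zeros(n)
    for i in range(n):
        e[i] = sum(1.0 / d[i][j] for j in range(n)
                   if j != i and d[i][j] < INF) / (n - 1)
    return e


class TestDegree:
    def test_complete_graph(self):
        k_av, k_i = average_degree_centrality(complete(7))
        assert k_av == 6
        assert np.all(k_i == 6)

    def test_edgeless_graph(self):
        k_av, _ = average_degree_centrality(graph(np.zeros((4, 4), dtype=int)))
        assert k_av == 0

    def test_path_graph_3_nodes(self):
        a = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        k_av, k_i = average_degree_centrality(graph(a))
        np.testing.assert_array_equal(k_i, [1, 2, 1])
        assert k_av == pytest.approx(4 / 3)


class TestBetweenness:
    def test_complete_graph_zero(self):
        b_av, b_i = average_betweenness_centrality(complete(6))
        assert b_av == 0
        assert np.all(b_i == 0)

    def test_star_graph(self):
        """Hub of a 3-leaf star routes all 3 leaf pairs: b_hub = 1."""
        a = np.zeros((4, 4), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        b_av, b_i = average_betweenness_centrality(graph(a))
        assert b_i[0] == pytest.approx(1.0)
        assert np.all(b_i[1:] == 0)
        assert b_av == pytest.approx(0.25)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(3, 9)), p=rng.uniform(0.2, 0.9))
            _, b_i = average_betweenness_centrality(g)
            np.testing.assert_allclose(b_i, brute_betweenness(g.a), atol=1e-12)

    def test_two_nodes_rejected(self):
        with pytest.raises(ValueError):
            average_betweenness_centrality(complete(2))


class TestEfficiency:
    def test_complete_graph_is_one(self):
        e, e_i = global_efficiency(complete(10))
        assert e == pytest.approx(1.0)
        assert np.all(e_i == 1.0)

    def test_edgeless_graph_is_zero(self):
        e, _ = global_efficiency(graph(np.zeros((5, 5), dtype=int)))
        assert e == 0.0

    def test_path_graph_3_nodes(self):
        a = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        e, e_i = global_efficiency(graph(a))
        np.testing.assert_allclose(e_i, [0.75, 1.0, 0.75])
        assert e == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(2, 9)), p=rng.uniform(0.1, 0.9))
            _, e_i = global_efficiency(g)
            np.testing.assert_allclose(e_i, brute_efficiency(g.a), atol=1e-12)

    def test_connected_graph_between_zero_and_one(self, rng):
        for _ in range(10):
            g = random_graph(rng, 6, p=0.8)
            e, _ = global_efficiency(g)
            assert 0 <= e <= 1
            is_complete = g.a.sum() == 6 * 5
            assert (e == pytest.approx(1.0)) == is_complete


class TestStructuralProperties:
    def test_permutation_invariance(self, rng):
        for _ in range(10):
            g = random_graph(rng, 7, p=0.5)
            perm = rng.permutation(7)
            gp = graph(g.a[np.ix_(perm, perm)])
            for fn in (average_degree_centrality,
                       average_betweenness_centrality, global_efficiency):
                assert fn(g)[0] == pytest.approx(fn(gp)[0], abs=1e-12)

    def test_edge_removal_never_increases_degree_or_efficiency(self, rng):
        for _ in range(10):
            g = random_graph(rng, 7, p=0.7)
            edges = np.argwhere(np.triu(g.a, 1))
            if not len(edges):
                continue
            i, j = edges[rng.integers(len(edges))]
            a2 = g.a.copy()
            a2[i, j] = a2[j, i] = 0
            g2 = graph(a2)
            assert average_degree_centrality(g2)[0] <= average_degree_centrality(g)[0]
            assert global_efficiency(g2)[0] <= global_efficiency(g)[0] + 1e-12


class TestMetricsTable:
    def _cohort(self, n_subjects, rng):
        items = []
        for i in range(n_subjects):
            a = random_graph(rng, 6, p=0.6)
            w = a.a.astype(float)
            lengths = np.where(w > 0, 10.0, 0.0)
            c = StructuralConnectome(
                subject_id=f"s{i:02d}",
                region_labels=[f"n{k}" for k in range(6)],
                weights=w,
                lengths=lengths,
                group_label="stroke" if i % 2 else "control",
            )
            fitted = FittedParameters(subject_id=c.subject_id, G=0.01 * (i + 1),
                                      v=20.0, K12=0.1, K21=0.2, K11=0.3)
            items.append((c, binarize(c), fitted))
        return items

    def test_single_subject_row(self, rng):
        table = metrics_table(self._cohort(1, rng))
        assert len(table) == 1
        assert {"degree_centrality", "betweenness_centrality",
                "global_efficiency"} <= set(table.columns)

    def test_row_counts_and_groups(self, rng):
        table = metrics_table(self._cohort(30, rng))
        assert len(table) == 30
        assert (table["group"] == "stroke").sum() == 15

    def test_values_match_direct_recomputation(self, rng):
        items = self._cohort(5, rng)
        table = metrics_table(items).set_index("subject_id")
        for c, g, _ in items:
            assert table.loc[c.subject_id, "global_efficiency"] == \
                pytest.approx(global_efficiency(g)[0])

    def test_duplicate_ids_rejected(self, rng):
        items = self._cohort(2, rng)
        items[1] = (items[0][0], items[1][1], items[1][2])
        with pytest.raises(ValueError, match="duplicate"):
            metrics_table(items)
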