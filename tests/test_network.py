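import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from guyot.data_io import OtuTable, SampleFrame
from guyot.network import (
    build_network,
    mean_clustering_coefficient,
    modularity,
    phi_matrix,
    shared_otu_horizontal,
    shared_otu_vertical,
)


def _exhaustive_best_modularity(g: nx.Graph) -> float:
    """Brute-force maximum modularity over all partitions of the nodes."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    return max(
        nx.community.modularity(g, [set(b) for b in part])
        for part in partitions(nodes)
    )


class TestPhi:
    def test_identical_rows_zero(self):
        clr = pd.DataFrame([[1.0, 2, 3, -6]] * 2, index=["a", "b"])
        phi = phi_matrix(clr)
        assert phi.loc["a", "b"] == pytest.approx(0.0)

    def test_antiproportional_flagged_nan(self):
        x = np.array([1.0, -2, 3, -2])
        clr = pd.DataFrame([x, -x], index=["a", "b"])
        phi = phi_matrix(clr)
        assert np.isnan(phi.loc["a", "b"])

    def test_matches_elementwise_variance_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 9))
        x -= x.mean(axis=1, keepdims=True)
        clr = pd.DataFrame(x, index=list("abcd"))
        phi = phi_matrix(clr)
        for i, j in itertools.combinations(range(4), 2):
            naive = np.var(x[i] - x[j]) / np.var(x[i] + x[j])
            assert abs(phi.iloc[i, j] - naive) < 1e-12
            assert phi.iloc[i, j] == phi.iloc[j, i]


class TestBuildNetwork:
    def _phi(self, vals, ids):
        return pd.DataFrame(vals, index=ids, columns=ids)

    def test_high_phi_gives_edgeless(self):
        ids = list("abc")
        phi = self._phi(0.5 * (1 - np.eye(3)), ids)
        g = build_network(phi)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == set(ids)

    def test_zero_phi_gives_complete_graph_weight_one(self):
        ids = list("abcd")
        g = build_network(self._phi(np.zeros((4, 4)), ids))
        assert g.number_of_edges() == 6
        assert all(d["weight"] == pytest.approx(1.0) for _, _, d in g.edges(data=True))

    def test_strict_threshold_inequality(self):
        ids = list("abc")
        m = np.array([[0, 0.10, 0.14], [0.10, 0, 0.16], [0.14, 0.16, 0]])
        g = build_network(self._phi(m, ids), threshold=0.15)
        assert g.number_of_edges() == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        m = rng.random((6, 6)) * 0.3
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(6)]
        phi = self._phi(m, ids)
        edges = [
            build_network(phi, threshold=t).number_of_edges()
            for t in (0.05, 0.10, 0.15, 0.25)
        ]
        assert edges == sorted(edges)
        low = set(build_network(phi, threshold=0.05).edges)
        high = set(build_network(phi, threshold=0.25).edges)
        assert low <= high

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_network(self._phi(np.zeros((2, 2)), ["a", "b"]), threshold=0.0)


class TestModularity:
    def test_two_triangles_q_half_confirmed_exhaustively(self):
        g = nx.Graph()
        g.add_edges_from(
            [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)], weight=1.0
        )
        res = modularity(g, seed=1)
        assert res.q == pytest.approx(0.5)
        parts = {frozenset(k for k, v in res.partition.items() if v == c) for c in set(res.partition.values())}
        assert parts == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        assert _exhaustive_best_modularity(g) == pytest.approx(0.5)

    def test_complete_graph_no_structure(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        res = modularity(g, seed=0)
        assert res.q <= 0.05

    def test_single_edge_best_is_together(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        res = modularity(g, seed=0)
        # enumeration: {ab} gives Q=0, {a}{b} gives Q=-0.5
        assert res.q == pytest.approx(0.0)
        assert res.partition["a"] == res.partition["b"]

    def test_edgeless_undefined(self):
        g = nx.empty_graph(3)
        res = modularity(g, seed=0)
        assert res.q is None

    def test_louvain_beats_trivial_partition(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(12, 0.3, seed=7)
        nx.set_edge_attributes(g, 1.0, "weight")
        res = modularity(g, seed=2)
        assert res.q >= 0.0


class TestClusteringCoefficient:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([(0, 1), (1, 2), (2, 0)], 1.0),  # triangle
            ([(0, 1), (1, 2)], 0.0),  # path
            (list(itertools.combinations(range(5), 2)), 1.0),  # K5
        ],
    )
    def test_known_graphs(self, edges, expected):
        g = nx.Graph(edges)
        assert mean_clustering_coefficient(g) == pytest.approx(expected)

    def test_degree_below_two_contributes_zero(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])  # node 3 pendant
        # triangle nodes: 1,1,1/3... node2 has deg3: 1/3; mean over 4 nodes
        cc = mean_clustering_coefficient(g)
        assert cc == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)


def _presence_table(sets, universe, ids):
    counts = pd.DataFrame(0, index=ids, columns=universe)
    for sid, s in zip(ids, sets):
        counts.loc[sid, list(s)] = 3
    return OtuTable(counts)


class TestSharedOtus:
    def test_identical_sets_full_sharing_every_mode(self):
        t = _presence_table([{"A", "B"}] * 3, ["A", "B", "C"], ["s1", "s2", "s3"])
        out = shared_otu_horizontal(t, pd.Series("L1", index=t.sample_ids))
        assert out.loc["L1", ["at_least_2", "all", "mean_pairwise_jaccard"]].tolist() == [
            100.0,
            100.0,
            100.0,
        ]

    def test_disjoint_sets_zero_every_mode(self):
        t = _presence_table(
            [{"A"}, {"B"}, {"C"}], ["A", "B", "C"], ["s1", "s2", "s3"]
        )
        out = shared_otu_horizontal(t, pd.Series("L1", index=t.sample_ids))
        assert out.loc["L1", ["at_least_2", "all", "mean_pairwise_jaccard"]].tolist() == [
            0.0,
            0.0,
            0.0,
        ]

    def test_hand_enumerated_mixed_sets(self):
        # {A,B}, {B,C}, {C,D}: at_least_2 -> 2/4; all -> 0; jaccard -> 2/9
        t = _presence_table(
            [{"A", "B"}, {"B", "C"}, {"C", "D"}],
            ["A", "B", "C", "D"],
            ["s1", "s2", "s3"],
        )
        out = shared_otu_horizontal(t, pd.Series("L1", index=t.sample_ids))
        assert out.loc["L1", "at_least_2"] == pytest.approx(50.0)
        assert out.loc["L1", "all"] == pytest.approx(0.0)
        assert out.loc["L1", "mean_pairwise_jaccard"] == pytest.approx(100 * 2 / 9)

    def test_all_mode_never_exceeds_at_least_2(self, random_table):
        groups = pd.Series(
            ["L1", "L1", "L1", "L2", "L2", "L2"], index=random_table.sample_ids
        )
        out = shared_otu_horizontal(random_table, groups)
        assert (out["all"] <= out["at_least_2"] + 1e-9).all()

    def test_single_sample_layer_skipped(self, random_table):
        groups = pd.Series(
            ["L1", "L1", "L1", "L1", "L1", "L2"], index=random_table.sample_ids
        )
        out = shared_otu_horizontal(random_table, groups)
        assert np.isnan(out.loc["L2", "at_least_2"])

    def test_vertical_window_inclusive_bounds(self):
        meta = SampleFrame(
            pd.DataFrame(
                {
                    "site": ["X"] * 3,
                    "layer": ["a", "b", "c"],
                    "depth": [5.0, 500.0, 2000.0],
                },
                index=["s1", "s2", "s3"],
            )
        )
        t = _presence_table(
            [{"A", "B"}, {"A", "B"}, {"C"}], ["A", "B", "C"], ["s1", "s2", "s3"]
        )
        out = shared_otu_vertical(t, meta, depth_window=(None, 1000.0))
        assert out.loc["X", "n_samples"] == 2
        assert out.loc["X", "at_least_2"] == pytest.approx(100.0)

    def test_vertical_identical_and_disjoint(self):
        meta = SampleFrame(
            pd.DataFrame(
                {
                    "site": ["X", "X", "Y", "Y"],
                    "layer": ["a", "b", "a", "b"],
                    "depth": [5.0, 100.0, 5.0, 100.0],
                },
                index=["s1", "s2", "s3", "s4"],
            )
        )
        t = _presence_table(
            [{"A"}, {"A"}, {"B"}, {"C"}], ["A", "B", "C"], ["s1", "s2", "s3", "s4"]
        )
        out = shared_otu_vertical(t, meta)
        assert out.loc["X", "at_least_2"] == pytest.approx(100.0)
        assert out.loc["Y", "at_least_2"] == pytest.approx(0.0)

    def test_subset_commutes_with_analysis(self, random_table):
        groups = pd.Series(
            ["L1", "L1", "L2", "L2", "L1", "L2"], index=random_table.sample_ids
        )
        keep = ["s0", "s1", "s2", "s3"]
        sub = random_table.subset_samples(keep)
        direct = shared_otu_horizontal(sub, groups.loc[keep])
        pre = shared_otu_horizontal(
            OtuTable(random_table.counts.loc[keep]), groups.loc[keep]
        )
        pd.testing.assert_frame_equal(direct, pre)
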