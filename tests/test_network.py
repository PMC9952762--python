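import numpy as np
import pandas as pd
import pytest

from omicsforest import (
    InteractionNetwork,
    apply_hub_penalty,
    assign_prizes,
    edge_costs_from_confidence,
    merge_networks,
    read_network,
)


def stats_frame(rows):
    """rows: (feature_id, layer, log2fc, significant)"""
    return pd.DataFrame(
        {
            "feature_id": [r[0] for r in rows],
            "layer": [r[1] for r in rows],
            "log2fc": [r[2] for r in rows],
            "p_value": 0.01,
            "fdr": 0.01,
            "significant": [r[3] for r in rows],
        }
    )


def simple_net(nodes, edges):
    net = InteractionNetwork()
    for n, t in nodes:
        net.add_node(n, t)
    for u, v, c in edges:
        net.add_edge(u, v, c)
    return net


class TestMerge:
    def test_disjoint_union_counts(self):
        rng = np.random.default_rng(1)
        a = simple_net(
            [(f"A{i}", "gene") for i in range(10)],
            [(f"A{i}", f"A{(i+1+j) % 10}", 0.9) for i in range(10) for j in range(2)],
        )
        b = simple_net(
            [(f"B{i}", "metabolite" if i < 2 else "gene") for i in range(5)],
            [(f"B{i}", f"B{(i+1) % 5}", 0.8) for i in range(5)] + [("B0", "B2", 0.7), ("B1", "B3", 0.7), ("B2", "B4", 0.7)],
        )
        merged = merge_networks(a, b)
        assert merged.n_nodes == a.n_nodes + b.n_nodes
        assert merged.n_edges == a.n_edges + b.n_edges

    def test_duplicate_edge_keeps_max_confidence(self):
        a = simple_net([("X", "gene"), ("Y", "gene")], [("X", "Y", 0.3)])
        b = simple_net([("X", "gene"), ("Y", "gene")], [("X", "Y", 0.9)])
        merged = merge_networks(a, b)
        assert merged.n_edges == 1
        assert merged.graph.edges["X", "Y"]["confidence"] == 0.9

    def test_conflicting_node_type_rejected(self):
        a = simple_net([("X", "gene")], [])
        b = simple_net([("X", "metabolite")], [])
        with pytest.raises(ValueError, match="X"):
            merge_networks(a, b)

    def test_commutative_and_idempotent(self):
        a = simple_net([("X", "gene"), ("Y", "gene"), ("Z", "metabolite")],
                       [("X", "Y", 0.6), ("Y", "Z", 0.8)])
        b = simple_net([("Y", "gene"), ("W", "gene")], [("Y", "W", 0.5)])
        ab, ba = merge_networks(a, b), merge_networks(b, a)
        assert set(ab.nodes()) == set(ba.nodes())
        assert set(map(frozenset, ab.graph.edges)) == set(map(frozenset, ba.graph.edges))
        aa = merge_networks(a, a)
        assert set(aa.nodes()) == set(a.nodes())
        assert aa.n_edges == a.n_edges


class TestPrizes:
    def test_metabolite_fold_change_becomes_absolute_prize(self):
        net = simple_net([("citric acid", "metabolite"), ("G", "gene")],
                         [("citric acid", "G", 0.9)])
        out = assign_prizes(net, stats_frame([("citric acid", "metabolite", -2.6, True)]))
        assert out.prize("citric acid") == pytest.approx(2.6)

    def test_max_abs_rule_across_layers(self):
        net = simple_net([("G", "gene"), ("H", "gene")], [("G", "H", 0.9)])
        stats = stats_frame([("G", "transcript", 2.0, True), ("G", "protein", -3.0, True)])
        assert assign_prizes(net, stats).prize("G") == pytest.approx(3.0)

    def test_unmeasured_nodes_have_zero_prize(self):
        net = simple_net([("G", "gene"), ("H", "gene")], [("G", "H", 0.9)])
        out = assign_prizes(net, stats_frame([("G", "transcript", 1.0, True)]))
        assert out.prize("H") == 0.0
        assert out.graph.nodes["H"]["measured"] is False
        unmeasured_total = sum(
            out.prize(v) for v in out.nodes() if not out.graph.nodes[v]["measured"]
        )
        assert unmeasured_total == 0.0

    def test_significant_only_and_floor_options(self):
        net = simple_net([("G", "gene"), ("H", "gene")], [("G", "H", 0.9)])
        stats = stats_frame([("G", "transcript", 2.0, False), ("H", "transcript", 0.4, True)])
        out = assign_prizes(net, stats, significant_only=True)
        assert out.prize("G") == 0.0 and out.prize("H") == pytest.approx(0.4)
        out = assign_prizes(net, stats, prize_floor=1.0)
        assert out.prize("G") == pytest.approx(2.0) and out.prize("H") == 0.0

    def test_features_absent_from_network_are_not_added(self):
        net = simple_net([("G", "gene"), ("H", "gene")], [("G", "H", 0.9)])
        out = assign_prizes(net, stats_frame([("nowhere", "transcript", 5.0, True)]))
        assert "nowhere" not in out.graph


class TestHubPenalty:
    def make_prized(self):
        net = simple_net(
            [("A", "gene"), ("B", "gene"), ("C", "gene"), ("D", "gene"), ("E", "gene")],
            [("A", "B", 0.9), ("A", "C", 0.9), ("A", "D", 0.9), ("A", "E", 0.9)],
        )
        net.graph.nodes["A"].update(prize=3.0, raw_prize=3.0)
        net.graph.nodes["B"].update(prize=1.0, raw_prize=1.0)
        return net

    def test_zero_mu_is_identity(self):
        net = self.make_prized()
        out = apply_hub_penalty(net, 0.0)
        assert [out.prize(v) for v in out.nodes()] == [net.prize(v) for v in net.nodes()]

    def test_degree_proportional_reduction_and_clamp(self):
        net = self.make_prized()
        out = apply_hub_penalty(net, 0.5)
        assert out.prize("A") == pytest.approx(1.0)  # 3 - 0.5*4
        assert out.prize("B") == pytest.approx(0.5)  # 1 - 0.5*1
        net.graph.nodes["A"].update(prize=1.0, raw_prize=1.0)
        heavily = apply_hub_penalty(net, 0.5)
        assert heavily.prize("A") == 0.0  # clamped

    def test_never_increases_any_prize(self):
        net = self.make_prized()
        out = apply_hub_penalty(net, 0.2)
        assert all(out.prize(v) <= net.prize(v) for v in net.nodes())

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            apply_hub_penalty(self.make_prized(), -0.1)


class TestEdgeCosts:
    def test_cost_is_one_minus_confidence(self):
        net = simple_net([("A", "gene"), ("B", "gene"), ("C", "gene")],
                         [("A", "B", 1.0), ("B", "C", 0.8)])
        out = edge_costs_from_confidence(net)
        assert out.cost("A", "B") == pytest.approx(0.0)
        assert out.cost("B", "C") == pytest.approx(0.2)

    def test_monotone_in_confidence(self):
        rng = np.random.default_rng(2)
        confs = rng.uniform(0.05, 1.0, 10)
        net = InteractionNetwork()
        for i in range(11):
            net.add_node(f"N{i}", "gene")
        for i, c in enumerate(confs):
            net.add_edge(f"N{i}", f"N{i+1}", float(c))
        out = edge_costs_from_confidence(net)
        costs = [out.cost(f"N{i}", f"N{i+1}") for i in range(10)]
        order_by_conf = np.argsort(confs)
        assert all(
            costs[order_by_conf[i]] >= costs[order_by_conf[i + 1]] for i in range(9)
        )


class TestIO:
    def test_edge_list_and_types_round_trip(self, tmp_path):
        (tmp_path / "edges.tsv").write_text("G1\tG2\t0.9\nG2\tM1\t0.7\n")
        (tmp_path / "types.tsv").write_text("G1\tgene\nG2\tgene\nM1\tmetabolite\n")
        net = read_network(tmp_path / "edges.tsv", tmp_path / "types.tsv")
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.node_type("M1") == "metabolite"

    def test_graphml_export_loads_back(self, tmp_path):
        import networkx as nx

        net = simple_net([("G1", "gene"), ("M1", "metabolite")], [("G1", "M1", 0.8)])
        net = edge_costs_from_confidence(net)
        net.write_graphml(tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert set(g.nodes) == {"G1", "M1"}
        assert g.nodes["M1"]["node_type"] == "metabolite"
        assert g.edges["G1", "M1"]["cost"] == pytest.approx(0.2)
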