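"""Centrality statistics: worked examples, closed forms, and oracles."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiscreen.centrality import (
    all_pairs_distances,
    betweenness,
    centrality_table,
    closeness,
    closeness_from_avg_length,
    round_for_report,
    stress,
)
from ppiscreen.graph import InputError, Network

from ._oracles import enumerate_bc_stress, fw_distances, random_connected_net


def cycle(n: int) -> Network:
    return Network(edges=[(f"N{i}", f"N{(i + 1) % n}") for i in range(n)])


def complete(n: int) -> Network:
    return Network(
        edges=[(f"N{i}", f"N{j}") for i in range(n) for j in range(i + 1, n)]
    )


def path(n: int) -> Network:
    return Network(edges=[(f"N{i}", f"N{i + 1}") for i in range(n - 1)])


class TestDistances:
    def test_path_distances(self, path3):
        d = all_pairs_distances(path3)
        assert d["A"]["C"] == 2 and d["A"]["B"] == 1 and d["A"]["A"] == 0

    def test_unreachable_pairs_omitted(self):
        net = Network(edges=[("A", "B"), ("C", "D")])
        d = all_pairs_distances(net)
        assert "C" not in d["A"]

    def test_symmetry(self, mixed_net):
        d = all_pairs_distances(mixed_net)
        for a in d:
            for b, dist in d[a].items():
                assert d[b][a] == dist

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_floyd_warshall_on_random_graphs(self, seed):
        net = random_connected_net(20, 0.15, seed)
        mine = all_pairs_distances(net)
        ref = fw_distances(net)
        for a in net.nodes:
            for b in net.nodes:
                assert mine[a].get(b, float("inf")) == ref[a][b]


class TestCloseness:
    def test_star_center_is_one(self, star5):
        avg_l, cc = closeness(star5, "C")
        assert avg_l == 1.0 and cc == 1.0

    def test_star_leaf(self, star5):
        avg_l, cc = closeness(star5, "L1")
        assert avg_l == pytest.approx(7 / 4)
        assert cc == pytest.approx(4 / 7)

    def test_isolated_node_is_undefined(self):
        net = Network(nodes=["X"], edges=[("A", "B")])
        assert closeness(net, "X") == (None, None)

    def test_reciprocal_definition(self):
        # 1/1.91 -> 0.52 at report precision, the published worked example
        assert round_for_report(closeness_from_avg_length(1.91)) == 0.52

    def test_averages_over_component_only(self, mixed_net):
        avg_l, cc = closeness(mixed_net, "T1")
        assert avg_l == 1.0 and cc == 1.0


class TestBetweennessStress:
    def test_path_middle_node(self, path3):
        assert betweenness(path3, "B") == 1.0
        assert stress(path3, "B") == 1

    def test_triangle_all_zero(self, triangle):
        for n in "ABC":
            assert betweenness(triangle, n) == 0.0
            assert stress(triangle, n) == 0

    def test_four_cycle_stress_one_each(self):
        net = cycle(4)
        for n in net.nodes:
            assert stress(net, n) == 1

    def test_star_center_stress_closed_form(self):
        for k in (3, 4, 6):
            net = Network(edges=[("C", f"L{i}") for i in range(k)])
            assert stress(net, "C") == k * (k - 1) // 2

    def test_leaf_has_zero_centrality(self, star5):
        assert betweenness(star5, "L1") == 0.0
        assert stress(star5, "L1") == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration_oracle(self, seed):
        net = random_connected_net(10, 0.3, seed)
        bc_ref, stress_ref = enumerate_bc_stress(net)
        table = centrality_table(net)
        for rec in table:
            assert rec.betweenness == pytest.approx(bc_ref[rec.node], abs=1e-12)
            assert rec.stress == stress_ref[rec.node]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_betweenness(self, seed):
        """Cross-check against an unrelated production implementation."""
        net = random_connected_net(15, 0.25, seed)
        ref = nx.betweenness_centrality(
            nx.Graph(net.sorted_edges()), normalized=True
        )
        table = centrality_table(net)
        for rec in table:
            assert rec.betweenness == pytest.approx(ref[rec.node], abs=1e-12)


class TestClosedForms:
    """Star, path, cycle, and complete graphs against hand-derived formulas."""

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star(self, k):
        net = Network(edges=[("C", f"L{i}") for i in range(k)])
        table = centrality_table(net)
        center = table.record("C")
        assert center.degree == k
        assert center.avg_l == 1.0 and center.closeness == 1.0
        assert center.betweenness == pytest.approx(1.0)
        assert center.stress == k * (k - 1) // 2
        leaf = table.record("L0")
        assert leaf.degree == 1
        assert leaf.avg_l == pytest.approx((2 * k - 1) / k)
        assert leaf.closeness == pytest.approx(k / (2 * k - 1))
        assert leaf.betweenness == 0.0 and leaf.stress == 0

    @pytest.mark.parametrize("n", [4, 7])
    def test_path(self, n):
        table = centrality_table(path(n))
        for i in range(n):
            rec = table.record(f"N{i}")
            assert rec.degree == (1 if i in (0, n - 1) else 2)
            assert rec.avg_l == pytest.approx(
                sum(abs(i - j) for j in range(n) if j != i) / (n - 1)
            )
            pairs_through = i * (n - 1 - i)
            assert rec.stress == pairs_through  # unique geodesics on a path
            assert rec.betweenness == pytest.approx(
                pairs_through * 2 / ((n - 1) * (n - 2))
            )

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_cycle(self, n):
        table = centrality_table(cycle(n))
        total_dist = n * n / 4 if n % 2 == 0 else (n * n - 1) / 4
        if n % 2 == 1:
            h = (n - 1) // 2
            expected_stress = (h - 1) * h // 2
            expected_raw_bc = expected_stress
        else:
            h = n // 2
            expected_stress = (h - 2) * (h - 1) // 2 + (h - 1)
            expected_raw_bc = (h - 2) * (h - 1) / 2 + (h - 1) / 2
        for rec in table:
            assert rec.degree == 2
            assert rec.avg_l == pytest.approx(total_dist / (n - 1))
            assert rec.closeness == pytest.approx((n - 1) / total_dist)
            assert rec.stress == expected_stress
            assert rec.betweenness == pytest.approx(
                expected_raw_bc * 2 / ((n - 1) * (n - 2))
            )

    @pytest.mark.parametrize("n", [3, 5])
    def test_complete(self, n):
        for rec in centrality_table(complete(n)):
            assert rec.degree == n - 1
            assert rec.avg_l == 1.0 and rec.closeness == 1.0
            assert rec.betweenness == 0.0 and rec.stress == 0


class TestCentralityTable:
    def test_disconnected_input_rejected(self, mixed_net):
        with pytest.raises(InputError, match="decompose"):
            centrality_table(mixed_net)

    def test_sorted_by_closeness_desc_then_symbol(self, star5):
        table = centrality_table(star5)
        assert [r.node for r in table] == ["C", "L1", "L2", "L3", "L4"]

    def test_one_record_per_node(self, triangle):
        table = centrality_table(triangle)
        assert sorted(r.node for r in table) == ["A", "B", "C"]

    def test_planted_dominating_hub_attains_max_closeness(self):
        from ppiscreen.synthetic import GeneratorConfig, generate

        cfg = GeneratorConfig(
            n_main=30, n_isolated=0, small_sizes=(), n_hubs=1,
            hub_boost=28, seed=7,
        )
        net, truth = generate(cfg)
        table = centrality_table(net)
        assert table.records[0].node in truth
        assert table.records[0].closeness == 1.0  # adjacent to every node

    def test_tsv_export_layout(self, path3):
        tsv = centrality_table(path3).to_tsv()
        lines = tsv.strip().split("\n")
        assert lines[0] == "node\tdegree\tstress\tavg_L\tbetweenness\tcloseness"
        assert lines[1].startswith("B\t2\t1\t1.00\t1.00\t1.00")


class TestInvariantProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_closeness_avg_l_reciprocal(self, seed):
        net = random_connected_net(8, 0.4, seed)
        for rec in centrality_table(net):
            assert rec.closeness * rec.avg_l == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adding_edge_monotonicity(self, seed):
        """New edge: endpoint degrees never drop, no avg_L ever rises."""
        net = random_connected_net(8, 0.4, seed)
        missing = [
            (a, b)
            for i, a in enumerate(net.sorted_nodes())
            for b in net.sorted_nodes()[i + 1 :]
            if not net.has_edge(a, b)
        ]
        if not missing:
            return
        a, b = missing[seed % len(missing)]
        before = {r.node: r for r in centrality_table(net)}
        grown = Network(nodes=net.sorted_nodes(), edges=net.sorted_edges())
        grown.add_edge(a, b)
        after = {r.node: r for r in centrality_table(grown)}
        assert after[a].degree == before[a].degree + 1
        for node in net.nodes:
            assert after[node].avg_l <= before[node].avg_l + 1e-12
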