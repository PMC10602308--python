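"""Signed network construction, root finding, attachment and direction split."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from phosphowalk.arrays import KSRelation
from phosphowalk.errors import AmbiguousProbeError
from phosphowalk.fixtures import load_demo_relations
from phosphowalk.network import (
    attach_measurements,
    build_network,
    find_roots,
    split_signed,
)

from conftest import attach_cfc, measurement


class TestBuildNetwork:
    def test_unknown_effect_coerced_to_activation(self):
        net = build_network([KSRelation("A", "B", "S1", "unknown")])
        assert net.edge_data("A", "B", "S1")["effect"] == "activation"
        assert all(
            net.edge_data(*key)["effect"] in ("activation", "inhibition")
            for key in net.edge_keys()
        )

    def test_signs_and_nodes_preserved(self):
        net = build_network(
            [
                KSRelation("PDK1", "AKT", "S473", "activation"),
                KSRelation("AKT", "BAD", "S75", "inhibition"),
            ]
        )
        assert set(net.nodes) == {"PDK1", "AKT", "BAD"}
        assert net.n_edges() == 2
        assert net.edge_data("AKT", "BAD", "S75")["effect"] == "inhibition"

    def test_empty_relations_give_empty_network(self):
        net = build_network([])
        assert len(net.nodes) == 0 and net.n_edges() == 0

    def test_same_pair_may_carry_multiple_site_edges(self):
        net = build_network(
            [
                KSRelation("PDK1", "AKT", "S473", "activation"),
                KSRelation("PDK1", "AKT", "T308", "activation"),
            ]
        )
        assert net.n_edges() == 2


class TestFindRoots:
    def test_simple_chain_root(self):
        net = build_network(
            [KSRelation("A", "B", "S1", "activation"), KSRelation("B", "C", "S2", "activation")]
        )
        assert find_roots(net) == {"A"}

    def test_demo_fixture_roots_include_upstream_kinases(self):
        roots = find_roots(build_network(load_demo_relations()))
        assert {"PDK1", "SRC"} <= roots

    def test_pure_cycle_has_no_roots(self, two_cycle_network):
        assert find_roots(two_cycle_network) == set()

    @given(
        edges=st.lists(
            st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]),
            max_size=20,
            unique=True,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_roots_match_brute_force_degree_count(self, edges):
        rels = [
            KSRelation(f"N{a}", f"N{b}", f"S{i + 1}", "activation")
            for i, (a, b) in enumerate(edges)
        ]
        net = build_network(rels)
        brute = {
            node
            for node in net.nodes
            if not any(sub == node for _, sub, _ in net.edge_keys())
        }
        assert find_roots(net) == brute


class TestAttachMeasurements:
    def test_probe_sets_every_edge_delivering_the_site(self):
        net = build_network(
            [
                KSRelation("PDK1", "AKT", "S473", "activation"),
                KSRelation("MAPK14", "AKT", "S473", "activation"),
                KSRelation("PDK1", "AKT", "T308", "activation"),
            ]
        )
        attached = attach_cfc(net, {("AKT", "S473"): 25.0})
        assert attached.edge_data("PDK1", "AKT", "S473")["cfc"] == 25.0
        assert attached.edge_data("MAPK14", "AKT", "S473")["cfc"] == 25.0
        assert attached.edge_data("PDK1", "AKT", "T308")["cfc"] is None

    def test_pan_probe_annotates_node_only(self):
        net = build_network([KSRelation("PDK1", "AKT", "S473", "activation")])
        m = measurement("x", "AKT", "pan", 32.0)  # log2fc ~0.4
        attached = attach_measurements(net, [m])
        assert attached.graph.nodes["AKT"]["expression_log2fc"] == pytest.approx(
            m.log2fc
        )
        assert attached.edge_data("PDK1", "AKT", "S473")["cfc"] is None

    def test_unmatched_probe_reported_unmapped(self):
        net = build_network([KSRelation("A", "B", "S1", "activation")])
        attached = attach_measurements(net, [measurement("x", "B", "S999", 10.0)])
        assert attached.unmapped_probes == ["x"]
        assert attached.edge_data("A", "B", "S1")["cfc"] is None

    def test_two_probes_for_one_site_is_ambiguous(self):
        net = build_network([KSRelation("A", "B", "S1", "activation")])
        with pytest.raises(AmbiguousProbeError, match="x.*y|y.*x"):
            attach_measurements(
                net, [measurement("x", "B", "S1", 10.0), measurement("y", "B", "S1", 12.0)]
            )


class TestSplitSigned:
    def build_attached(self, cfcs):
        net = build_network(
            [
                KSRelation("A", "B", "S1", "activation"),
                KSRelation("A", "C", "S2", "activation"),
                KSRelation("A", "D", "S3", "activation"),
            ]
        )
        return attach_cfc(net, cfcs)

    def test_partition_of_measured_and_sharing_of_unmeasured(self):
        attached = self.build_attached({("B", "S1"): 10.0, ("C", "S2"): -8.0})
        up, down = split_signed(attached)
        assert set(up.edge_keys()) == {("A", "B", "S1"), ("A", "D", "S3")}
        assert set(down.edge_keys()) == {("A", "C", "S2"), ("A", "D", "S3")}

    def test_all_positive_leaves_only_unmeasured_in_down(self):
        attached = self.build_attached({("B", "S1"): 10.0, ("C", "S2"): 8.0})
        up, down = split_signed(attached)
        assert set(down.edge_keys()) == {("A", "D", "S3")}

    def test_zero_cfc_excluded_from_both(self):
        attached = self.build_attached({("B", "S1"): 0.0})
        up, down = split_signed(attached)
        assert ("A", "B", "S1") not in set(up.edge_keys())
        assert ("A", "B", "S1") not in set(down.edge_keys())

    def test_measured_edges_never_in_both(self):
        attached = self.build_attached({("B", "S1"): 5.0, ("C", "S2"): -5.0, ("D", "S3"): 0.0})
        up, down = split_signed(attached)
        measured_up = {k for k in up.edge_keys() if up.edge_data(*k)["cfc"] is not None}
        measured_down = {k for k in down.edge_keys() if down.edge_data(*k)["cfc"] is not None}
        assert not (measured_up & measured_down)


class TestSerialisation:
    def test_graphml_round_trip(self, tmp_path):
        net = build_network(load_demo_relations())
        attached = attach_cfc(net, {("AKT", "S473"): 25.0, ("CDK1", "Y15"): -20.0})
        path = tmp_path / "net.graphml"
        attached.to_graphml(path)
        back = type(attached).from_graphml(path)
        assert set(back.edge_keys()) == set(attached.edge_keys())
        assert back.edge_data("PDK1", "AKT", "S473")["cfc"] == 25.0

    def test_edgelist_export(self, tmp_path):
        net = attach_cfc(
            build_network([KSRelation("A", "B", "S1", "activation")]), {("B", "S1"): 7.5}
        )
        path = tmp_path / "net.tsv"
        net.to_edgelist(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["kinase", "substrate", "site", "effect", "cfc", "weight"]
        assert lines[1].startswith("A\tB\tS1\tactivation\t7.5")
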