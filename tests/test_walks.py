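"""Chain inference: termination, imputation, enumeration oracle, walks,
permutation null, parallel resolution and selection."""

from __future__ import annotations

import pytest

from phosphowalk.arrays import KSRelation
from phosphowalk.config import RunConfig
from phosphowalk.errors import NotApplicableError, ParameterError, RootlessNetworkError
from phosphowalk.network import build_network
from phosphowalk.walks import (
    check_termination,
    enumerate_chains,
    impute_single_path,
    infer_direction_run,
    null_expectation,
    random_walk,
    resolve_parallel,
    select_chains,
)

from conftest import attach_cfc, chain


class TestCheckTermination:
    def test_inhibitory_last_edge_stops(self, fork_network):
        c = chain([("A", "B", "S1", "activation"), ("B", "D", "S3", "inhibition")], [10.0, 10.0])
        assert check_termination(c, fork_network) == "inhibition"

    def test_node_without_fresh_edges_is_sink(self, fork_network):
        c = chain([("A", "B", "S1", "activation"), ("B", "C", "S2", "activation")], [10.0, 10.0])
        assert check_termination(c, fork_network) == "sink"

    def test_fresh_activation_edge_continues(self, fork_network):
        c = chain([("A", "B", "S1", "activation")], [10.0])
        assert check_termination(c, fork_network) == "continue"


class TestImputeSinglePath:
    def test_control_condition_is_exactly_twenty(self, single_path_network):
        assert impute_single_path("A", single_path_network, "control", 7) == 20.0

    def test_experimental_draw_is_bounded_and_reproducible(self, single_path_network):
        v1 = impute_single_path("A", single_path_network, "experimental", 7)
        v2 = impute_single_path("A", single_path_network, "experimental", 7)
        assert 0.0 <= v1 <= 20.0
        assert v1 == v2

    def test_two_downstream_options_not_applicable(self, fork_network):
        with pytest.raises(NotApplicableError):
            impute_single_path("B", fork_network, "experimental", 7)

    def test_fixed_mode_is_midpoint(self, single_path_network):
        assert impute_single_path("A", single_path_network, "experimental", 7, "fixed") == 10.0


class TestEnumerateChains:
    def test_equal_weight_fork_splits_half_half(self, fork_network):
        dist = enumerate_chains(fork_network)
        abc = (("A", "B", "S1"), ("B", "C", "S2"))
        abd = (("A", "B", "S1"), ("B", "D", "S3"))
        assert dist == {abc: pytest.approx(0.5), abd: pytest.approx(0.5)}

    def test_single_path_has_probability_one(self, single_path_network):
        dist = enumerate_chains(single_path_network)
        assert dist == {(("A", "B", "T7"),): pytest.approx(1.0)}

    def test_rootless_network_raises(self, two_cycle_network):
        with pytest.raises(RootlessNetworkError):
            enumerate_chains(two_cycle_network)

    def test_probabilities_sum_to_one_with_weights(self, fork_network):
        attached = attach_cfc(fork_network, {("C", "S2"): 30.0, ("D", "S3"): -10.0})
        dist = enumerate_chains(attached)
        assert sum(dist.values()) == pytest.approx(1.0)
        # weighted transition: P(B->C) = 31/(31+11)
        abc = (("A", "B", "S1"), ("B", "C", "S2"))
        assert dist[abc] == pytest.approx(31.0 / 42.0)


class TestRandomWalk:
    def test_matches_enumeration_oracle(self, fork_network):
        est = random_walk(fork_network, 100_000, seed=5)
        abc = (("A", "B", "S1"), ("B", "C", "S2"))
        abd = (("A", "B", "S1"), ("B", "D", "S3"))
        assert est.observed[abc] == pytest.approx(0.5, abs=0.01)
        assert est.observed[abd] == pytest.approx(0.5, abs=0.01)

    def test_deterministic_single_path(self, single_path_network):
        est = random_walk(single_path_network, 1000, seed=0)
        assert est.observed == {(("A", "B", "T7"),): 1.0}

    def test_same_seed_identical_estimate(self, fork_network):
        a = random_walk(fork_network, 5000, seed=11)
        b = random_walk(fork_network, 5000, seed=11)
        assert a.observed == b.observed

    def test_invalid_walk_count(self, fork_network):
        with pytest.raises(ParameterError):
            random_walk(fork_network, 0, seed=1)

    def test_rootless_raises(self, two_cycle_network):
        with pytest.raises(RootlessNetworkError):
            random_walk(two_cycle_network, 100, seed=1)

    def test_cyclic_network_walks_are_edge_self_avoiding(self):
        net = build_network(
            [
                KSRelation("R", "A", "S1", "activation"),
                KSRelation("A", "B", "S2", "activation"),
                KSRelation("B", "A", "S3", "activation"),
            ]
        )
        est = random_walk(net, 2000, seed=3)
        for key in est.observed:
            assert len(key) == len(set(key))  # no edge repeats
            assert len(key) <= 3

    def test_observed_frequencies_sum_to_one(self, fork_network):
        est = random_walk(fork_network, 10_000, seed=2)
        assert sum(est.observed.values()) == pytest.approx(1.0)


class TestNullExpectation:
    def test_equal_weights_give_unit_enrichment(self, fork_network):
        attached = attach_cfc(
            fork_network, {("B", "S1"): 10.0, ("C", "S2"): 10.0, ("D", "S3"): 10.0}
        )
        est = null_expectation(attached, 20_000, 40, seed=1)
        for key, enr in est.enrichment.items():
            assert enr == pytest.approx(1.0, rel=0.15)

    def test_heavy_branch_enriched_light_depleted(self):
        net = build_network(
            [
                KSRelation("A", "B", "S1", "activation"),
                KSRelation("A", "C", "S2", "activation"),
            ]
        )
        attached = attach_cfc(net, {("B", "S1"): 100.0, ("C", "S2"): 10.0})
        est = null_expectation(attached, 20_000, 100, seed=2)
        heavy = ((("A", "B", "S1"),))
        assert est.enrichment[(("A", "B", "S1"),)] > 1.0
        assert est.enrichment[(("A", "C", "S2"),)] < 1.0

    def test_expected_reproducible_for_fixed_seed(self, fork_network):
        attached = attach_cfc(fork_network, {("C", "S2"): 25.0})
        a = null_expectation(attached, 2000, 20, seed=9)
        b = null_expectation(attached, 2000, 20, seed=9)
        assert a.expected == b.expected and a.enrichment == b.enrichment

    def test_zero_permutations_rejected(self, fork_network):
        with pytest.raises(ParameterError):
            null_expectation(fork_network, 100, 0, seed=1)


class TestResolveParallel:
    def test_greater_magnitude_wins_for_shared_site(self):
        weak = chain([("A", "JUN", "S73", "activation")], [10.0])
        strong = chain([("B", "JUN", "S73", "activation")], [25.0])
        kept = resolve_parallel([weak, strong])
        assert kept == [strong]

    def test_different_sites_unaffected(self):
        c1 = chain([("PDK1", "AKT", "S473", "activation")], [25.0])
        c2 = chain([("SRC", "AKT", "Y326", "activation")], [10.0])
        assert set(c.key for c in resolve_parallel([c1, c2])) == {c1.key, c2.key}

    def test_ties_keep_all_in_deterministic_order(self):
        c1 = chain([("B", "JUN", "S73", "activation")], [25.0])
        c2 = chain([("A", "JUN", "S73", "activation")], [25.0])
        kept = resolve_parallel([c1, c2])
        assert [c.edges[0][0] for c in kept] == ["A", "B"]

    def test_same_kinase_chains_not_competing(self):
        c1 = chain([("A", "JUN", "S73", "activation")], [10.0])
        c2 = chain([("X", "A", "S9", "activation"), ("A", "JUN", "S73", "activation")],
                   [30.0, 10.0])
        assert len(resolve_parallel([c1, c2])) == 2


def _long_chain(cfcs):
    edges = [(f"N{i}", f"N{i + 1}", f"S{i + 1}", "activation") for i in range(len(cfcs))]
    return chain(edges, cfcs)


class TestSelectChains:
    def test_two_intermediates_rejected(self):
        assert select_chains([_long_chain([10, 10, 10])]) == []  # 3 edges = 2 internal

    def test_three_intermediates_all_above_threshold_retained(self):
        kept = select_chains([_long_chain([6, 6, 6, 6])])  # 4 edges = 3 internal
        assert len(kept) == 1

    def test_interior_weak_edge_rejects_chain(self):
        assert select_chains([_long_chain([10, 4, 10, 10, 10])]) == []

    def test_trailing_weak_edges_trimmed_not_fatal(self):
        kept = select_chains([_long_chain([10, 10, 10, 10, 2.0])])
        assert len(kept) == 1
        assert len(kept[0].edges) == 4

    def test_boundary_is_strict(self):
        assert select_chains([_long_chain([5.0, 5.0, 5.0, 5.0])]) == []

    def test_output_sorted_by_score_descending(self):
        a = _long_chain([6, 6, 6, 6])
        b = chain(
            [(f"M{i}", f"M{i + 1}", f"T{i + 1}", "activation") for i in range(4)],
            [20, 20, 20, 20],
        )
        assert [c.score for c in select_chains([a, b])] == [20, 6]

    def test_raising_min_cfc_never_grows_selection(self):
        chains = [
            _long_chain([30, 25, 18, 12]),
            _long_chain([8, 7, 9, 6]),
            _long_chain([50, 45, 40, 35]),
        ]
        previous = None
        for min_cfc in (0, 5, 10, 20, 40, 60):
            keys = {c.key for c in select_chains(chains, min_cfc=min_cfc)}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_mean_mode_uses_aggregate(self):
        c = _long_chain([20, 4, 20, 20])
        assert select_chains([c], cfc_mode="mean") and not select_chains([c])


class TestInferDirectionRun:
    @pytest.fixture
    def planted_network(self):
        rels = [
            KSRelation("R", "A", "S1", "activation"),
            KSRelation("A", "B", "S2", "activation"),
            KSRelation("B", "C", "S3", "activation"),
            KSRelation("C", "D", "S4", "activation"),
            KSRelation("D", "E", "S5", "activation"),
            KSRelation("R", "X", "S6", "activation"),
            KSRelation("X", "Y", "S7", "activation"),
            KSRelation("B", "Z", "S8", "activation"),
        ]
        cfcs = {
            ("A", "S1"): 30.0,
            ("B", "S2"): 28.0,
            ("C", "S3"): 32.0,
            ("D", "S4"): 29.0,
            ("E", "S5"): 31.0,
        }
        return attach_cfc(build_network(rels), cfcs)

    def test_planted_path_recovered_in_up_direction(self, planted_network):
        run = infer_direction_run(planted_network, RunConfig(seed=3))
        keys = {c.key for c in run.up_chains}
        planted = tuple(
            (k, s, f"S{i + 1}")
            for i, (k, s) in enumerate(
                [("R", "A"), ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
            )
        )
        assert planted in keys
        assert run.down_chains == []
        hit_sites = {(t, s) for t, s, d, _ in run.hits if d == "up"}
        assert {("A", "S1"), ("E", "S5")} <= hit_sites

    def test_termination_soundness_of_emitted_chains(self, planted_network):
        run = infer_direction_run(planted_network, RunConfig(seed=3))
        for est in (run.up_estimate, run.down_estimate):
            for c in est.chains.values():
                effects = [e[3] for e in c.edges]
                # no edge ever follows an inhibitory edge
                assert "inhibition" not in effects[:-1]
                assert c.termination_reason in ("sink", "inhibition", "max_length")

    def test_identical_seed_gives_identical_chains(self, planted_network):
        a = infer_direction_run(planted_network, RunConfig(seed=5))
        b = infer_direction_run(planted_network, RunConfig(seed=5))
        assert [c.key for c in a.up_chains] == [c.key for c in b.up_chains]
        assert a.hits == b.hits

    def test_empty_network_yields_nothing(self):
        net = attach_cfc(build_network([]), {})
        run = infer_direction_run(net, RunConfig(seed=1))
        assert run.up_chains == [] and run.down_chains == [] and run.hits == []
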