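"""Dependency graphs, blanket extraction, classification and d-separation."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroblankets.graph import (
    BlanketPartition,
    CyclicGraphError,
    DependencyGraph,
    GraphError,
    PartitionError,
    StateNode,
    ViolationRule,
    all_dags_in_order,
    classify_blanket,
    d_separated,
    partition_from_roles,
    pearl_blanket,
    unroll_one_step,
    validate_partition,
)


def brute_force_blanket(graph: DependencyGraph, target: str) -> set[str]:
    """Smallest S separating the target from every other node, by subset search.

    Independent oracle: enumerates candidate conditioning sets in increasing
    size and returns the unique smallest one that d-separates the target
    from the remaining nodes.
    """
    others = sorted(graph.node_ids - {target})
    for size in range(len(others) + 1):
        found = [
            set(S) for S in itertools.combinations(others, size)
            if d_separated(graph, {target}, set(others) - set(S), set(S))
        ]
        if found:
            assert len(found) == 1, "minimal separator should be unique"
            return found[0]
    raise AssertionError("unreachable: the full complement always separates")


class TestDependencyGraph:
    def test_duplicate_ids_rejected(self):
        g = DependencyGraph(nodes=["a"])
        with pytest.raises(GraphError, match="duplicate"):
            g.add_node("a")

    def test_self_loops_rejected(self):
        g = DependencyGraph(nodes=["a"])
        with pytest.raises(GraphError, match="implicit"):
            g.add_edge("a", "a")

    def test_edge_endpoints_must_exist(self):
        g = DependencyGraph(nodes=["a"])
        with pytest.raises(GraphError, match="unknown node"):
            g.add_edge("a", "b")

    def test_bad_role_rejected(self):
        with pytest.raises(GraphError, match="role"):
            StateNode("a", role="blanket")

    def test_networkx_round_trip(self, six_node_dag):
        again = DependencyGraph.from_networkx(six_node_dag.to_networkx())
        assert again == six_node_dag


class TestPearlBlanket:
    def test_parents_children_coparents(self, six_node_dag):
        assert pearl_blanket(six_node_dag, {"3"}) == {"1", "2", "4", "5"}

    def test_isolated_node_has_empty_blanket(self):
        g = DependencyGraph(nodes=["x", "y"], edges=[])
        assert pearl_blanket(g, {"x"}) == set()

    def test_all_nodes_give_empty_blanket(self, six_node_dag):
        assert pearl_blanket(six_node_dag, six_node_dag.node_ids) == set()

    def test_unknown_target_named_in_error(self, six_node_dag):
        with pytest.raises(GraphError, match="'zz'"):
            pearl_blanket(six_node_dag, {"zz"})

    def test_agrees_with_minimal_separator_on_all_5_node_dags(self):
        """Exhaustive: every 5-node DAG structure, every target node.

        The blanket (parents + children + co-parents) must equal the unique
        smallest conditioning set that d-separates the target from all
        remaining nodes.
        """
        for g in all_dags_in_order(5):
            for v in g.node_ids:
                assert pearl_blanket(g, {v}) == brute_force_blanket(g, v)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_minimal_separator_on_random_10_node_dags(self, seed):
        from neuroblankets.fixtures import random_dag

        g = random_dag(10, 0.3, seed=seed)
        v = sorted(g.node_ids)[seed % 10]
        assert pearl_blanket(g, {v}) == brute_force_blanket(g, v)


class TestDSeparation:
    def test_blocked_chain(self):
        g = DependencyGraph(nodes=["a", "b", "c"], edges=[("a", "b"), ("b", "c")])
        assert d_separated(g, {"a"}, {"c"}, {"b"})
        assert not d_separated(g, {"a"}, {"c"}, set())

    def test_conditioned_collider_opens_path(self):
        g = DependencyGraph(nodes=["a", "b", "c"], edges=[("a", "b"), ("c", "b")])
        assert d_separated(g, {"a"}, {"c"}, set())
        assert not d_separated(g, {"a"}, {"c"}, {"b"})

    def test_descendant_of_collider_opens_path(self):
        g = DependencyGraph(nodes=["a", "b", "c", "d"],
                            edges=[("a", "b"), ("c", "b"), ("b", "d")])
        assert not d_separated(g, {"a"}, {"c"}, {"d"})

    def test_blanket_separates_in_six_node_dag(self, six_node_dag):
        assert d_separated(six_node_dag, {"3"}, {"6"}, {"1", "2", "4", "5"})

    def test_symmetry_and_networkx_agreement(self, rng):
        from neuroblankets.fixtures import random_dag

        for seed in range(40):
            g = random_dag(8, 0.3, seed=seed)
            nodes = sorted(g.node_ids)
            picks = rng.permutation(nodes)
            A, B, C = {picks[0]}, {picks[1]}, set(picks[2:2 + int(rng.integers(4))])
            ours = d_separated(g, A, B, C)
            assert ours == d_separated(g, B, A, C)
            assert ours == nx.is_d_separator(g.to_networkx(), A, B, C)

    def test_cyclic_graph_directs_to_unroll(self):
        g = DependencyGraph(nodes=["a", "b"], edges=[("a", "b"), ("b", "a")])
        with pytest.raises(CyclicGraphError, match="unroll_one_step"):
            d_separated(g, {"a"}, {"b"}, set())


class TestUnrollOneStep:
    def test_single_node_gains_only_self_dependence(self):
        g = DependencyGraph(nodes=["x"])
        u = unroll_one_step(g)
        assert u.edges == {("x@t", "x@t+1")}

    def test_four_role_template_excludes_external_from_internal(self):
        g = DependencyGraph(nodes=[
            StateNode("mu", role="internal"), StateNode("s", role="sensory"),
            StateNode("a", role="active"), StateNode("eta", role="external")])
        for u, v in [("s", "mu"), ("a", "mu"), ("mu", "a"), ("s", "a"),
                     ("eta", "s"), ("a", "s"), ("s", "eta"), ("a", "eta")]:
            g.add_edge(u, v)
        un = unroll_one_step(g)
        assert un.parents("mu@t+1") == {"mu@t", "s@t", "a@t"}
        assert "eta@t" not in un.parents("mu@t+1")

    def test_two_node_cycle_becomes_acyclic(self):
        g = DependencyGraph(nodes=["a", "b"], edges=[("a", "b"), ("b", "a")])
        u = unroll_one_step(g)
        assert len(u) == 4 and u.is_acyclic()

    def test_valid_partition_implies_one_step_d_separation(self, linear_system):
        g = linear_system.declared_edges
        p = linear_system.partition()
        un = unroll_one_step(g)
        A = {f"{i}@t+1" for i in p.internal}
        B = {f"{i}@t" for i in p.external}
        C = {f"{i}@t" for i in p.internal | p.blanket}
        assert d_separated(un, A, B, C)


class TestClassifyBlanket:
    def test_two_column_macro_graph_roles(self):
        # macro graph over populations of a 2-column microcircuit chain
        from neuroblankets.models import cmc_chain
        from neuroblankets.multiscale import CoarseGraining, coarse_grain

        model = cmc_chain(2)
        grouping = CoarseGraining(
            {n: n.rsplit(".", 1)[0] for n in model.declared_edges.node_ids})
        macro = coarse_grain(model.declared_edges, grouping)
        internal = {"c1.SS", "c1.II"}
        external = {"c2.SS", "c2.II"}
        blanket = macro.node_ids - internal - external
        sensory, active, ambiguous, violations = classify_blanket(
            macro, internal, external, blanket)
        assert violations == []
        assert "c1.SP" in active and "c2.DP" in sensory

    def test_two_neuron_pair_voltages(self):
        from neuroblankets.models import neural_mass_pair

        g = neural_mass_pair().declared_edges
        sensory, active, ambiguous, violations = classify_blanket(
            g, {"u1.g"}, {"u2.g"}, {"u1.v", "u2.v"})
        assert sensory == {"u2.v"} and active == {"u1.v"}
        assert ambiguous == set() and violations == []

    def test_orphan_blanket_node_is_ambiguous(self):
        g = DependencyGraph(nodes=[
            StateNode("mu"), StateNode("eta"), StateNode("b")])
        sensory, active, ambiguous, violations = classify_blanket(
            g, {"mu"}, {"eta"}, {"b"})
        assert ambiguous == {"b"} and not sensory and not active and not violations

    def test_node_with_parents_on_both_sides_is_violation(self):
        g = DependencyGraph(
            nodes=["mu", "eta", "b"], edges=[("mu", "b"), ("eta", "b")])
        *_, violations = classify_blanket(g, {"mu"}, {"eta"}, {"b"})
        rules = {v.rule for v in violations}
        assert rules == {ViolationRule.MU_TO_S, ViolationRule.ETA_TO_A}

    def test_swapping_labels_swaps_sensory_and_active(self):
        from neuroblankets.fixtures import random_blanket_system

        for seed in range(10):
            g = random_blanket_system(seed=seed).declared_edges
            p = partition_from_roles(g)
            s1, a1, amb1, v1 = classify_blanket(
                g, p.internal, p.external, p.blanket)
            s2, a2, amb2, v2 = classify_blanket(
                g, p.external, p.internal, p.blanket)
            assert (s1, a1) == (a2, s2) and amb1 == amb2 and v1 == [] and v2 == []

    def test_non_covering_sets_rejected(self, six_node_dag):
        with pytest.raises(PartitionError, match="complement"):
            classify_blanket(six_node_dag, {"1"}, {"2"}, {"3"})


class TestValidatePartition:
    def _four_role_graph(self):
        g = DependencyGraph(nodes=[
            StateNode("mu", role="internal"), StateNode("s", role="sensory"),
            StateNode("a", role="active"), StateNode("eta", role="external")])
        g.add_edge("s", "mu")
        g.add_edge("mu", "a")
        g.add_edge("a", "eta")
        g.add_edge("eta", "s")
        return g

    def test_template_graph_is_valid(self):
        g = self._four_role_graph()
        assert validate_partition(g, partition_from_roles(g)) == []

    def test_gained_external_to_active_edge_is_one_violation(self):
        g = self._four_role_graph()
        g.add_edge("eta", "a")
        violations = validate_partition(g, partition_from_roles(g))
        assert len(violations) == 1
        assert violations[0].rule == ViolationRule.ETA_TO_A
        assert violations[0].edge == ("eta", "a")

    def test_losing_an_edge_never_creates_violations(self):
        g = self._four_role_graph()
        g.remove_edge("s", "mu")
        assert validate_partition(g, partition_from_roles(g)) == []

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_forbidden_edges_give_exactly_k_violations(self, k):
        g = self._four_role_graph()
        forbidden = [("mu", "s"), ("mu", "eta"), ("eta", "a"), ("eta", "mu")]
        for u, v in forbidden[:k]:
            g.add_edge(u, v)
        assert len(validate_partition(g, partition_from_roles(g))) == k

    def test_partition_graph_mismatch_rejected(self, six_node_dag):
        p = BlanketPartition(internal={"1"}, sensory={"2"}, active={"3"},
                             external={"4"})
        with pytest.raises(PartitionError, match="cover"):
            validate_partition(six_node_dag, p)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(PartitionError, match="disjoint"):
            BlanketPartition(internal={"x"}, sensory={"x"}, active=set(),
                             external=set())


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 9),
       p=st.floats(0.0, 1.0))
def test_pearl_blanket_symmetric_under_blanket_membership(seed, n, p):
    """v is in the blanket of w iff w is in the blanket of v.

    Holds because parents/children relations flip while the co-parent
    relation is symmetric.
    """
    from neuroblankets.fixtures import random_dag

    g = random_dag(n, p, seed=seed)
    nodes = sorted(g.node_ids)
    for v in nodes:
        for w in pearl_blanket(g, {v}):
            assert v in pearl_blanket(g, {w})
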