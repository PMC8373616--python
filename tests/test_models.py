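"""Model zoo: flow forms, declared sparsity and documented blanket roles."""

import numpy as np
import pytest
from scipy import optimize

from neuroblankets import fixtures, models
from neuroblankets.graph import classify_blanket, validate_partition
from neuroblankets.models import (
    FHNParams,
    HHParams,
    MLParams,
    ModelParameterError,
    cmc_chain,
    fitzhugh_nagumo,
    hodgkin_huxley,
    hodgkin_huxley_classic,
    morris_lecar,
    neural_mass_network,
    neural_mass_pair,
    random_probe_points,
    structural_graph,
)
from neuroblankets.multiscale import CoarseGraining, coarse_grain


class TestHodgkinHuxley:
    def test_gates_depend_only_on_voltage(self):
        g = hodgkin_huxley().declared_edges
        for gate in ("mNa", "nK"):
            assert g.parents(gate) == {"v"}
        # default leak rates are constants, so the leak gate sees nothing
        assert g.parents("mL") == set()

    def test_voltage_dependent_leak_rates_declare_the_edge(self):
        p = HHParams()
        p.alpha["l"] = lambda v: 0.1 + 0.001 * v
        g = hodgkin_huxley(p).declared_edges
        assert g.parents("mL") == {"v"}

    def test_voltage_parents_are_current_and_gates(self):
        g = hodgkin_huxley().declared_edges
        assert g.parents("v") == {"I", "mNa", "nK", "mL"}

    def test_zero_conductance_gives_pure_capacitive_charging(self):
        m = hodgkin_huxley(HHParams(g_K=0, g_Na=0, g_l=0, C=2.0))
        dv = m.flow_at(np.array([-65.0, 0.1, 0.3, 0.5]), np.array([3.0]))[0]
        assert dv == pytest.approx(3.0 / 2.0)

    def test_no_driving_force_no_current(self):
        p = HHParams(v_K=-20.0, v_Na=-20.0, v_l=-20.0)
        m = hodgkin_huxley(p)
        dv = m.flow_at(np.array([-20.0, 0.4, 0.4, 0.4]), np.array([0.0]))[0]
        assert dv == pytest.approx(0.0, abs=1e-12)

    def test_negative_capacitance_rejected(self):
        with pytest.raises(ModelParameterError, match="capacitance"):
            hodgkin_huxley(HHParams(C=-1.0))

    def test_classic_variant_has_ungated_leak(self):
        g = hodgkin_huxley_classic().declared_edges
        assert g.parents("v") == {"I", "m", "h", "n"}

    def test_gates_stay_in_unit_interval_along_trajectory(self):
        from neuroblankets.simulate import integrate

        m = hodgkin_huxley()
        traj = integrate(m, np.array([-65.0, 0.05, 0.3, 0.5]), 30.0, 0.005,
                         input_fn=lambda t: np.array([10.0]))
        gates = traj.states[:, 1:]
        assert gates.min() >= 0.0 and gates.max() <= 1.0


class TestFitzHughNagumo:
    def test_origin_is_fixed_point_without_drive_or_offsets(self):
        m = fitzhugh_nagumo(FHNParams(tau=12.5, alpha=0.0, beta=0.0))
        assert m.flow_at(np.zeros(2)) == pytest.approx(np.zeros(2))

    def test_fixed_point_matches_nullcline_root(self):
        """Root-finding oracle on the nullcline intersection.

        With drive s the rest point solves v - v^3/3 - (v+alpha)/beta + s = 0
        and w = (v+alpha)/beta; the model flow must vanish there.
        """
        s, alpha, beta, tau = 0.5, 0.7, 0.8, 12.5
        v_star = optimize.brentq(
            lambda v: v - v ** 3 / 3.0 - (v + alpha) / beta + s, -3, 3)
        w_star = (v_star + alpha) / beta
        m = fitzhugh_nagumo(FHNParams(tau=tau, alpha=alpha, beta=beta))
        dx = m.flow_at(np.array([v_star, w_star]), np.array([s]))
        assert dx == pytest.approx(np.zeros(2), abs=1e-12)

    def test_recovery_is_independent_of_drive(self):
        g = fitzhugh_nagumo().declared_edges
        assert g.parents("w") == {"v"}
        assert not g.has_edge("I", "w")

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ModelParameterError, match="tau"):
            fitzhugh_nagumo(FHNParams(tau=0.0))


class TestMorrisLecar:
    def test_gating_steady_state_is_half_at_midpoint(self):
        p = MLParams()
        assert p.w_inf(p.V3) == pytest.approx(0.5)

    def test_zero_conductances_give_capacitive_charging(self):
        m = morris_lecar(MLParams(g_L=0, g_Ca=0, g_K=0))
        dv = m.flow_at(np.array([-40.0, 0.2]), np.array([30.0]))[0]
        assert dv == pytest.approx(30.0 / 20.0)

    def test_resting_state_matches_nullcline_root(self):
        """2-D root-finding oracle: with w pinned to its voltage nullcline,
        the rest potential solves the current-balance equation."""
        p = MLParams()
        I = 0.0

        def balance(v):
            m_inf = 0.5 * (1 + np.tanh((v - p.V1) / p.V2))
            w_inf = 0.5 * (1 + np.tanh((v - p.V3) / p.V4))
            return (I - p.g_L * (v - p.v_L) - p.g_Ca * m_inf * (v - p.v_Ca)
                    - p.g_K * w_inf * (v - p.v_K))

        v_star = optimize.brentq(balance, -80, 20)
        w_star = 0.5 * (1 + np.tanh((v_star - p.V3) / p.V4))
        m = morris_lecar(p)
        dx = m.flow_at(np.array([v_star, w_star]), np.array([I]))
        assert dx == pytest.approx(np.zeros(2), abs=1e-10)

    def test_gate_depends_only_on_voltage(self):
        g = morris_lecar().declared_edges
        assert g.parents("w") == {"v"}
        assert g.parents("v") == {"I", "w"}


class TestNeuralMass:
    def test_pair_blanket_roles_validate(self):
        m = neural_mass_pair()
        assert validate_partition(m.declared_edges, m.partition()) == []

    def test_decoupled_pair_still_validates(self):
        # losing the sensory->internal dependency preserves the blanket
        m = neural_mass_pair(A_mu=0.0)
        assert not m.declared_edges.has_edge("u2.v", "u1.g")
        assert validate_partition(m.declared_edges, m.partition()) == []

    def test_many_presynaptic_units_one_postsynaptic(self):
        n = 6  # units 2..6 presynaptic onto unit 1
        W = np.zeros((n, n))
        W[0, 1:] = 0.4
        m = neural_mass_network(W)
        g = m.declared_edges
        assert g.parents("u1.g") == {f"u{i}.v" for i in range(2, n + 1)} | {"u1.g"} - {"u1.g"}
        assert g.parents("u1.v") == {"u1.g"}

    def test_voltage_only_sees_own_conductance(self):
        m = neural_mass_pair()
        for unit in ("u1", "u2"):
            assert m.declared_edges.parents(f"{unit}.v") == {f"{unit}.g"}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ModelParameterError, match="square"):
            neural_mass_network(np.zeros((2, 3)))


class TestCMCChain:
    def test_single_column_has_no_extrinsic_edges(self):
        m = cmc_chain(1)
        edges = m.declared_edges.edges
        assert all(u.split(".")[0] == v.split(".")[0] for u, v in edges)

    def test_forward_edges_originate_at_superficial_pyramidal(self):
        m = cmc_chain(3)
        cross = [(u, v) for u, v in m.declared_edges.edges
                 if u.split(".")[0] != v.split(".")[0]]
        for u, v in cross:
            col_u = int(u.split(".")[0][1:])
            col_v = int(v.split(".")[0][1:])
            if col_v == col_u + 1:  # forward
                assert u.endswith("SP.v")
                assert v.split(".")[1] in ("SS", "II")
            else:  # backward
                assert col_v == col_u - 1
                assert u.endswith("DP.v")
                assert v.split(".")[1] in ("SP", "II")

    def test_no_stellate_or_interneuron_projections_leave_a_column(self):
        m = cmc_chain(4)
        for u, v in m.declared_edges.edges:
            if u.split(".")[0] != v.split(".")[0]:
                assert u.split(".")[1] not in ("SS", "II")

    @pytest.mark.parametrize("L", [1, 2, 4])
    def test_documented_roles_validate(self, L):
        m = cmc_chain(L)
        assert validate_partition(m.declared_edges, m.partition()) == []

    def test_two_column_role_recovery_on_population_graph(self):
        m = cmc_chain(2)
        grouping = CoarseGraining(
            {n: n.rsplit(".", 1)[0] for n in m.declared_edges.node_ids})
        macro = coarse_grain(m.declared_edges, grouping)
        sensory, active, ambiguous, violations = classify_blanket(
            macro, {"c1.SS", "c1.II"}, {"c2.SS", "c2.II"},
            macro.node_ids - {"c1.SS", "c1.II", "c2.SS", "c2.II"})
        assert violations == [] and ambiguous == set()
        assert "c1.SP" in active and "c2.DP" in sensory

    def test_reversed_labels_swap_pyramidal_roles(self):
        m = cmc_chain(2)
        grouping = CoarseGraining(
            {n: n.rsplit(".", 1)[0] for n in m.declared_edges.node_ids})
        macro = coarse_grain(m.declared_edges, grouping)
        blanket = macro.node_ids - {"c1.SS", "c1.II", "c2.SS", "c2.II"}
        s1, a1, *_ = classify_blanket(
            macro, {"c1.SS", "c1.II"}, {"c2.SS", "c2.II"}, blanket)
        s2, a2, *_ = classify_blanket(
            macro, {"c2.SS", "c2.II"}, {"c1.SS", "c1.II"}, blanket)
        assert s2 == a1 and a2 == s1

    def test_custom_intrinsic_weights_keep_roles_valid(self):
        dense = {(s, d): 0.3 for s in models.CMC_POPULATIONS
                 for d in models.CMC_POPULATIONS if s != d}
        m = cmc_chain(2, intrinsic=dense)
        assert validate_partition(m.declared_edges, m.partition()) == []

    def test_forward_to_dp_option(self):
        m = cmc_chain(2, forward_to_dp=True)
        assert m.declared_edges.has_edge("c1.SP.v", "c2.DP.g")
        assert validate_partition(m.declared_edges, m.partition()) == []

    def test_zero_columns_rejected(self):
        with pytest.raises(ModelParameterError, match="column"):
            cmc_chain(0)


class TestStructuralGraph:
    def test_probed_graph_is_subgraph_of_declared(self, zoo_model, rng):
        probes = random_probe_points(zoo_model, 20, rng)
        probed = structural_graph(zoo_model, probes)
        assert probed.edges <= zoo_model.declared_edges.edges

    def test_hh_probing_recovers_all_declared_edges(self, rng):
        m = hodgkin_huxley()
        probed = structural_graph(m, random_probe_points(m, 5, rng))
        assert probed.edges == m.declared_edges.edges

    def test_zero_flow_gives_empty_graph(self):
        m = fixtures.spring_chain(3, k=0.0)
        # k=0: no spring coupling; only momentum->position edges survive
        probed = structural_graph(m, [np.zeros(6)])
        assert probed.edges == {(f"p{i}", f"q{i}") for i in (1, 2, 3)}

    def test_fhn_self_edge_detected_at_origin(self):
        # dv/dt = v - v^3/3 ... has derivative 1 at v=0; the probe sees the
        # drive and recovery edges even from the single degenerate point
        m = fitzhugh_nagumo()
        probed = structural_graph(m, [(np.zeros(2), np.zeros(1))])
        assert probed.has_edge("w", "v") and probed.has_edge("I", "v")

    def test_nonfinite_flow_reported(self):
        m = fitzhugh_nagumo()
        with pytest.raises(ModelParameterError, match="non-finite"):
            structural_graph(m, [np.array([np.inf, 0.0])])


def test_every_zoo_model_roles_validate(zoo_model):
    """The documented role assignment of every shipped model satisfies the
    blanket flow constraints with zero violations."""
    assert validate_partition(zoo_model.declared_edges, zoo_model.partition()) == []
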