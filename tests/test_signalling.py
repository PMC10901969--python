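"""Unit and property tests of the logic-based signalling network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasotone.errors import DomainError, SingularEquilibriumError
from vasotone.signalling import (
    CONTROL,
    EDGE_LABELS,
    Intervention,
    LogisticEdge,
    NetworkState,
    chemical_output,
    ec50,
    integrate_transient,
    logic_combine,
    logistic_eval,
    network_rhs,
    steady_state,
)

edges_strategy = st.builds(
    LogisticEdge,
    B0=st.floats(0.0, 0.99),
    K=st.floats(1e-3, 1e4),
    n=st.floats(0.05, 400.0),
)


class TestLogisticEdge:
    def test_basal_value_of_pressure_calcium_edge(self, net):
        # the pressure->Ca2+ curve starts at its fitted basal level
        assert logistic_eval(net.chi(0), 0.0) == pytest.approx(0.131, abs=1e-15)

    def test_all_edges_pinned_at_saturation(self, net):
        for lab in EDGE_LABELS:
            e = net.edges[lab]
            assert abs(e(0.0) - e.B0) <= 1e-12
            assert abs(e(1.0) - 1.0) <= 1e-12

    def test_hand_evaluated_point(self):
        # B0=0, K=0.5, n=1 at x=0.5: (1+0.5)*0.5/(0.5+0.5) = 0.75
        e = LogisticEdge(B0=0.0, K=0.5, n=1.0)
        assert e(0.5) == pytest.approx(0.75, rel=1e-14)

    def test_vector_and_scalar_paths_agree(self, net):
        x = np.linspace(0.0, 1.0, 17)
        for lab in EDGE_LABELS:
            e = net.edges[lab]
            vec = logistic_eval(e, x)
            scal = np.array([logistic_eval(e, float(v)) for v in x])
            np.testing.assert_allclose(vec, scal, rtol=0, atol=1e-14)

    @pytest.mark.parametrize("bad", [-0.1, 1.0001])
    def test_out_of_range_input_rejected(self, net, bad):
        with pytest.raises(DomainError):
            logistic_eval(net.chi(0), bad)

    @pytest.mark.parametrize("kwargs", [dict(B0=1.0, K=1, n=1),
                                        dict(B0=-0.1, K=1, n=1),
                                        dict(B0=0.1, K=0, n=1),
                                        dict(B0=0.1, K=1, n=-2)])
    def test_invalid_coefficients_rejected(self, kwargs):
        with pytest.raises(DomainError):
            LogisticEdge(**kwargs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(edge=edges_strategy)
    def test_contract_and_monotonicity(self, edge):
        assert abs(edge(0.0) - edge.B0) <= 1e-12
        assert abs(edge(1.0) - 1.0) <= 1e-12
        grid = np.linspace(0.0, 1.0, 1001)
        vals = logistic_eval(edge, grid)
        assert np.all(vals >= edge.B0 - 1e-12)
        assert np.all(vals <= 1.0 + 1e-12)
        assert np.all(np.diff(vals) >= -1e-12)


class TestLogicOperators:
    @pytest.mark.parametrize("kind,a,b,expected", [
        ("OR", 1.0, 0.0, 1.0),
        ("AND", 1.0, 1.0, 1.0),
        ("ANDNOT", 1.0, 1.0, 0.0),
        ("OR", 0.3, 0.4, 0.58),
        ("AND", 0.5, 0.5, 0.25),
        ("ANDNOT", 0.5, 0.2, 0.4),
    ])
    def test_known_values(self, kind, a, b, expected):
        assert logic_combine(kind, a, b) == pytest.approx(expected, rel=1e-14)

    def test_domain_and_operator_errors(self):
        with pytest.raises(DomainError):
            logic_combine("OR", 1.2, 0.0)
        with pytest.raises(DomainError):
            logic_combine("XOR", 0.5, 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(0, 1), b=st.floats(0, 1),
           kind=st.sampled_from(["AND", "OR", "ANDNOT"]))
    def test_results_stay_in_unit_interval(self, a, b, kind):
        assert 0.0 <= logic_combine(kind, a, b) <= 1.0


def _independent_rhs(xi, p_bar, net):
    """Independent transcription of the seven ODE right-hand sides."""
    def chi(e, x):
        a = e.K ** e.n
        t = x ** e.n
        if t == 0.0 and a == 0.0:
            return 1.0
        return e.B0 + (1 - e.B0) * (1 + a) * t / (t + a)

    c = [net.chi(i) for i in range(9)]
    d = np.empty(7)
    d[0] = chi(c[0], p_bar) - xi[0]
    d[1] = chi(c[1], p_bar) - xi[1]
    d[2] = chi(c[2], p_bar) - xi[2]
    d[3] = chi(c[3], xi[1]) - xi[3]
    d[4] = chi(c[4], xi[1]) - xi[4]
    d[5] = chi(c[5], xi[0]) * (1 - xi[5]) - (1 - chi(c[6], xi[3])) * xi[5]
    a7 = 1 - chi(c[7], xi[4])
    a8 = 1 - chi(c[8], xi[2])
    d[6] = a7 + a8 - a7 * a8 - xi[6]
    return d / np.asarray(net.tau)


class TestNetworkDynamics:
    def test_rhs_vanishes_at_steady_state(self, net):
        for p_bar in (0.0, 0.15, 0.5, 0.9):
            for iv in (CONTROL, Intervention.preset("ca_free"),
                       Intervention.preset("gf_3")):
                st_ = steady_state(p_bar, net, iv)
                assert np.max(np.abs(network_rhs(st_, p_bar, net, iv))) < 1e-10

    def test_rhs_matches_independent_transcription(self, net, rng):
        # avoid exact 0/1 inputs where the direct power-form over/underflows
        for _ in range(50):
            xi = rng.uniform(0.05, 0.95, 7)
            p_bar = float(rng.uniform(0.05, 0.95))
            got = network_rhs(NetworkState(xi), p_bar, net)
            want = _independent_rhs(xi, p_bar, net)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_clamped_calcium_keeps_plc20_off(self, net):
        # the MLCK drive has zero basal activity, so with Ca2+ clamped to 0
        # an unphosphorylated LC20 pool stays unphosphorylated
        iv = Intervention(clamps={0: 0.0})
        xi = np.zeros(7)
        d = network_rhs(NetworkState(xi), 0.0, net, iv)
        assert d[0] == 0.0          # clamped node frozen
        assert d[5] == pytest.approx(0.0, abs=1e-15)

    def test_pressure_out_of_range_rejected(self, net):
        with pytest.raises(DomainError):
            network_rhs(NetworkState(np.full(7, 0.5)), 1.5, net)


class TestSteadyState:
    def test_zero_pressure_basal_calcium(self, net):
        st_ = steady_state(0.0, net)
        assert st_[0] == pytest.approx(0.131, abs=1e-15)

    def test_full_pressure_saturates_sensing_nodes(self, net):
        st_ = steady_state(1.0, net)
        for i in (0, 1, 2):
            assert st_[i] == pytest.approx(1.0, abs=1e-14)

    def test_calcium_clamp_zero_gives_zero_plc20(self, net):
        st_ = steady_state(0.0, net, Intervention(clamps={0: 0.0}))
        assert st_[5] == 0.0

    def test_singular_equilibrium_flagged(self, net):
        # kinase fully off (Ca2+ at 0, chi5 basal 0) while phosphatase fully
        # inhibited (pMLCP clamped to 1, chi6(1)=1) leaves pLC20 at 0/0
        iv = Intervention(clamps={0: 0.0, 3: 1.0})
        with pytest.raises(SingularEquilibriumError):
            steady_state(0.5, net, iv)

    def test_plc20_monotone_in_calcium(self, net):
        xi5 = [steady_state(0.5, net, Intervention(clamps={0: c}))[5]
               for c in np.linspace(0.0, 1.0, 41)]
        assert np.all(np.diff(xi5) >= -1e-12)

    def test_ca_free_plc20_bounded_by_low_pressure_control(self, net):
        # calibration constraint of the published fit: under Ca2+ removal
        # pLC20 never exceeds the 10 mmHg control value up to 120 mmHg
        ref = steady_state(net.normalize_pressure(10.0), net)[5]
        ca_free = Intervention.preset("ca_free")
        for P in np.arange(10.0, 121.0, 5.0):
            assert steady_state(net.normalize_pressure(P), net, ca_free)[5] <= ref


class TestTransient:
    def test_constant_pressure_relaxes_to_steady_state(self, net):
        x0 = NetworkState(np.full(7, 0.5))
        sol = integrate_transient(x0, 0.4, net, t_span=(0.0, 200.0))
        target = steady_state(0.4, net).xi
        np.testing.assert_allclose(sol.y[:, -1], target, rtol=0, atol=1e-6)

    def test_steady_initial_state_stays_constant(self, net):
        x0 = steady_state(0.6, net)
        sol = integrate_transient(x0, 0.6, net, t_span=(0.0, 50.0),
                                  t_eval=np.linspace(0, 50, 11))
        np.testing.assert_allclose(
            sol.y, np.tile(x0.xi[:, None], sol.y.shape[1]), rtol=0, atol=1e-7)

    def test_single_node_matches_exponential_relaxation(self, net):
        # with frozen forcing, the Ca2+ node is a scalar linear ODE:
        # xi0(t) = chi0(p) + (xi0(0) - chi0(p)) exp(-t/tau0)
        p_bar = 0.3
        x0 = steady_state(p_bar, net).xi.copy()
        x0[0] = 0.9
        t_eval = np.array([0.0, 0.5, 1.0, 2.0])
        sol = integrate_transient(NetworkState(x0), p_bar, net,
                                  t_span=(0.0, 2.0), t_eval=t_eval)
        chi0 = net.chi(0)(p_bar)
        expected = chi0 + (0.9 - chi0) * np.exp(-t_eval / net.tau[0])
        np.testing.assert_allclose(sol.y[0], expected, rtol=0, atol=1e-7)

    def test_trajectory_stays_in_unit_cube(self, net, rng):
        for _ in range(5):
            x0 = NetworkState(rng.uniform(0, 1, 7))
            sol = integrate_transient(
                x0, float(rng.uniform(0, 1)), net, t_span=(0.0, 30.0),
                t_eval=np.linspace(0.0, 30.0, 61))
            assert sol.y.min() >= -1e-9
            assert sol.y.max() <= 1.0 + 1e-9


class TestChemicalOutput:
    def test_full_activation_gives_max_fraction(self, net):
        st_ = NetworkState(np.array([1, 1, 1, 1, 1, 1.0, 0.25]))
        out = chemical_output(st_, net)
        assert out.n_XB == pytest.approx(0.55, abs=0)
        assert out.xi7 == pytest.approx(0.75, abs=1e-15)

    def test_no_phosphorylation_no_crossbridges(self, net):
        st_ = NetworkState(np.zeros(7))
        assert chemical_output(st_, net).n_XB == 0.0


class TestEC50:
    def test_symmetric_curve_analytic_value(self):
        # chi(x) = 2x/(x+1) reaches half of its range (0.5) at x = 1/3
        e = LogisticEdge(B0=0.0, K=1.0, n=1.0)
        assert ec50(e) == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_pressure_calcium_edge_satisfies_fit_constraint(self, net):
        assert ec50(net.chi(0)) >= 0.1

    def test_defined_for_high_basal_edges(self):
        e = LogisticEdge(B0=0.95, K=0.5, n=2.0)
        x = ec50(e)
        assert 0.0 < x < 1.0
        assert e(x) == pytest.approx(e.B0 + 0.5 * (1 - e.B0), abs=1e-10)


class TestIntervention:
    def test_presets_match_pharmacology(self):
        assert Intervention.preset("ca_free").clamps == {0: 0.1}
        assert Intervention.preset("h1152_0.3").clamps == {1: 0.12}
        assert Intervention.preset("h1152_0.5").clamps == {1: 0.07}
        assert Intervention.preset("gf_3").clamps == {2: 0.1}

    def test_clamp_string_parsing(self):
        iv = Intervention.from_clamp_strings(["xi1=0.12", "rock=0.07"])
        assert iv.clamps == {1: 0.07}

    @pytest.mark.parametrize("bad", [{0: 1.5}, {9: 0.5}])
    def test_invalid_clamps_rejected(self, bad):
        with pytest.raises(DomainError):
            Intervention(clamps=bad)
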