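"""Tests of the penalty-constrained two-tier calibration machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from vasotone.calibration import (
    FitConfig,
    ObservableTable,
    chemical_constraints,
    data_cost,
    default_free_param,
    fit,
    mechanical_constraints,
    penalty,
    preprocess_gf_plc20,
    simulate_observables,
)
from vasotone.errors import DomainError
from vasotone.synthetic_data import SynthSpec, generate_chemical_observables


def _table(rows):
    return ObservableTable(pd.DataFrame(rows))


def _row(cond="control", obs="pLC20", P=10.0, mean=0.5, sd=0.0,
         norm="absolute"):
    return {"condition": cond, "observable": obs, "pressure_mmHg": P,
            "mean": mean, "sd": sd, "normalization": norm}


class TestObservableTable:
    def test_schema_enforced(self):
        with pytest.raises(DomainError):
            ObservableTable(pd.DataFrame({"condition": ["control"]}))

    def test_negative_sd_rejected(self):
        with pytest.raises(DomainError):
            _table([_row(sd=-0.1)])

    def test_inconsistent_normalization_rejected(self):
        with pytest.raises(DomainError):
            _table([_row(norm="absolute"),
                    _row(P=40.0, norm="rel_control_10mmHg")])

    def test_csv_round_trip(self, tmp_path):
        t = _table([_row(), _row(P=40.0, mean=0.73)])
        path = tmp_path / "obs.csv"
        t.to_csv(path)
        back = ObservableTable.from_csv(path)
        pd.testing.assert_frame_equal(t.frame, back.frame, check_dtype=False)


class TestDataCost:
    def test_perfect_fit_costs_nothing(self, bundle):
        table = _table([_row(mean=0.0)])
        sim = np.array([table.frame["mean"][0]])
        assert data_cost(sim, table) == 0.0

    def test_single_row_residual(self):
        table = _table([_row(mean=0.2)])
        assert data_cost(np.array([0.5]), table) == pytest.approx(0.3, rel=1e-12)

    def test_euclidean_combination(self):
        table = _table([_row(mean=0.0), _row(P=40.0, mean=0.0)])
        assert data_cost(np.array([3.0, 4.0]), table) == pytest.approx(5.0)

    def test_simulated_values_match_steady_state(self, bundle, net):
        from vasotone.signalling import steady_state
        table = _table([_row(obs="pLC20", P=80.0, norm="absolute"),
                        _row(obs="pMLCP", P=80.0, norm="rel_control_10mmHg")])
        sim = simulate_observables(table, bundle)
        s80 = steady_state(net.normalize_pressure(80.0), net)
        s10 = steady_state(net.normalize_pressure(10.0), net)
        assert sim[0] == pytest.approx(s80[5], rel=1e-14)
        assert sim[1] == pytest.approx(s80[3] / s10[3], rel=1e-14)


class TestPenalty:
    def test_satisfied_constraint_costs_nothing(self):
        assert penalty(0.0, 1.0e3) == 0.0

    def test_paper_scale_penalty(self):
        assert penalty(0.02, 1.0e3) == pytest.approx(20.0)

    def test_linear_in_violation(self):
        assert penalty(0.4, 1.0e3) == pytest.approx(2 * penalty(0.2, 1.0e3))

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            penalty(-0.1, 1.0e3)


class TestChemicalConstraints:
    def test_published_fit_is_feasible(self, net):
        deltas = chemical_constraints(net, _warn=False)
        assert all(d == 0.0 for d in deltas.values())

    def test_fast_saturating_calcium_curve_violates_ec50(self, net):
        # K -> tiny makes the pressure-Ca2+ curve saturate immediately,
        # pushing its EC50 towards 0 and the violation towards 0.1
        bad = net.with_edge("chi0", K=1e-6, n=2.0)
        deltas = chemical_constraints(bad, _warn=False)
        assert deltas["ec50"] == pytest.approx(0.1, abs=1e-3)

    def test_phosphatase_shutdown_violates_ca_free_bound(self, net):
        # basal kinase activity plus a phosphatase that is inhibited at any
        # pMLCP level drives Ca2+-free pLC20 above the 10 mmHg control value
        bad = (net.with_edge("chi5", B0=0.3, K=0.423, n=5.0)
                  .with_edge("chi6", K=1e-3, n=5.0))
        deltas = chemical_constraints(bad, _warn=False)
        assert deltas["ca_free_plc20"] > 0.0

    def test_envelope_constraint_when_supplied(self, net):
        band = pd.DataFrame({"pressure_mmHg": [40.0, 80.0],
                             "low": [0.0, 0.0], "high": [1.0, 1.0]})
        deltas = chemical_constraints(net, ca_envelope=band, _warn=False)
        assert deltas["ca_envelope"] == 0.0
        tight = pd.DataFrame({"pressure_mmHg": [80.0],
                              "low": [0.9], "high": [1.0]})
        deltas = chemical_constraints(net, ca_envelope=tight, _warn=False)
        assert deltas["ca_envelope"] > 0.0

    def test_missing_envelope_warns(self, net):
        with pytest.warns(UserWarning, match="envelope"):
            chemical_constraints(net)


class TestMechanicalConstraints:
    def test_published_fit_is_feasible(self, bundle):
        deltas = mechanical_constraints(bundle)
        assert all(d == 0.0 for d in deltas.values()), deltas

    def test_passive_vessel_has_no_plateau(self, bundle):
        from vasotone.signalling import Intervention
        from vasotone.solver import pressure_sweep
        sweep = pressure_sweep(np.arange(10.0, 121.0, 5.0),
                               Intervention(clamps={5: 0.0}, name="passive"),
                               bundle)
        deltas = mechanical_constraints(bundle, control_sweep=sweep)
        assert deltas["plateau"] > 0.0

    def test_wall_thickness_box_violation(self, bundle):
        thick = bundle.with_geometry(h_w=0.5)
        deltas = mechanical_constraints(thick,
                                        control_sweep=[])  # boxes only
        assert deltas["box_h_w"] == pytest.approx(0.10, abs=1e-12)

    def test_scale_bounds_relative_to_reference(self, bundle):
        from dataclasses import replace
        big = replace(bundle, contractile=replace(bundle.contractile,
                                                  u_PS=bundle.contractile.u_PS * 20))
        deltas = mechanical_constraints(
            big, control_sweep=[],
            reference_values={"u_PS": bundle.contractile.u_PS})
        assert deltas["box_u_PS"] == pytest.approx(10.0, abs=1e-9)


class TestGFPreprocessing:
    def test_identity_factor(self):
        v, s = preprocess_gf_plc20([0.5, 0.6], [0.1, 0.2], factor=1.0)
        np.testing.assert_allclose(v, [0.5, 0.6])
        np.testing.assert_allclose(s, [0.1, 0.2])

    def test_default_rescale(self):
        v, s = preprocess_gf_plc20([0.5], [0.1])
        assert v[0] == pytest.approx(0.55)
        assert s[0] == pytest.approx(0.11)


class TestFit:
    def test_cost_decomposition_reconstructs(self, bundle):
        spec = SynthSpec(bundle=bundle, seed=7,
                         pressures=np.array([10.0, 60.0, 110.0]),
                         conditions=("control",),
                         observables=("pHSP27",), noise_frac=0.0)
        table = generate_chemical_observables(spec)
        cfg = FitConfig(free=[default_free_param("chemical.chi2.K")],
                        maxiter=5, seeds=(0,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit("chemical", table, cfg, base=bundle)
        assert res.L_tot == pytest.approx(res.L_data + res.L_con_sum,
                                          abs=1e-12)

    def test_infeasible_start_escapes_penalty_region(self, bundle):
        # start with an EC50-violating pressure-Ca2+ curve; the penalty
        # (kappa = 1e3) dominates and the optimizer restores feasibility
        spec = SynthSpec(bundle=bundle, seed=7,
                         pressures=np.arange(10.0, 121.0, 20.0),
                         conditions=("control",),
                         observables=("pLC20",), noise_frac=0.0)
        table = generate_chemical_observables(spec)
        from dataclasses import replace as dc_replace
        free = [dc_replace(default_free_param("chemical.chi0.K"), init=0.001)]
        cfg = FitConfig(free=free, maxiter=60, seeds=(0,), sigma0=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit("chemical", table, cfg, base=bundle)
        assert res.L_con_sum == 0.0

    def test_invalid_stage_rejected(self, bundle):
        with pytest.raises(DomainError):
            fit("thermal", _table([_row()]),
                FitConfig(free=[default_free_param("chemical.chi2.K")]),
                base=bundle)

    def test_sigma0_bound_enforced(self):
        with pytest.raises(DomainError):
            FitConfig(free=[default_free_param("chemical.chi2.K")], sigma0=1.5)
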