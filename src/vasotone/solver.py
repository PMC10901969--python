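"""Steady-state coupling of SMC chemistry to vessel-wall mechanics.

For each luminal pressure and intervention the chemistry is solved first
(the network is feed-forward in pressure), then the deformed inner radius
``r_i`` and the normalized filament sliding ``u_fs_bar`` are obtained
simultaneously from the two-equation system

* wall equilibrium:  ``luminal_pressure(r_i, u_fs_bar) = P``
* force balance:     ``F_a(mean lambda_theta(r_i), u_fs_bar) = F_c(u_fs_bar)``

with the sliding driven by the thickness-averaged circumferential stretch.
A passive vessel (``n_XB = 0``) decouples: the force equation degenerates
to 0 = 0, the sliding fixed point is 0 and only the scalar pressure
equation remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root

from . import contractile as ct
from . import signalling as sg
from . import vessel_wall as vw
from .errors import DomainError, SolverError

__all__ = [
    "ModelBundle",
    "SolverOptions",
    "EquilibriumResult",
    "solve_equilibrium",
    "passive_radius",
    "pressure_sweep",
    "normalized_stiffness_curves",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelBundle:
    """All parameters of the chemo-mechanical model in one object."""

    network: sg.NetworkParams
    contractile: ct.ContractileParams = field(default_factory=ct.ContractileParams)
    geometry: vw.WallGeometry = field(default_factory=vw.WallGeometry)
    passive: vw.PassiveParams = field(default_factory=vw.PassiveParams)

    def with_geometry(self, **kw) -> "ModelBundle":
        return replace(self, geometry=replace(self.geometry, **kw))


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and restart policy of the equilibrium solve."""

    n_nodes: int = 81                  # Simpson nodes across the wall
    pressure_tol_mmHg: float = 1e-8
    force_tol_dyne: float = 1e-10
    n_restarts: int = 3                # perturbed restarts after a failure
    u_fs_restarts: tuple = (0.0, -0.03, -0.06, 0.03)


@dataclass(frozen=True)
class EquilibriumResult:
    """One converged chemo-mechanical equilibrium."""

    pressure_mmHg: float
    condition: str
    r_i: float
    u_fs_bar: float
    D_o: float
    lambda_theta_mean: float
    chem: sg.ChemicalOutput
    k_tCU: float
    k_AC: float
    residual_P_mmHg: float
    residual_F_dyne: float

    @property
    def n_XB(self) -> float:
        return self.chem.n_XB


def passive_radius(P_mmHg: float, b: ModelBundle,
                   opts: SolverOptions = SolverOptions()) -> float:
    """Deformed inner radius of the purely passive wall at pressure P.

    The passive pressure-radius curve is monotone increasing, so the root
    is bracketed by expanding an interval around the reference radius and
    polished with Brent's method.
    """
    g = b.geometry

    def f(r_i):
        return vw.luminal_pressure(r_i, 0.0, 0.0, 0.0, g, b.passive,
                                   b.contractile, opts.n_nodes) - P_mmHg

    lo, hi = 0.05 * g.R_i, 1.05 * g.R_i
    f_lo, f_hi = f(lo), f(hi)
    n_expand = 0
    while f_lo * f_hi > 0 and n_expand < 60:
        if f_hi < 0:         # wall still below target pressure: inflate
            hi *= 1.3
            f_hi = f(hi)
        else:                # even the collapsed wall exceeds target
            lo *= 0.5
            f_lo = f(lo)
        n_expand += 1
    if f_lo * f_hi > 0:
        raise SolverError(f"could not bracket passive radius at P={P_mmHg} mmHg")
    return float(brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16))


def _chemistry(P_mmHg: float, iv: sg.Intervention,
               b: ModelBundle) -> sg.ChemicalOutput:
    p_bar = b.network.normalize_pressure(P_mmHg)
    state = sg.steady_state(p_bar, b.network, iv)
    return sg.chemical_output(state, b.network)


def _force_residual(r_i, u_fs_bar, chem, b: ModelBundle, opts) -> float:
    lam_mean = vw.mean_circumferential_stretch(r_i, b.geometry, opts.n_nodes)
    k_tCU, k_AC, L_fo = ct.machinery_stiffnesses(chem.n_XB, chem.xi7,
                                                 u_fs_bar, b.contractile)
    F_a = ct.active_force(lam_mean, u_fs_bar, k_tCU, k_AC, b.contractile)
    F_c = ct.driving_force(chem.n_XB, L_fo, b.contractile)
    return F_a - F_c


def solve_equilibrium(P_mmHg: float, iv: sg.Intervention, b: ModelBundle,
                      opts: SolverOptions = SolverOptions(),
                      x0: Optional[tuple] = None) -> EquilibriumResult:
    """Solve the coupled pressure/force equilibrium at one pressure level.

    ``x0`` optionally seeds ``(r_i, u_fs_bar)`` (e.g. from a neighbouring
    pressure during continuation).  The 2-D root problem is solved with a
    quasi-Newton method (scipy ``root``), falling back through a ladder of
    perturbed restarts; residual tolerances come from ``opts``.
    """
    if P_mmHg < 0:
        raise DomainError("pressure must be non-negative")
    chem = _chemistry(P_mmHg, iv, b)
    g = b.geometry

    # F_c scale used to non-dimensionalize the force residual
    F_ref = ct.driving_force(b.network.n_XBmax, 1.0, b.contractile)

    if chem.n_XB <= 1e-14:
        # decoupled passive limit: no cross-bridges, no sliding
        r_i = passive_radius(P_mmHg, b, opts)
        return _package(P_mmHg, iv, r_i, 0.0, chem, b, opts)

    r_guess = x0[0] if x0 is not None else passive_radius(P_mmHg, b, opts)
    u_guesses: List[float] = [x0[1]] if x0 is not None else []
    u_guesses += [u for u in opts.u_fs_restarts]

    def residuals(z):
        r_i, u_fs = z[0] * g.R_i, z[1]
        if r_i <= 0.0:
            # steer quasi-Newton iterates back into the physical domain
            return [1e4 * (1.0 - z[0]), 1e4]
        res_P = vw.luminal_pressure(r_i, u_fs, chem.n_XB, chem.xi7,
                                    g, b.passive, b.contractile,
                                    opts.n_nodes) - P_mmHg
        res_F = _force_residual(r_i, u_fs, chem, b, opts)
        return [res_P, res_F / F_ref]

    best = None
    tried = []
    for attempt, u0 in enumerate(u_guesses[: 1 + opts.n_restarts + len(u_guesses)]):
        for method in ("hybr", "lm"):
            z0 = np.array([r_guess / g.R_i, u0])
            try:
                sol = root(residuals, z0, method=method,
                           options={"xtol": 1e-14} if method == "hybr"
                           else {"xtol": 1e-15, "ftol": 1e-15})
            except (vw.SolverIntegrandError, Exception) as exc:  # noqa: BLE001
                tried.append((u0, method, repr(exc)))
                continue
            res_P, res_F_scaled = residuals(sol.x)
            res_F = res_F_scaled * F_ref
            cand = (abs(res_P), abs(res_F), sol.x)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
            if (abs(res_P) <= opts.pressure_tol_mmHg
                    and abs(res_F) <= opts.force_tol_dyne):
                r_i, u_fs = sol.x[0] * g.R_i, sol.x[1]
                log.debug("P=%.2f mmHg converged (u0=%.3f, %s): "
                          "|dP|=%.2e mmHg |dF|=%.2e dyne",
                          P_mmHg, u0, method, abs(res_P), abs(res_F))
                return _package(P_mmHg, iv, r_i, u_fs, chem, b, opts)
            tried.append((u0, method, f"|dP|={abs(res_P):.1e}, |dF|={abs(res_F):.1e}"))

    raise SolverError(
        f"equilibrium at P={P_mmHg} mmHg ({iv.name}) did not converge; "
        f"attempts: {tried}",
        last_iterate=None if best is None else best[2],
        residuals=None if best is None else best[:2])


def _package(P_mmHg, iv, r_i, u_fs, chem, b, opts) -> EquilibriumResult:
    g = b.geometry
    lam_mean = vw.mean_circumferential_stretch(r_i, g, opts.n_nodes)
    k_tCU, k_AC, L_fo = ct.machinery_stiffnesses(chem.n_XB, chem.xi7,
                                                 u_fs, b.contractile)
    res_P = vw.luminal_pressure(r_i, u_fs, chem.n_XB, chem.xi7, g,
                                b.passive, b.contractile, opts.n_nodes) - P_mmHg
    res_F = _force_residual(r_i, u_fs, chem, b, opts) if chem.n_XB > 1e-14 else 0.0
    return EquilibriumResult(
        pressure_mmHg=P_mmHg, condition=iv.name, r_i=r_i, u_fs_bar=u_fs,
        D_o=vw.outer_diameter(r_i, g), lambda_theta_mean=lam_mean,
        chem=chem, k_tCU=k_tCU, k_AC=k_AC,
        residual_P_mmHg=res_P, residual_F_dyne=res_F)


def pressure_sweep(pressures: Sequence[float], iv: sg.Intervention,
                   b: ModelBundle, opts: SolverOptions = SolverOptions(),
                   continuation: bool = True) -> List[EquilibriumResult]:
    """Equilibria along an increasing pressure schedule.

    With ``continuation`` (default) each solution seeds the next pressure,
    which keeps the solver on the physical branch near the autoregulatory
    plateau.  Solver failures are re-raised with the failing pressure
    identified.
    """
    pressures = list(pressures)
    if not pressures:
        raise DomainError("empty pressure list")
    if any(b2 <= a for a, b2 in zip(pressures, pressures[1:])):
        raise DomainError("pressures must be strictly increasing")

    results: List[EquilibriumResult] = []
    x0 = None
    for P in pressures:
        try:
            res = solve_equilibrium(P, iv, b, opts, x0=x0)
        except SolverError as exc:
            raise SolverError(f"sweep failed at P={P} mmHg ({iv.name}): {exc}",
                              last_iterate=exc.last_iterate,
                              residuals=exc.residuals) from exc
        results.append(res)
        if continuation:
            x0 = (res.r_i, res.u_fs_bar)
    return results


def normalized_stiffness_curves(sweeps: Dict[str, List[EquilibriumResult]],
                                control: str = "control"):
    """Per-condition CU and cortex stiffness normalized to same-pressure control.

    Returns ``{condition: (pressures, kbar_tCU, kbar_AC)}``; the control
    curves are identically 1.  All sweeps must share the control's pressure
    grid.
    """
    if control not in sweeps:
        raise DomainError(f"control sweep {control!r} missing")
    ctrl = sweeps[control]
    P_ctrl = np.array([r.pressure_mmHg for r in ctrl])
    out = {}
    for name, sweep in sweeps.items():
        P = np.array([r.pressure_mmHg for r in sweep])
        if P.shape != P_ctrl.shape or not np.allclose(P, P_ctrl):
            raise DomainError(f"pressure grid of {name!r} does not match control")
        kbar_tCU = np.array([r.k_tCU / c.k_tCU for r, c in zip(sweep, ctrl)])
        kbar_AC = np.array([r.k_AC / c.k_AC for r, c in zip(sweep, ctrl)])
        out[name] = (P, kbar_tCU, kbar_AC)
    return out
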