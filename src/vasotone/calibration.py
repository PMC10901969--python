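"""Two-tier penalty-constrained parameter identification.

The chemical sub-model (logistic-edge coefficients) and the mechanical
sub-model (geometry, passive, active parameters) are fitted in two stages
against observable tables of (condition, observable, pressure, mean, sd)
rows.  The cost is

``L_tot = L_data + sum_i L_con_i``,

where ``L_data`` is the unweighted L2 norm of simulated-minus-mean
residuals (after each row's normalization) and each constraint enters as a
linear penalty ``L_con_i = kappa * delta_i`` with ``delta_i`` the distance
by which the constraint is violated (0 when satisfied).  Minimization uses
CMA-ES with a seed list; the best-of-seeds result is returned with full
reproducibility metadata.

Observable kinds and their simulated counterparts:

==========  =======================  ===========================
kind        network quantity          normalization used in data
==========  =======================  ===========================
pLC20       xi5                      absolute
pMLCP       xi3                      relative to control, 10 mmHg
pHSP27      xi2                      relative to control, 10 mmHg
pCofilin    xi4                      relative to control, 10 mmHg
Gactin      xi6                      relative to control, 10 mmHg
Do          outer diameter (cm)      absolute
==========  =======================  ===========================
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cmaes
from . import signalling as sg
from .errors import CoverageError, DomainError, SolverError
from .solver import ModelBundle, SolverOptions, pressure_sweep
from .signalling import Intervention, ec50

__all__ = [
    "ObservableTable", "FreeParam", "FitConfig", "FitResult",
    "simulate_observables", "data_cost", "penalty",
    "chemical_constraints", "mechanical_constraints", "fit",
    "preprocess_gf_plc20", "CHEMICAL_OBSERVABLES",
]

log = logging.getLogger(__name__)

OBSERVABLE_NODE = {"pLC20": 5, "pMLCP": 3, "pHSP27": 2, "pCofilin": 4, "Gactin": 6}
CHEMICAL_OBSERVABLES = tuple(OBSERVABLE_NODE)
VALID_NORMALIZATIONS = {"absolute", "rel_control_10mmHg"}
TABLE_COLUMNS = ["condition", "observable", "pressure_mmHg", "mean", "sd",
                 "normalization"]


@dataclass
class ObservableTable:
    """Tidy table of experimental/synthetic observables.

    Thin wrapper over a DataFrame with the schema
    ``condition, observable, pressure_mmHg, mean, sd, normalization``
    (extra columns such as ``group`` are carried through untouched).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DomainError(f"observable table missing columns {missing}")
        if (self.frame["sd"] < 0).any():
            raise DomainError("standard deviations must be >= 0")
        if (self.frame["pressure_mmHg"] <= 0).any():
            raise DomainError("pressures must be positive")
        bad_norm = set(self.frame["normalization"]) - VALID_NORMALIZATIONS
        if bad_norm:
            raise DomainError(f"unknown normalization(s): {bad_norm}")
        per_kind = self.frame.groupby("observable")["normalization"].nunique()
        if (per_kind > 1).any():
            raise DomainError("normalization must be consistent per observable")

    @classmethod
    def from_csv(cls, path) -> "ObservableTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, float_format="%.10g")

    def __len__(self):
        return len(self.frame)


def _interventions_for(conditions) -> Dict[str, Intervention]:
    return {c: Intervention.preset(c) for c in conditions}


def simulate_observables(table: ObservableTable, bundle: ModelBundle,
                         solver_opts: SolverOptions = SolverOptions()) -> np.ndarray:
    """Simulated value for every row of ``table``, in row order.

    Chemical observables come from the closed-form network steady state;
    ``Do`` rows require full chemo-mechanical sweeps (one per condition and
    vessel group).  Rows normalized ``rel_control_10mmHg`` are divided by
    the simulated control value at 10 mmHg.
    """
    df = table.frame
    ivs = _interventions_for(df["condition"].unique())
    net = bundle.network

    state_cache: Dict[Tuple[str, float], sg.NetworkState] = {}

    def state(cond, P):
        key = (cond, P)
        if key not in state_cache:
            state_cache[key] = sg.steady_state(net.normalize_pressure(P),
                                               net, ivs[cond])
        return state_cache[key]

    # mechanical sweeps per (condition, group R_o')
    do_cache: Dict[Tuple[str, float], Dict[float, float]] = {}
    do_rows = df[df["observable"] == "Do"]
    if len(do_rows):
        groups = (do_rows["R_o_prime_cm"] if "R_o_prime_cm" in do_rows
                  else pd.Series(bundle.geometry.R_o_prime, index=do_rows.index))
        for (cond, Ro), sub in do_rows.groupby([do_rows["condition"], groups]):
            P_list = sorted(sub["pressure_mmHg"].unique())
            bnd = bundle.with_geometry(R_o_prime=float(Ro))
            sweep = pressure_sweep(P_list, ivs[cond], bnd, solver_opts)
            do_cache[(cond, float(Ro))] = {r.pressure_mmHg: r.D_o for r in sweep}

    ro_col = (df["R_o_prime_cm"].to_numpy() if "R_o_prime_cm" in df
              else np.full(len(df), bundle.geometry.R_o_prime))
    values = np.empty(len(df))
    cols = zip(df["observable"].to_numpy(), df["condition"].to_numpy(),
               df["pressure_mmHg"].to_numpy(), df["normalization"].to_numpy(),
               ro_col)
    for i, (kind, cond, P, norm, Ro) in enumerate(cols):
        if kind in OBSERVABLE_NODE:
            v = state(cond, P)[OBSERVABLE_NODE[kind]]
            if norm == "rel_control_10mmHg":
                ref = state("control", 10.0)[OBSERVABLE_NODE[kind]]
                if ref == 0:
                    raise CoverageError(
                        f"control reference for {kind} at 10 mmHg is zero")
                v = v / ref
        elif kind == "Do":
            try:
                v = do_cache[(cond, float(Ro))][P]
            except KeyError as exc:
                raise CoverageError(f"no simulated Do for {cond}@{P}") from exc
        else:
            raise CoverageError(f"unknown observable kind {kind!r}")
        values[i] = v
    return values


def data_cost(sim: np.ndarray, table: ObservableTable) -> float:
    """Unweighted L2 norm of simulated-minus-mean residuals."""
    if len(sim) != len(table):
        raise CoverageError("simulated values do not cover the table")
    return float(np.linalg.norm(sim - table.frame["mean"].to_numpy()))


def penalty(delta: float, kappa: float) -> float:
    """Linear penalty ``kappa * delta`` for a constraint violated by ``delta``."""
    if delta < 0:
        raise DomainError("constraint distance must be >= 0")
    return kappa * delta


def chemical_constraints(net: sg.NetworkParams,
                         pressures=None,
                         ca_envelope: Optional[pd.DataFrame] = None,
                         _warn=True) -> Dict[str, float]:
    """Violation distances of the chemical-stage constraints.

    * ``ec50``: the pressure-Ca2+ activation must have EC50 >= 0.1
      (normalized pressure).
    * ``ca_free_plc20``: with Ca2+ clamped to 0.1 the steady-state pLC20
      must not exceed the unclamped control value at 10 mmHg, for any
      pressure up to 120 mmHg.
    * ``ca_envelope``: the pressure-Ca2+ curve must lie inside a
      user-supplied (pressure_mmHg, low, high) band; skipped with a warning
      when no band is given.
    """
    if pressures is None:
        pressures = np.arange(10.0, 121.0, 5.0)
    deltas: Dict[str, float] = {}
    deltas["ec50"] = max(0.0, 0.1 - ec50(net.chi(0)))

    ref = sg.steady_state(net.normalize_pressure(10.0), net)[5]
    ca_free = Intervention.preset("ca_free")
    worst = 0.0
    for P in pressures:
        xi5 = sg.steady_state(net.normalize_pressure(P), net, ca_free)[5]
        worst = max(worst, xi5 - ref)
    deltas["ca_free_plc20"] = max(0.0, worst)

    if ca_envelope is not None:
        viol = 0.0
        for _, row in ca_envelope.iterrows():
            chi0 = net.chi(0)(net.normalize_pressure(row["pressure_mmHg"]))
            viol = max(viol, row["low"] - chi0, chi0 - row["high"])
        deltas["ca_envelope"] = max(0.0, viol)
    elif _warn:
        warnings.warn("no pressure-Ca2+ envelope supplied; the envelope "
                      "constraint is skipped", stacklevel=2)
    return deltas


#: box constraints enforced during the mechanical fit; the scale-bound
#: parameters are restrained to [0.1, 10] x reference value
GEOMETRY_BOXES = {"h_w": (0.13, 0.40), "lambda_z": (1.0, 1.5),
                  "k_omega": (1.0, 1.5)}
SCALE_BOUND_PARAMS = ("u_PS", "kXB_over_dm", "k_ACmax")


def _box_delta(value, lo, hi) -> float:
    return max(0.0, lo - value, value - hi)


def mechanical_constraints(bundle: ModelBundle,
                           control_sweep=None,
                           reference_values: Optional[Mapping[str, float]] = None,
                           solver_opts: SolverOptions = SolverOptions(),
                           plateau_band=(60.0, 100.0)) -> Dict[str, float]:
    """Violation distances of the mechanical-stage constraints.

    * ``u_fs``: |u_fs_bar| must stay within 0.1 over the control sweep.
    * ``plateau``: dD_o/dP under control must not be positive across the
      whole 60-100 mmHg band (central differences on the sweep grid), i.e.
      the myogenic response must flatten or invert the passive inflation
      somewhere in that band.
    * box constraints on h_w, lambda_z, k_omega and on the scale-bound
      active parameters (u_PS, k_XB/delta_m, k_ACmax within [0.1, 10] times
      their reference values).
    """
    if control_sweep is None:
        control_sweep = pressure_sweep(np.arange(10.0, 121.0, 5.0),
                                       Intervention.preset("control"),
                                       bundle, solver_opts)
    deltas: Dict[str, float] = {}

    if len(control_sweep):
        max_ufs = max(abs(r.u_fs_bar) for r in control_sweep)
        deltas["u_fs"] = max(0.0, max_ufs - 0.1)
        P = np.array([r.pressure_mmHg for r in control_sweep])
        Do = np.array([r.D_o for r in control_sweep])
        dDo_dP = np.gradient(Do, P)       # central differences inside the grid
        band = (P >= plateau_band[0]) & (P <= plateau_band[1])
        if band.sum() >= 2:
            # penalized only when the slope is positive across the entire band
            deltas["plateau"] = max(0.0, float(dDo_dP[band].min()))
        else:
            deltas["plateau"] = 0.0
    else:
        deltas["u_fs"] = 0.0
        deltas["plateau"] = 0.0

    g = bundle.geometry
    for name, (lo, hi) in GEOMETRY_BOXES.items():
        deltas[f"box_{name}"] = _box_delta(getattr(g, name), lo, hi)

    rv = dict(reference_values or {})
    for name in SCALE_BOUND_PARAMS:
        ref = rv.get(name, getattr(bundle.contractile, name))
        val = getattr(bundle.contractile, name)
        deltas[f"box_{name}"] = _box_delta(val / ref, 0.1, 10.0)
    return deltas


@dataclass(frozen=True)
class FreeParam:
    """One fitted parameter: dotted path, search transform and bounds.

    ``path`` addresses the bundle, e.g. ``chemical.chi2.K``,
    ``geometry.h_w`` or ``mechanical.u_PS``.  ``transform`` is ``linear``
    or ``log10`` (positive scale parameters search in decades).  Bounds are
    enforced through the penalty term, not by clipping.
    """

    path: str
    transform: str = "linear"
    init: float = 0.3
    lower: float = -np.inf
    upper: float = np.inf

    def encode(self, value: float) -> float:
        return np.log10(value) if self.transform == "log10" else value

    def decode(self, z: float) -> float:
        return 10.0 ** z if self.transform == "log10" else z


def default_free_param(path: str) -> FreeParam:
    """Sensible search spec for a parameter named by its dotted path."""
    leaf = path.rsplit(".", 1)[-1]
    if leaf == "B0":
        return FreeParam(path, "linear", init=0.3, lower=0.0, upper=0.999)
    if leaf in ("K", "n"):
        return FreeParam(path, "log10", init=1.0, lower=1e-4, upper=1e4)
    if leaf in GEOMETRY_BOXES:
        lo, hi = GEOMETRY_BOXES[leaf]
        return FreeParam(path, "linear", init=0.5 * (lo + hi), lower=lo, upper=hi)
    return FreeParam(path, "log10", init=1.0, lower=1e-8, upper=1e12)


def _set_path(bundle: ModelBundle, path: str, value: float) -> ModelBundle:
    parts = path.split(".")
    if parts[0] == "chemical" and len(parts) == 3:
        return replace(bundle, network=bundle.network.with_edge(
            parts[1], **{parts[2]: value}))
    if parts[0] == "chemical" and len(parts) == 2:
        return replace(bundle, network=replace(bundle.network, **{parts[1]: value}))
    if parts[0] == "geometry":
        return replace(bundle, geometry=replace(bundle.geometry, **{parts[1]: value}))
    if parts[0] == "passive":
        return replace(bundle, passive=replace(bundle.passive, **{parts[1]: value}))
    if parts[0] == "mechanical":
        return replace(bundle, contractile=replace(bundle.contractile,
                                                   **{parts[1]: value}))
    raise DomainError(f"cannot address parameter {path!r}")


def get_path(bundle: ModelBundle, path: str) -> float:
    parts = path.split(".")
    if parts[0] == "chemical" and len(parts) == 3:
        return getattr(bundle.network.edges[parts[1]], parts[2])
    obj = {"chemical": bundle.network, "geometry": bundle.geometry,
           "passive": bundle.passive, "mechanical": bundle.contractile}[parts[0]]
    return getattr(obj, parts[-1])


@dataclass
class FitConfig:
    """Settings of one calibration stage."""

    free: Sequence[FreeParam]
    kappa: float = 1.0e3
    maxiter: int = 1000
    sigma0: float = 0.3
    seeds: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7)
    popsize: Optional[int] = None
    gf_rescale_factor: float = 1.1
    ca_envelope: Optional[pd.DataFrame] = None
    reference_values: Optional[Dict[str, float]] = None
    solver_opts: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if not (self.sigma0 <= 1.0):
            raise DomainError("sigma0 must not exceed 1")
        if not (self.kappa > 0):
            raise DomainError("kappa must be positive")


@dataclass
class FitResult:
    """Best-of-seeds calibration outcome with reproducibility metadata."""

    best_params: Dict[str, float]
    L_data: float
    L_con: Dict[str, float]
    L_con_sum: float
    L_tot: float
    best_seed: int
    n_iter: int
    seed_results: List[dict]
    stage: str
    bundle: ModelBundle


def _objective_factory(stage: str, table: ObservableTable, cfg: FitConfig,
                       base: ModelBundle):
    free = list(cfg.free)

    def build(z) -> ModelBundle:
        b = base
        for fp, zi in zip(free, z):
            b = _set_path(b, fp.path, fp.decode(zi))
        return b

    def bound_deltas(z) -> Dict[str, float]:
        out = {}
        for fp, zi in zip(free, z):
            v = fp.decode(zi)
            d = _box_delta(v, fp.lower, fp.upper)
            if d > 0:
                out[f"bound_{fp.path}"] = d
        return out

    def evaluate(z) -> Tuple[float, float, Dict[str, float]]:
        deltas = bound_deltas(z)
        try:
            bundle = build(z)
        except (DomainError, ValueError):
            # invalid decode (e.g. B0 >= 1): bound penalty plus a fixed offset
            return 1e6 + sum(deltas.values()) * cfg.kappa, 0.0, deltas
        try:
            sim = simulate_observables(table, bundle, cfg.solver_opts)
            L_data = data_cost(sim, table)
            if stage == "chemical":
                deltas.update(chemical_constraints(
                    bundle.network, ca_envelope=cfg.ca_envelope, _warn=False))
            else:
                deltas.update(mechanical_constraints(
                    bundle, reference_values=cfg.reference_values,
                    solver_opts=cfg.solver_opts))
        except (SolverError, CoverageError, DomainError, ValueError,
                ArithmeticError) as exc:
            log.debug("objective evaluation failed: %s", exc)
            return 1e6 + sum(deltas.values()) * cfg.kappa, 0.0, deltas
        L_con = sum(penalty(d, cfg.kappa) for d in deltas.values())
        return L_data + L_con, L_data, deltas

    return build, evaluate


def fit(stage: str, table: ObservableTable, cfg: FitConfig,
        base: Optional[ModelBundle] = None) -> FitResult:
    """Run one calibration stage (``chemical`` or ``mechanical``).

    For the mechanical stage, pass the base bundle carrying the (frozen)
    best-fit chemical parameters.  Runs CMA-ES once per seed in
    ``cfg.seeds`` and returns the best result; deterministic given the
    seed list.
    """
    if stage not in ("chemical", "mechanical"):
        raise DomainError("stage must be 'chemical' or 'mechanical'")
    if base is None:
        from .config import default_params
        base = default_params()
    if stage == "chemical" and cfg.ca_envelope is None:
        warnings.warn("no pressure-Ca2+ envelope supplied; that constraint "
                      "is skipped during the chemical fit", stacklevel=2)

    build, evaluate = _objective_factory(stage, table, cfg, base)
    z0 = np.array([fp.encode(fp.init) for fp in cfg.free])

    seed_results = []
    best = None
    for seed in cfg.seeds:
        res = cmaes.minimize(lambda z: evaluate(z)[0], z0, cfg.sigma0,
                             maxiter=cfg.maxiter, seed=seed,
                             popsize=cfg.popsize)
        seed_results.append({"seed": seed, "L_tot": res.fun,
                             "n_iter": res.nit, "nfev": res.nfev,
                             "x": res.x.tolist()})
        if best is None or res.fun < best[0].fun:
            best = (res, seed)
    res, best_seed = best

    if res.fun >= evaluate(z0)[0]:
        warnings.warn("no seed improved on the initial point; "
                      "inspect seed_results", stacklevel=2)

    L_tot, L_data, deltas = evaluate(res.x)
    L_con = {k: penalty(d, cfg.kappa) for k, d in deltas.items()}
    bundle = build(res.x)
    best_params = {fp.path: fp.decode(zi) for fp, zi in zip(cfg.free, res.x)}
    return FitResult(best_params=best_params, L_data=L_data, L_con=L_con,
                     L_con_sum=sum(L_con.values()), L_tot=L_tot,
                     best_seed=best_seed, n_iter=res.nit,
                     seed_results=seed_results, stage=stage, bundle=bundle)


def preprocess_gf_plc20(values, sds, factor: float = 1.1):
    """Re-scale a 100 mmHg-referenced pLC20 series to the control reference.

    Multiplies means by ``factor`` and propagates the standard deviations by
    the same factor (scaling of an independent variable).
    """
    values = np.asarray(values, float) * factor
    sds = np.asarray(sds, float) * factor
    return values, sds
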