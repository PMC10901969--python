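"""Pressure-driven logic-based signalling network of the vascular SMC.

The chemical sub-model is a seven-node network driven by normalized luminal
pressure ``p_bar``.  Nodes are the normalized activity/phosphorylation levels

====  ===========  ==========================================
idx   name         meaning
====  ===========  ==========================================
xi0   ca           cytosolic Ca2+ level
xi1   rock         ROCK activity
xi2   phsp27       HSP27 phosphorylation (PKC pathway)
xi3   pmlcp        MLCP phosphorylation (Ca2+ sensitization)
xi4   pcofilin     Cofilin phosphorylation
xi5   plc20        LC20 phosphorylation (activated myosin)
xi6   gactin       G-actin content (1 - F-actin)
====  ===========  ==========================================

Each activation/inhibition edge is a three-parameter logistic curve
``chi(x) = B0 + (1 - B0) (1 + K^n) x^n / (x^n + K^n)`` pinned to
``chi(0) = B0`` and ``chi(1) = 1``.  Multiple influences on a node combine
with fuzzy-logic AND / OR / AND-NOT operators; the pLC20 node instead obeys
a kinase/phosphatase mass balance.  The network is a DAG, so steady states
are available in closed form by topological order; time integration of the
relaxation ODEs is provided as an independent route to the same fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import DomainError, SingularEquilibriumError, SolverError

__all__ = [
    "LogisticEdge",
    "NetworkParams",
    "NetworkState",
    "Intervention",
    "ChemicalOutput",
    "EDGE_LABELS",
    "NODE_NAMES",
    "logistic_eval",
    "logic_combine",
    "network_rhs",
    "steady_state",
    "integrate_transient",
    "chemical_output",
    "ec50",
]

EDGE_LABELS = tuple(f"chi{i}" for i in range(9))
NODE_NAMES = ("xi0", "xi1", "xi2", "xi3", "xi4", "xi5", "xi6")

#: biological aliases accepted wherever a node is named
NODE_ALIASES = {
    "ca": 0, "rock": 1, "phsp27": 2, "pmlcp": 3,
    "pcofilin": 4, "plc20": 5, "gactin": 6,
    **{name: i for i, name in enumerate(NODE_NAMES)},
}


@dataclass(frozen=True)
class LogisticEdge:
    """One activation/inhibition curve of the signalling network.

    Parameters
    ----------
    B0 : float
        Basal activity level, ``0 <= B0 < 1``; the curve's value at input 0.
    K : float
        Half-saturation-like coefficient, ``K > 0``.
    n : float
        Steepness exponent, ``n > 0``.
    label : str
        One of ``chi0 .. chi8`` (purely informational).
    """

    B0: float
    K: float
    n: float
    label: str = ""

    def __post_init__(self):
        if not (0.0 <= self.B0 < 1.0):
            raise DomainError(f"{self.label or 'edge'}: B0={self.B0} outside [0, 1)")
        if not (self.K > 0.0):
            raise DomainError(f"{self.label or 'edge'}: K={self.K} must be > 0")
        if not (self.n > 0.0):
            raise DomainError(f"{self.label or 'edge'}: n={self.n} must be > 0")

    def __call__(self, x):
        return logistic_eval(self, x)


def logistic_eval(edge: LogisticEdge, x):
    """Evaluate a logistic edge at normalized input ``x`` in [0, 1].

    The curve is ``B0 + (1 - B0)(1 + K^n) x^n / (x^n + K^n)``.  Evaluation is
    carried out in log space so that extreme fitted exponents (e.g. n > 500)
    neither overflow nor underflow: with ``a = K^n`` the gain factor is
    ``(1 + a) x^n / (x^n + a) = exp(log1p(a) - log1p(exp(n log(K/x))))``.

    Endpoints are returned exactly: ``chi(0) = B0`` and ``chi(1) = 1``.
    """
    if isinstance(x, float) or isinstance(x, int):
        return _logistic_scalar(edge, float(x))
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr < 0.0) or np.any(xarr > 1.0):
        raise DomainError(f"logistic input outside [0, 1]: {x!r}")

    log_a = edge.n * math.log(edge.K)          # log K^n
    # log1p(K^n), safe against overflow of K^n itself
    l1p_a = log_a if log_a > 700.0 else math.log1p(math.exp(log_a))

    with np.errstate(divide="ignore"):
        s = edge.n * (math.log(edge.K) - np.log(xarr))   # log (K/x)^n; inf at x=0
    l1p_s = np.where(s > 700.0, s, np.log1p(np.exp(np.minimum(s, 700.0))))
    gain = np.exp(l1p_a - l1p_s)

    out = edge.B0 + (1.0 - edge.B0) * gain
    # pin the endpoints to their exact contract values
    out = np.where(xarr == 0.0, edge.B0, out)
    out = np.where(xarr == 1.0, 1.0, out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def _logistic_scalar(edge: LogisticEdge, x: float) -> float:
    # pure-math fast path; hot inside steady-state loops and calibration
    if x < 0.0 or x > 1.0:
        raise DomainError(f"logistic input outside [0, 1]: {x!r}")
    if x == 0.0:
        return edge.B0
    if x == 1.0:
        return 1.0
    log_a = edge.n * math.log(edge.K)
    l1p_a = log_a if log_a > 700.0 else math.log1p(math.exp(log_a))
    s = edge.n * (math.log(edge.K) - math.log(x))
    l1p_s = s if s > 700.0 else math.log1p(math.exp(s))
    return edge.B0 + (1.0 - edge.B0) * math.exp(l1p_a - l1p_s)


def logic_combine(kind: str, a, b):
    """Fuzzy-logic combination of two activity levels in [0, 1].

    ``AND -> a*b``,  ``OR -> a + b - a*b``,  ``ANDNOT -> a*(1 - b)``.
    """
    a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
    if np.any((a_arr < 0) | (a_arr > 1)) or np.any((b_arr < 0) | (b_arr > 1)):
        raise DomainError("logic_combine inputs must lie in [0, 1]")
    kind_up = kind.upper()
    if kind_up == "AND":
        out = a_arr * b_arr
    elif kind_up == "OR":
        out = a_arr + b_arr - a_arr * b_arr
    elif kind_up == "ANDNOT":
        out = a_arr * (1.0 - b_arr)
    else:
        raise DomainError(f"unknown logic operator {kind!r}")
    if np.ndim(out) == 0:
        return float(out)
    return out


def _default_tau() -> tuple:
    return (1.0,) * 7


@dataclass(frozen=True)
class NetworkParams:
    """Full parameter set of the chemical sub-model.

    ``edges`` holds the nine logistic edges keyed ``chi0 .. chi8``; ``tau``
    are the seven relaxation time constants (dimensionless, all 1 for the
    steady-state studies); ``P_max_mmHg`` is the pressure beyond which all
    intracellular processes saturate; ``n_XBmax`` the maximum fraction of
    cross-bridges that can be phosphorylated.
    """

    edges: Mapping[str, LogisticEdge]
    tau: Sequence[float] = field(default_factory=_default_tau)
    P_max_mmHg: float = 150.0
    n_XBmax: float = 0.55

    def __post_init__(self):
        missing = [lab for lab in EDGE_LABELS if lab not in self.edges]
        if missing:
            raise DomainError(f"missing edges: {missing}")
        if len(self.tau) != 7 or any(t <= 0 for t in self.tau):
            raise DomainError("tau must be seven positive time constants")
        if not (self.P_max_mmHg > 0):
            raise DomainError("P_max_mmHg must be positive")
        if not (0.0 < self.n_XBmax <= 1.0):
            raise DomainError("n_XBmax must lie in (0, 1]")

    def chi(self, i: int) -> LogisticEdge:
        return self.edges[f"chi{i}"]

    def normalize_pressure(self, P_mmHg) -> float:
        """p_bar = min(P / P_max, 1); pressures above P_max saturate."""
        p = np.minimum(np.asarray(P_mmHg, float) / self.P_max_mmHg, 1.0)
        if np.any(p < 0):
            raise DomainError("pressure must be non-negative")
        return float(p) if np.ndim(P_mmHg) == 0 else p

    def with_edge(self, label: str, **coef) -> "NetworkParams":
        """Return a copy with one edge's coefficients replaced."""
        edges = dict(self.edges)
        edges[label] = replace(edges[label], **coef)
        return replace(self, edges=edges)


@dataclass(frozen=True)
class NetworkState:
    """Normalized node levels xi0..xi6, each in [0, 1]."""

    xi: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.xi, dtype=float)
        if arr.shape != (7,):
            raise DomainError("NetworkState needs exactly seven levels")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise DomainError(f"node levels outside [0, 1]: {arr}")
        object.__setattr__(self, "xi", np.clip(arr, 0.0, 1.0))

    def __getitem__(self, i):
        return float(self.xi[i])

    def as_dict(self) -> Dict[str, float]:
        return {name: float(v) for name, v in zip(NODE_NAMES, self.xi)}


#: named interventions from the pharmacology the model emulates
PRESETS: Dict[str, Dict[int, float]] = {
    "control": {},
    "ca_free": {0: 0.1},        # extracellular Ca2+ removal
    "h1152_0.3": {1: 0.12},     # 0.3 uM ROCK inhibitor H1152
    "h1152_0.5": {1: 0.07},     # 0.5 uM H1152
    "gf_3": {2: 0.1},           # 3.0 uM PKC inhibitor GF109203X
}


@dataclass(frozen=True)
class Intervention:
    """A set of node clamps, e.g. a Ca2+-free bath or a drug dose.

    A clamped node's ODE is removed and the clamp value is substituted
    wherever the node feeds another equation; downstream nodes still
    equilibrate.
    """

    clamps: Mapping[int, float] = field(default_factory=dict)
    name: str = "control"

    def __post_init__(self):
        for node, value in self.clamps.items():
            if node not in range(7):
                raise DomainError(f"unknown node index {node}")
            if not (0.0 <= value <= 1.0):
                raise DomainError(f"clamp value {value} for node {node} outside [0, 1]")

    @classmethod
    def preset(cls, name: str) -> "Intervention":
        if name not in PRESETS:
            raise DomainError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(clamps=dict(PRESETS[name]), name=name)

    @classmethod
    def from_clamp_strings(cls, specs: Sequence[str], name: str = "custom") -> "Intervention":
        """Parse CLI-style clamp strings like ``xi1=0.12`` or ``rock=0.12``."""
        clamps = {}
        for s in specs:
            key, _, val = s.partition("=")
            key = key.strip().lower()
            if key not in NODE_ALIASES:
                raise DomainError(f"unknown node {key!r} in clamp {s!r}")
            clamps[NODE_ALIASES[key]] = float(val)
        return cls(clamps=clamps, name=name)

    def is_clamped(self, i: int) -> bool:
        return i in self.clamps


CONTROL = Intervention()


@dataclass(frozen=True)
class ChemicalOutput:
    """What the chemistry hands to the mechanics.

    ``n_XB`` is the fraction of phosphorylated (cycling) cross-bridges,
    ``xi7 = 1 - xi6`` the F-actin (polymerized) level.
    """

    n_XB: float
    xi7: float
    state: NetworkState


def _apply_clamps(xi: np.ndarray, iv: Intervention) -> np.ndarray:
    out = xi.copy()
    for node, value in iv.clamps.items():
        out[node] = value
    return out


def network_rhs(state: NetworkState | np.ndarray, p_bar: float,
                params: NetworkParams, iv: Intervention = CONTROL) -> np.ndarray:
    """Time derivatives of the seven node ODEs.

    Upstream drives relax each node towards its logistic target; pLC20
    follows the kinase/phosphatase mass balance
    ``chi5(xi0)(1 - xi5) - (1 - chi6(xi3)) xi5``, and G-actin relaxes to the
    OR-combined down-regulation by pCofilin and pHSP27.  Clamped nodes have
    zero derivative and their clamp value substituted everywhere.
    """
    if not (0.0 <= p_bar <= 1.0):
        raise DomainError(f"p_bar={p_bar} outside [0, 1]")
    xi = state.xi if isinstance(state, NetworkState) else np.asarray(state, float)
    # tolerate the tiny box overshoots an adaptive ODE stepper can produce
    xi = np.clip(_apply_clamps(xi, iv), 0.0, 1.0)
    chi = params.chi
    tau = np.asarray(params.tau, float)

    d = np.empty(7)
    d[0] = chi(0)(p_bar) - xi[0]
    d[1] = chi(1)(p_bar) - xi[1]
    d[2] = chi(2)(p_bar) - xi[2]
    d[3] = chi(3)(xi[1]) - xi[3]
    d[4] = chi(4)(xi[1]) - xi[4]
    d[5] = chi(5)(xi[0]) * (1.0 - xi[5]) - (1.0 - chi(6)(xi[3])) * xi[5]
    d[6] = logic_combine("OR", 1.0 - chi(7)(xi[4]), 1.0 - chi(8)(xi[2])) - xi[6]
    d /= tau
    for node in iv.clamps:
        d[node] = 0.0
    return d


def steady_state(p_bar: float, params: NetworkParams,
                 iv: Intervention = CONTROL) -> NetworkState:
    """Closed-form steady state of the network at normalized pressure ``p_bar``.

    The network is acyclic, so nodes equilibrate in topological order:
    the pressure-sensing nodes take their logistic targets, pMLCP and
    pCofilin follow ROCK, pLC20 balances kinase against phosphatase
    (``chi5 / (chi5 + 1 - chi6)``) and G-actin takes the OR-combined
    down-regulation.  Clamps override the corresponding node.

    Raises
    ------
    SingularEquilibriumError
        If the kinase drive is zero while the phosphatase is fully
        inhibited (``chi5 = 0`` and ``chi6 = 1`` simultaneously), which
        leaves the pLC20 balance 0/0.
    """
    if not (0.0 <= p_bar <= 1.0):
        raise DomainError(f"p_bar={p_bar} outside [0, 1]")
    chi = params.chi
    c = iv.clamps
    xi = np.empty(7)
    xi[0] = c.get(0, chi(0)(p_bar))
    xi[1] = c.get(1, chi(1)(p_bar))
    xi[2] = c.get(2, chi(2)(p_bar))
    xi[3] = c.get(3, chi(3)(xi[1]))
    xi[4] = c.get(4, chi(4)(xi[1]))
    if 5 in c:
        xi[5] = c[5]
    else:
        kin = chi(5)(xi[0])
        phos = 1.0 - chi(6)(xi[3])
        denom = kin + phos
        if denom == 0.0:
            raise SingularEquilibriumError(
                "pLC20 equilibrium is 0/0: kinase drive chi5 = 0 with "
                "phosphatase fully inhibited (chi6 = 1)")
        xi[5] = kin / denom
    xi[6] = c.get(6, logic_combine("OR", 1.0 - chi(7)(xi[4]), 1.0 - chi(8)(xi[2])))
    return NetworkState(xi)


def integrate_transient(state0: NetworkState, p_bar_schedule,
                        params: NetworkParams, iv: Intervention = CONTROL,
                        t_span=(0.0, 1.0e3), t_eval=None,
                        rtol=1e-10, atol=1e-12):
    """Integrate the relaxation ODEs over time.

    ``p_bar_schedule`` is either a constant in [0, 1] or a callable
    ``t -> p_bar``.  Returns the scipy ``OdeResult``; under constant
    pressure the long-time limit matches :func:`steady_state`.
    """
    if callable(p_bar_schedule):
        p_of_t: Callable[[float], float] = p_bar_schedule
    else:
        p_const = float(p_bar_schedule)
        p_of_t = lambda t: p_const  # noqa: E731

    y0 = _apply_clamps(state0.xi, iv)

    def rhs(t, y):
        return network_rhs(y, p_of_t(t), params, iv)

    sol = solve_ivp(rhs, t_span, y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"transient integration failed: {sol.message}",
                          last_iterate=sol.y[:, -1] if sol.y.size else y0)
    return sol


def chemical_output(state: NetworkState, params: NetworkParams) -> ChemicalOutput:
    """Chemistry-to-mechanics coupling: ``n_XB = xi5 * n_XBmax``, ``xi7 = 1 - xi6``."""
    return ChemicalOutput(n_XB=state[5] * params.n_XBmax,
                          xi7=1.0 - state[6], state=state)


def ec50(edge: LogisticEdge, xtol: float = 1e-12) -> float:
    """Input at which the edge reaches half of its dynamic range.

    Solves ``chi(x) = B0 + (1 - B0)/2`` by bracketed root search on (0, 1);
    monotonicity of the logistic curve guarantees uniqueness.
    """
    target = edge.B0 + 0.5 * (1.0 - edge.B0)

    def f(x):
        return logistic_eval(edge, x) - target

    return float(brentq(f, 0.0, 1.0, xtol=xtol))
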