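"""Synthetic observable tables with the statistical structure of pressure
myography experiments.

Forward-simulates a ground-truth parameter set over a pressure grid and a
set of pharmacological conditions, then emulates biological replicates by
adding independent truncated Gaussian noise and emitting per-point means
and standard deviations.  The emitted CSV schema is identical to the
calibration input, so the full generate -> fit -> recover loop runs with no
external data.

Emulated observables: absolute pLC20 fractions; pMLCP, pHSP27, pCofilin
and G-actin levels normalized to the 10 mmHg control; and per-condition
pressure-outer-diameter curves (two vessel groups with distinct load-free
radii).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CHEMICAL_OBSERVABLES, OBSERVABLE_NODE, ObservableTable
from .errors import DomainError
from .signalling import Intervention, steady_state
from .solver import ModelBundle, SolverOptions, pressure_sweep

__all__ = ["SynthSpec", "generate_chemical_observables", "generate_pd_curves"]

#: load-free outer radii (cm) of the two vessel groups of the source protocol
DEFAULT_GROUPS: Dict[str, float] = {"group1": 0.0110, "group2": 0.0126}

DEFAULT_CONDITIONS = ("control", "ca_free", "h1152_0.3", "h1152_0.5", "gf_3")


def _default_pressures() -> np.ndarray:
    return np.arange(10.0, 121.0, 20.0)


@dataclass
class SynthSpec:
    """Recipe for one synthetic data set.

    ``noise_frac`` is the per-observable noise SD expressed as a fraction
    of that observable's dynamic range across the noiseless table (0.05
    emulates tight, well-powered recordings); ``n_replicates`` vessels are
    drawn per point and summarized as mean and sample SD.  ``seed`` is
    mandatory so every emitted file is reproducible bit-for-bit.
    """

    bundle: ModelBundle
    seed: int
    pressures: np.ndarray = field(default_factory=_default_pressures)
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    observables: Sequence[str] = CHEMICAL_OBSERVABLES
    noise_frac: float = 0.05
    n_replicates: int = 5
    groups: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    solver_opts: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if self.noise_frac < 0:
            raise DomainError("noise_frac must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if self.seed is None:
            raise DomainError("a seed is mandatory for synthetic data")


def _noisy_rows(truth: pd.DataFrame, spec: SynthSpec, rng,
                lower, upper) -> pd.DataFrame:
    """Replicate means/SDs from noiseless truth values, truncated to range."""
    out = truth.copy()
    means = np.empty(len(truth))
    sds = np.empty(len(truth))
    for kind, sub in truth.groupby("observable"):
        vals = sub["truth"].to_numpy()
        dyn = vals.max() - vals.min()
        sd_point = spec.noise_frac * (dyn if dyn > 0 else 1.0)
        for idx, v in zip(sub.index, vals):
            if spec.noise_frac == 0:
                means[idx], sds[idx] = v, 0.0
            else:
                reps = v + rng.normal(0.0, sd_point, size=spec.n_replicates)
                reps = np.clip(reps, lower.get(kind, -np.inf),
                               upper.get(kind, np.inf))
                means[idx] = reps.mean()
                sds[idx] = reps.std(ddof=1)
    out["mean"] = means
    out["sd"] = sds
    return out.drop(columns="truth")


def generate_chemical_observables(spec: SynthSpec) -> ObservableTable:
    """Synthetic phosphorylation/content observables per condition/pressure.

    pLC20 is emitted as an absolute fraction; the other kinds are divided
    by the noiseless control value at 10 mmHg before noise is applied, so
    the zero-noise 10 mmHg control rows equal 1 exactly.
    """
    net = spec.bundle.network
    rows = []
    ref = {kind: steady_state(net.normalize_pressure(10.0), net)
           [OBSERVABLE_NODE[kind]] for kind in spec.observables}
    for cond in spec.conditions:
        iv = Intervention.preset(cond)
        for P in spec.pressures:
            state = steady_state(net.normalize_pressure(P), net, iv)
            for kind in spec.observables:
                v = state[OBSERVABLE_NODE[kind]]
                if kind == "pLC20":
                    norm = "absolute"
                else:
                    norm = "rel_control_10mmHg"
                    v = v / ref[kind]
                rows.append({"condition": cond, "observable": kind,
                             "pressure_mmHg": float(P), "truth": v,
                             "normalization": norm})
    truth = pd.DataFrame(rows)
    rng = np.random.default_rng(spec.seed)
    lower = {kind: 0.0 for kind in spec.observables}
    upper = {"pLC20": 1.0}
    return ObservableTable(_noisy_rows(truth, spec, rng, lower, upper))


def generate_pd_curves(spec: SynthSpec,
                       conditions: Optional[Sequence[str]] = None) -> ObservableTable:
    """Synthetic pressure-outer-diameter curves per condition and group.

    Runs a full chemo-mechanical sweep per (condition, vessel group); the
    emitted table carries the group name and its load-free radius in extra
    ``group`` / ``R_o_prime_cm`` columns.
    """
    conditions = list(conditions if conditions is not None else spec.conditions)
    rows = []
    for group, Ro in spec.groups.items():
        bundle = spec.bundle.with_geometry(R_o_prime=Ro)
        for cond in conditions:
            sweep = pressure_sweep(spec.pressures, Intervention.preset(cond),
                                   bundle, spec.solver_opts)
            for res in sweep:
                rows.append({"condition": cond, "observable": "Do",
                             "pressure_mmHg": res.pressure_mmHg,
                             "truth": res.D_o, "normalization": "absolute",
                             "group": group, "R_o_prime_cm": Ro})
    truth = pd.DataFrame(rows)
    rng = np.random.default_rng(spec.seed)
    return ObservableTable(_noisy_rows(truth, spec, rng,
                                       lower={"Do": 0.0}, upper={}))
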