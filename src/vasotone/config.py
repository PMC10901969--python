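"""Parameter-file loading, validation and run manifests.

Human-edited configuration is YAML with four sections (``chemical``,
``mechanical``, ``geometry``, ``passive``); a shipped default file carries
the published fitted parameter set.  Validation distinguishes hard errors
(schema violations, bound breaches such as ``B0 >= 1``) from warnings
(values outside the ranges that were enforced during the original fitting).
"""

from __future__ import annotations

import importlib.resources as resources
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import scipy
import yaml

from . import __version__
from .contractile import ContractileParams
from .errors import ConfigError, DomainError, GeometryError
from .signalling import EDGE_LABELS, LogisticEdge, NetworkParams
from .solver import ModelBundle
from .vessel_wall import PassiveParams, WallGeometry

__all__ = ["load_params", "default_params", "validate_params",
           "ValidationReport", "write_manifest"]

_MECH_KEYS = {
    "N_CU": "N_CU", "L_SMC_cm": "L_SMC", "L_m_cm": "L_m",
    "u_PS_cm": "u_PS", "kXB_over_dm_dyne_cm2": "kXB_over_dm",
    "u_fs_opt": "u_fs_opt", "s_f0_cm": "s_f0",
    "k_ACmax_dyne_cm": "k_ACmax", "n_AC": "n_AC", "K_AC": "K_AC",
    "N_CF_cm2": "N_CF", "beta_c": "beta_c",
}
_GEOM_KEYS = {"R_o_prime_cm": "R_o_prime", "h_w": "h_w",
              "lambda_z": "lambda_z", "k_omega": "k_omega"}
_PASSIVE_KEYS = {"c0_dyne_cm2": "c0", "c1_dyne_cm2": "c1",
                 "c2": "c2", "phi_deg": "phi_deg"}


def _default_text() -> str:
    return resources.files("vasotone").joinpath("data/default_params.yaml").read_text()


def _build_bundle(doc: dict) -> ModelBundle:
    try:
        chem = doc["chemical"]
        edges = {lab: LogisticEdge(B0=float(e["B0"]), K=float(e["K"]),
                                   n=float(e["n"]), label=lab)
                 for lab, e in chem["edges"].items()}
        network = NetworkParams(
            edges=edges,
            tau=tuple(float(t) for t in chem.get("tau", (1.0,) * 7)),
            P_max_mmHg=float(chem.get("P_max_mmHg", 150.0)),
            n_XBmax=float(chem.get("n_XBmax", 0.55)))
        mech = {dst: (int if dst == "N_CU" else float)(doc["mechanical"][src])
                for src, dst in _MECH_KEYS.items() if src in doc["mechanical"]}
        geom = {dst: float(doc["geometry"][src])
                for src, dst in _GEOM_KEYS.items() if src in doc["geometry"]}
        passive = {dst: float(doc["passive"][src])
                   for src, dst in _PASSIVE_KEYS.items() if src in doc["passive"]}
        return ModelBundle(network=network,
                           contractile=ContractileParams(**mech),
                           geometry=WallGeometry(**geom),
                           passive=PassiveParams(**passive))
    except (KeyError, TypeError, ValueError, DomainError, GeometryError) as exc:
        raise ConfigError(f"invalid parameter file: {exc}") from exc


def default_params() -> ModelBundle:
    """The shipped fitted parameter set (vessels group 1 geometry)."""
    return _build_bundle(yaml.safe_load(_default_text()))


def load_params(path: str | Path) -> ModelBundle:
    """Load a YAML parameter file; sections fall back to shipped defaults."""
    doc = yaml.safe_load(Path(path).read_text())
    base = yaml.safe_load(_default_text())
    for section in ("chemical", "mechanical", "geometry", "passive"):
        if section in doc:
            if section == "chemical":
                merged = dict(base[section])
                merged.update({k: v for k, v in doc[section].items() if k != "edges"})
                if "edges" in doc[section]:
                    edges = dict(base[section]["edges"])
                    edges.update(doc[section]["edges"])
                    merged["edges"] = edges
                base[section] = merged
            else:
                base[section].update(doc[section])
    return _build_bundle(base)


@dataclass
class ValidationReport:
    """Field-by-field outcome of parameter validation."""

    present: List[str] = field(default_factory=list)
    missing: List[str] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_params(path: Optional[str | Path] = None) -> ValidationReport:
    """Validate a parameter file (or the shipped defaults).

    Hard bounds (``0 <= B0 < 1``, ``K, n > 0``, positive lengths and
    stiffnesses) are errors; the ranges enforced during fitting (e.g.
    ``0.13 <= h_w <= 0.40``) produce warnings only.
    """
    report = ValidationReport()
    doc = yaml.safe_load(Path(path).read_text() if path else _default_text())
    base = yaml.safe_load(_default_text())

    for section, keys in (("chemical", ["P_max_mmHg", "n_XBmax", "tau"]),
                          ("mechanical", list(_MECH_KEYS)),
                          ("geometry", list(_GEOM_KEYS)),
                          ("passive", list(_PASSIVE_KEYS))):
        src = doc.get(section, {})
        for key in keys:
            (report.present if key in src else report.missing).append(f"{section}.{key}")
    for lab in EDGE_LABELS:
        tgt = doc.get("chemical", {}).get("edges", {})
        (report.present if lab in tgt else report.missing).append(f"chemical.edges.{lab}")

    # merge with defaults, then try to build (hard-bound check)
    merged = dict(base)
    for section in merged:
        if section in doc:
            if section == "chemical":
                merged[section] = dict(base[section])
                merged[section].update({k: v for k, v in doc[section].items()
                                        if k != "edges"})
                edges = dict(base[section]["edges"])
                edges.update(doc[section].get("edges", {}))
                merged[section]["edges"] = edges
            else:
                merged[section] = {**base[section], **doc[section]}
    try:
        bundle = _build_bundle(merged)
    except ConfigError as exc:
        report.errors.append(str(exc))
        return report

    report.warnings.extend(bundle.geometry.fit_range_warnings())
    return report


def write_manifest(path: str | Path, *, command: str, seed=None,
                   params: Optional[ModelBundle] = None, extra: Dict = None):
    """Write a JSON sidecar recording everything needed to regenerate a file."""
    manifest = {
        "command": command,
        "seed": seed,
        "vasotone_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "python_version": platform.python_version(),
    }
    if params is not None:
        manifest["parameters"] = {
            "chemical": {
                "P_max_mmHg": params.network.P_max_mmHg,
                "n_XBmax": params.network.n_XBmax,
                "tau": list(params.network.tau),
                "edges": {lab: {"B0": e.B0, "K": e.K, "n": e.n}
                          for lab, e in sorted(params.network.edges.items())},
            },
            "mechanical": asdict(params.contractile),
            "geometry": asdict(params.geometry),
            "passive": asdict(params.passive),
        }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
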