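"""Deterministic table/report writers shared by the CLI and scripts.

Sweep tables are CSV with a fixed column order and ``%.10g`` float
formatting; every emitted file gets a JSON manifest sidecar
(``<name>.manifest.json``) recording parameters, seeds and library
versions, so two identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .config import write_manifest
from .errors import DomainError
from .solver import EquilibriumResult, ModelBundle

__all__ = ["sweep_to_frame", "write_sweep_csv", "write_fit_report"]

SWEEP_COLUMNS = [
    "pressure_mmHg", "D_o_cm", "r_i_cm", "u_fs_bar", "lambda_theta_mean",
    "n_XB", "xi0", "xi1", "xi2", "xi3", "xi4", "xi5", "xi6", "xi7",
    "k_tCU", "k_AC", "condition",
]


def sweep_to_frame(results: List[EquilibriumResult]) -> pd.DataFrame:
    """Flatten equilibrium results into the canonical sweep table."""
    if not results:
        raise DomainError("empty sweep")
    rows = []
    for r in results:
        row = {"pressure_mmHg": r.pressure_mmHg, "D_o_cm": r.D_o,
               "r_i_cm": r.r_i, "u_fs_bar": r.u_fs_bar,
               "lambda_theta_mean": r.lambda_theta_mean, "n_XB": r.n_XB}
        row.update(r.chem.state.as_dict())
        row["xi7"] = r.chem.xi7
        row.update({"k_tCU": r.k_tCU, "k_AC": r.k_AC, "condition": r.condition})
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def write_sweep_csv(results: List[EquilibriumResult], path,
                    params: Optional[ModelBundle] = None,
                    command: str = "", seed=None) -> pd.DataFrame:
    """Write a sweep CSV plus its manifest sidecar; returns the frame."""
    frame = sweep_to_frame(results)
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.10g")
    write_manifest(path.with_suffix(path.suffix + ".manifest.json"),
                   command=command, seed=seed, params=params)
    return frame


def write_fit_report(fit_result, path, command: str = "") -> Dict:
    """Serialize a FitResult as JSON (with manifest sidecar)."""
    path = Path(path)
    report = {
        "stage": fit_result.stage,
        "best_params": fit_result.best_params,
        "L_data": fit_result.L_data,
        "L_con": fit_result.L_con,
        "L_con_sum": fit_result.L_con_sum,
        "L_tot": fit_result.L_tot,
        "best_seed": fit_result.best_seed,
        "n_iter": fit_result.n_iter,
        "seed_results": fit_result.seed_results,
    }
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    write_manifest(path.with_suffix(path.suffix + ".manifest.json"),
                   command=command, seed=list(r["seed"] for r in
                                              fit_result.seed_results),
                   params=fit_result.bundle)
    return report
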