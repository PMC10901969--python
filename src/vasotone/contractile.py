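"""Cell-scale contractile machinery: filament sliding, stiffnesses, forces.

Contractile units (CUs) — serially arranged overlapping actin/myosin
filaments — sit in series with the passive F-actin cortex.  Phosphorylated
cross-bridges both stiffen the CU chain and generate a driving force through
the power-stroke; the relative filament sliding ``u_fs_bar`` evolves until
the elastic reaction force of the CU-cortex assembly balances the
cross-bridge driving force.  All quantities are CGS (cm, dyne).

Latched (dephosphorylated, attached) cross-bridges are assumed to carry no
force, so no four-state cross-bridge kinetics is needed; only the
phosphorylated fraction ``n_XB`` enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "ContractileParams",
    "MachineState",
    "actin_cortex_stiffness",
    "xb_stiffness",
    "filament_overlap",
    "cu_stiffness",
    "series_stiffness",
    "active_force",
    "driving_force",
    "sliding_rate",
    "active_stress",
    "active_energy",
]


@dataclass(frozen=True)
class ContractileParams:
    """Mechanical parameters of the contractile apparatus (CGS units).

    Defaults are the fitted/literature values for rat middle cerebral
    artery SMCs.  ``N_CU`` (contractile units in series per fibre) is an
    order-of-magnitude literature value exposed for configuration; it is
    recorded in every output manifest.

    Attributes
    ----------
    N_CU : int
        Contractile units in series per contractile fibre.
    L_SMC : float
        Reference length of the CU chain (cm).
    L_m : float
        Average myosin filament length (cm).
    u_PS : float
        Average power-stroke elongation (cm).
    kXB_over_dm : float
        Cross-bridge elastic stiffness per myosin monomer spacing
        (dyne cm^-2); only this ratio is identifiable.
    u_fs_opt : float
        Normalized filament sliding at which thick/thin overlap peaks.
    s_f0 : float
        Overlap Gaussian scaling length (cm); the overlap width in
        normalized-sliding units is ``s_f0 / L_m``.
    k_ACmax : float
        Actin-cortex stiffness scale (dyne cm^-1).
    n_AC, K_AC : float
        Hill coefficients of cortex activation by F-actin content.
    N_CF : float
        Surface density of contractile fibres (cm^-2).
    beta_c : float
        Filament-sliding kinetic constant (1 for steady-state studies).
    """

    N_CU: int = 10
    L_SMC: float = 0.01
    L_m: float = 3.0e-5
    u_PS: float = 1.424e-6
    kXB_over_dm: float = 8.166777e6
    u_fs_opt: float = 1.490e-2
    s_f0: float = 5.870e-7
    k_ACmax: float = 10.04
    n_AC: float = 4.156
    K_AC: float = 10.201
    N_CF: float = 2.44e10
    beta_c: float = 1.0

    def __post_init__(self):
        positive = ["L_SMC", "L_m", "u_PS", "kXB_over_dm", "s_f0",
                    "k_ACmax", "n_AC", "K_AC", "N_CF", "beta_c"]
        for name in positive:
            if not (getattr(self, name) > 0):
                raise DomainError(f"ContractileParams.{name} must be > 0")
        if self.N_CU < 1:
            raise DomainError("N_CU must be >= 1")


@dataclass(frozen=True)
class MachineState:
    """Normalized filament sliding and circumferential stretch of the fibre."""

    u_fs_bar: float
    lambda_theta: float

    def __post_init__(self):
        if not (self.lambda_theta > 0):
            raise DomainError("lambda_theta must be positive")


def actin_cortex_stiffness(xi7: float, p: ContractileParams) -> float:
    """Cortex stiffness from the F-actin level: Hill curve in ``xi7``.

    ``k_AC = k_ACmax xi7^n_AC / (xi7^n_AC + K_AC^n_AC)``; zero at xi7 = 0.
    """
    if not (0.0 <= xi7 <= 1.0):
        raise DomainError(f"xi7={xi7} outside [0, 1]")
    if xi7 == 0.0:
        return 0.0
    t = xi7 ** p.n_AC
    return p.k_ACmax * t / (t + p.K_AC ** p.n_AC)


def xb_stiffness(n_XB: float, p: ContractileParams) -> float:
    """Total stiffness of attached cross-bridges in half a CU.

    ``k_tCB = L_m n_XB (k_XB / delta_m)``; linear in the phosphorylated
    fraction.
    """
    if not (0.0 <= n_XB <= 1.0):
        raise DomainError(f"n_XB={n_XB} outside [0, 1]")
    return p.L_m * n_XB * p.kXB_over_dm


def filament_overlap(u_fs_bar: float, p: ContractileParams) -> float:
    """Normalized thick/thin filament overlap, Gaussian in the sliding.

    ``L_fo_bar = exp[-(u_fs_bar - u_fs_opt)^2 / (2 (s_f0/L_m)^2)]``,
    peaking at 1 for sliding equal to the optimum.
    """
    width = p.s_f0 / p.L_m
    z = (u_fs_bar - p.u_fs_opt) / width
    return math.exp(-0.5 * z * z)


def cu_stiffness(k_tCB: float, L_fo_bar: float, p: ContractileParams) -> float:
    """Stiffness of the CU chain: ``k_tCU = L_fo_bar k_tCB / (2 N_CU)``."""
    if k_tCB < 0 or not (0.0 <= L_fo_bar <= 1.0):
        raise DomainError("k_tCB must be >= 0 and L_fo_bar in [0, 1]")
    return L_fo_bar * k_tCB / (2.0 * p.N_CU)


def series_stiffness(k_tCU: float, k_AC: float) -> float:
    """Composite stiffness of N_CU units in series with cortex elements.

    ``k_tCU k_AC / (2 k_tCU + k_AC)``; the 0/0 limit of vanishing machinery
    is defined as 0.
    """
    denom = 2.0 * k_tCU + k_AC
    if denom == 0.0:
        return 0.0
    return k_tCU * k_AC / denom


def active_force(lambda_theta: float, u_fs_bar: float,
                 k_tCU: float, k_AC: float, p: ContractileParams) -> float:
    """Elastic reaction force of the CU-cortex assembly (dyne).

    ``F_a = (lambda_theta - 1 - 2 N_CU u_fs_bar) * series_stiffness``:
    the stretch not absorbed by filament sliding loads the series springs.
    """
    disp = lambda_theta - 1.0 - 2.0 * p.N_CU * u_fs_bar
    return disp * series_stiffness(k_tCU, k_AC)


def driving_force(n_XB: float, L_fo_bar: float, p: ContractileParams) -> float:
    """Power-stroke driving force of the cycling cross-bridges (dyne).

    ``F_c = L_fo_bar L_m (k_XB/delta_m) n_XB u_PS``.
    """
    if not (0.0 <= n_XB <= 1.0):
        raise DomainError(f"n_XB={n_XB} outside [0, 1]")
    return L_fo_bar * p.L_m * p.kXB_over_dm * n_XB * p.u_PS


def sliding_rate(F_a: float, F_c: float, p: ContractileParams) -> float:
    """Filament sliding kinetics: ``d u_fs_bar / dt = beta_c (F_a - F_c)``."""
    return p.beta_c * (F_a - F_c)


def active_stress(F_a: float, p: ContractileParams) -> float:
    """Active first Piola-Kirchhoff stress of the tissue: ``P_a = N_CF F_a``."""
    return p.N_CF * F_a


def active_energy(lambda_theta: float, u_fs_bar: float,
                  k_tCU: float, k_AC: float, p: ContractileParams) -> float:
    """Active strain-energy density (dyne cm^-2).

    ``Psi_a = (N_CF / 2) * series_stiffness * (lambda_theta - 1
    - 2 N_CU u_fs_bar)^2``; its derivative in ``lambda_theta`` (at frozen
    stiffnesses and sliding) is the active stress ``P_a``.
    """
    disp = lambda_theta - 1.0 - 2.0 * p.N_CU * u_fs_bar
    return 0.5 * p.N_CF * series_stiffness(k_tCU, k_AC) * disp * disp


def machinery_stiffnesses(n_XB: float, xi7: float, u_fs_bar: float,
                          p: ContractileParams):
    """Convenience: (k_tCU, k_AC, L_fo_bar) for a chemical/mechanical state."""
    L_fo = filament_overlap(u_fs_bar, p)
    k_tCU = cu_stiffness(xb_stiffness(n_XB, p), L_fo, p)
    k_AC = actin_cortex_stiffness(xi7, p)
    return k_tCU, k_AC, L_fo
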