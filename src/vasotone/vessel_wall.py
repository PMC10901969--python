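"""Tissue-scale equilibrium of the incompressible thick-walled artery.

The wall is an axisymmetric, homogeneous, incompressible hyperelastic tube
held at fixed axial stretch ``lambda_z`` with a scalar circumferential
pre-stretch ``k_omega`` standing in for residual strain.  The passive
response is neo-Hookean plus an exponential fibre term aligned with the
circumferential direction (fibres carry no compression); the active
response is the contractile-machinery strain energy.  Radial momentum
balance yields luminal pressure as a wall-thickness integral over the
reference radius, evaluated with composite Simpson quadrature.

Internal units are CGS; pressures cross the API boundary in mmHg
(1 mmHg = 1333.22 dyne cm^-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from . import contractile as ct
from .errors import DomainError, GeometryError

__all__ = [
    "MMHG_TO_DYNE_CM2",
    "WallGeometry",
    "PassiveParams",
    "derive_reference_geometry",
    "map_radius",
    "stretches",
    "passive_energy",
    "passive_stress_terms",
    "luminal_pressure",
    "mean_circumferential_stretch",
    "outer_diameter",
]

MMHG_TO_DYNE_CM2 = 1333.22

#: fitted-range warnings for geometry factors (soft bounds; hard ones are >0)
GEOMETRY_FIT_RANGES = {"h_w": (0.13, 0.40), "lambda_z": (1.0, 1.5),
                       "k_omega": (1.0, 1.5)}


def derive_reference_geometry(R_o_prime: float, h_w: float):
    """Reference inner radius and thickness from load-free outer radius.

    The thickness-to-medium-radius ratio uses the mid-wall radius, so ``H``
    solves ``h_w = H / (R_o_prime - H/2)``, giving
    ``H = h_w R_o_prime / (1 + h_w/2)`` and ``R_i = R_o_prime - H``.
    """
    if not (0.0 < h_w < 2.0):
        raise GeometryError(f"h_w={h_w} outside (0, 2)")
    if not (R_o_prime > 0.0):
        raise GeometryError("R_o_prime must be positive")
    H = h_w * R_o_prime / (1.0 + 0.5 * h_w)
    R_i = R_o_prime - H
    if R_i <= 0:
        raise GeometryError("derived inner radius is non-positive")
    return R_i, H


@dataclass(frozen=True)
class WallGeometry:
    """Load-free / reference geometry and kinematic factors of the wall."""

    R_o_prime: float = 0.0110
    h_w: float = 0.367
    lambda_z: float = 1.364
    k_omega: float = 1.373

    def __post_init__(self):
        derive_reference_geometry(self.R_o_prime, self.h_w)  # validates
        if not (self.lambda_z > 0 and self.k_omega > 0):
            raise GeometryError("lambda_z and k_omega must be positive")

    @property
    def R_i(self) -> float:
        return derive_reference_geometry(self.R_o_prime, self.h_w)[0]

    @property
    def H(self) -> float:
        return derive_reference_geometry(self.R_o_prime, self.h_w)[1]

    def fit_range_warnings(self):
        """Geometry factors outside the ranges enforced during fitting."""
        out = []
        for name, (lo, hi) in GEOMETRY_FIT_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                out.append(f"{name}={v} outside fitted range [{lo}, {hi}]")
        return out


@dataclass(frozen=True)
class PassiveParams:
    """Constitutive parameters of the passive wall (CGS).

    ``c0`` scales the isotropic neo-Hookean term, ``c1``/``c2`` the
    exponential collagen-fibre term, ``phi_deg`` the fibre angle from the
    circumferential direction (0 for this vessel type).
    """

    c0: float = 9.1633e4
    c1: float = 3.15e4
    c2: float = 0.646
    phi_deg: float = 0.0

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0:
            raise DomainError("c0 and c1 must be >= 0")
        if not (self.c2 > 0):
            raise DomainError("c2 must be > 0")


def map_radius(R, r_i: float, g: WallGeometry):
    """Incompressible mapping of reference radius R to deformed radius r.

    ``r = sqrt((R^2 - R_i^2) / (k_omega lambda_z) + r_i^2)``; equals ``r_i``
    at the inner surface and preserves wall volume.
    """
    if r_i <= 0:
        raise GeometryError("r_i must be positive")
    R = np.asarray(R, float)
    radicand = (R * R - _Ri_sq(g)) / (g.k_omega * g.lambda_z) + r_i * r_i
    if np.any(radicand <= 0):
        raise GeometryError("deformed radius undefined (negative radicand); "
                            "the wall would self-intersect")
    r = np.sqrt(radicand)
    return float(r) if np.ndim(r) == 0 else r


def _Ri_sq(g: WallGeometry) -> float:
    R_i = g.R_i
    return R_i * R_i


def stretches(R, r, g: WallGeometry):
    """Circumferential and radial stretches at a wall point.

    ``lambda_theta = k_omega r / R`` and ``lambda_r = R / (r k_omega
    lambda_z)``; by construction ``lambda_r lambda_theta lambda_z = 1``.
    """
    R = np.asarray(R, float)
    r = np.asarray(r, float)
    lam_theta = g.k_omega * r / R
    lam_r = R / (r * g.k_omega * g.lambda_z)
    if np.ndim(lam_theta) == 0:
        return float(lam_theta), float(lam_r)
    return lam_theta, lam_r


def _aniso_terms(lam_theta, lam_z, p: PassiveParams):
    """(I4, fibre stress factor 2 c1 (I4-1) exp[c2 (I4-1)^2]), tension only."""
    phi = math.radians(p.phi_deg)
    cos2, sin2 = math.cos(phi) ** 2, math.sin(phi) ** 2
    I4 = lam_theta * lam_theta * cos2 + lam_z * lam_z * sin2
    q = np.maximum(I4 - 1.0, 0.0)           # fibres carry no compression
    factor = 2.0 * p.c1 * q * np.exp(p.c2 * q * q)
    return I4, factor, cos2


def passive_energy(lam_r, lam_theta, lam_z, p: PassiveParams):
    """Passive strain-energy density (dyne cm^-2)."""
    I1 = lam_r ** 2 + lam_theta ** 2 + lam_z ** 2
    I4, _, _ = _aniso_terms(lam_theta, lam_z, p)
    q = np.maximum(I4 - 1.0, 0.0)
    return p.c0 * (I1 - 3.0) + p.c1 / (2.0 * p.c2) * np.expm1(p.c2 * q * q)


def passive_stress_terms(lam_r, lam_theta, lam_z, p: PassiveParams):
    """``(lambda_theta dPsi_p/dlambda_theta, lambda_r dPsi_p/dlambda_r)``.

    Analytic derivatives of the passive energy; the anisotropic part and its
    derivative vanish when the fibre invariant I4 < 1.
    """
    lam_r = np.asarray(lam_r, float)
    lam_theta = np.asarray(lam_theta, float)
    _, fibre, cos2 = _aniso_terms(lam_theta, lam_z, p)
    term_theta = 2.0 * p.c0 * lam_theta ** 2 + fibre * lam_theta ** 2 * cos2
    term_r = 2.0 * p.c0 * lam_r ** 2
    if np.ndim(term_theta) == 0 and np.ndim(term_r) == 0:
        return float(term_theta), float(term_r)
    return term_theta, term_r


def _wall_grid(g: WallGeometry, n_nodes: int):
    if n_nodes < 3 or n_nodes % 2 == 0:
        raise DomainError("Simpson quadrature needs an odd node count >= 3")
    R_i = g.R_i
    return np.linspace(R_i, R_i + g.H, n_nodes)


def luminal_pressure(r_i: float, u_fs_bar: float, n_XB: float, xi7: float,
                     g: WallGeometry, pp: PassiveParams,
                     cp: ct.ContractileParams, n_nodes: int = 81,
                     P_ext_mmHg: float = 0.0) -> float:
    """Luminal pressure (mmHg) supported by the wall at a given state.

    Integrates the radial momentum balance
    ``(lambda_theta dPsi/dlambda_theta - lambda_r dPsi/dlambda_r)
    dR / (lambda_theta lambda_z r)`` across the wall with composite Simpson
    quadrature on ``n_nodes`` reference-radius nodes (the default resolves
    the exponential collagen term to ~1e-7 relative).  The active energy is
    evaluated pointwise in ``lambda_theta(R)`` with the single
    thickness-level filament sliding ``u_fs_bar``.
    """
    Rg = _wall_grid(g, n_nodes)
    r = map_radius(Rg, r_i, g)
    lam_theta, lam_r = stretches(Rg, r, g)

    t_theta, t_r = passive_stress_terms(lam_r, lam_theta, g.lambda_z, pp)

    k_tCU, k_AC, _ = ct.machinery_stiffnesses(n_XB, xi7, u_fs_bar, cp)
    comp = ct.series_stiffness(k_tCU, k_AC)
    disp = lam_theta - 1.0 - 2.0 * cp.N_CU * u_fs_bar
    t_theta = t_theta + lam_theta * cp.N_CF * comp * disp

    integrand = (t_theta - t_r) / (lam_theta * g.lambda_z * r)
    if not np.all(np.isfinite(integrand)):
        bad = Rg[~np.isfinite(integrand)]
        raise SolverIntegrandError(bad)
    P_dyn = simpson(integrand, x=Rg)
    return P_ext_mmHg + P_dyn / MMHG_TO_DYNE_CM2


class SolverIntegrandError(DomainError):
    def __init__(self, bad_radii):
        super().__init__(f"non-finite wall integrand at reference radii {bad_radii}")
        self.bad_radii = bad_radii


def mean_circumferential_stretch(r_i: float, g: WallGeometry,
                                 n_nodes: int = 81) -> float:
    """Equal-weight mean of lambda_theta over the Simpson grid nodes."""
    Rg = _wall_grid(g, n_nodes)
    r = map_radius(Rg, r_i, g)
    lam_theta, _ = stretches(Rg, r, g)
    return float(np.mean(lam_theta))


def outer_diameter(r_i: float, g: WallGeometry) -> float:
    """Deformed outer diameter ``D_o = 2 r(R_i + H)`` (cm)."""
    return 2.0 * map_radius(g.R_i + g.H, r_i, g)
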