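"""Viscoelastic capped-shell model for AFM force-relaxation on epithelial cells.

A confluent cell is modeled as a liquid-filled capped cylinder: a spherical
apical cap of base radius ``R1`` and contact angle ``phi`` sitting on a
fixed cylindrical footprint.  A conical AFM tip (half-angle ``vartheta``)
indents the apex at constant height while the enclosed volume stays fixed;
the cap deforms into a cone-frustum contact region plus a free spherical
cap through the original base circle.  The force on the tip is carried by
the in-plane tension of the shell,

    F = 2π T(t) [ R1² (R1 sin φ + r1 sin θ) / (R1² − r1²) − R1 sin φ ],

with ``r1`` the cone contact radius and ``θ = 90° − ϑ``.  Viscoelasticity
enters through a power-law (soft glassy) area compressibility modulus,

    T(t) = T0 + K_A⁰ (t/t0)^(−β) · ε,

where ``ε`` is the relative apical area dilation imposed by the
indentation, ``T0`` the prestress (resting tension of cortex plus
membrane), and ``β`` the fluidity exponent (0 = elastic solid,
1 = Newtonian fluid).  Fitting F(t) over the dwell yields (T0, K_A⁰, β).
Membrane tension is obtained separately from the tether rupture force as
T_t = F_t² / (8π²κ).

Units: lengths µm, times s, tensions mN/m, forces N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import GeometryError, ShapeSolverError

__all__ = [
    "ShellGeometry",
    "MechParams",
    "RelaxationCurve",
    "ShapeSolution",
    "MechFit",
    "GEOMETRY_PRESETS",
    "force_from_tension",
    "solve_shape",
    "tension_at_time",
    "forward_relaxation",
    "fit_relaxation",
    "tether_tension",
]

_MN_PER_M_TO_N_PER_M = 1e-3
_UM_TO_M = 1e-6


@dataclass(frozen=True)
class ShellGeometry:
    """Undeformed apical cap geometry and indenter angle.

    ``R1_um`` is the radius at the base of the spherical cap, ``phi_deg``
    its contact angle with the base plane, and ``indenter_half_angle_deg``
    the cone half-angle ϑ of the tip (MLCT-C nominal side angle 17.5° by
    default); ``theta_deg`` = 90° − ϑ.
    """

    R1_um: float
    phi_deg: float
    indenter_half_angle_deg: float = 17.5

    def __post_init__(self) -> None:
        if self.R1_um <= 0:
            raise GeometryError("R1 must be positive")
        if not 0 < self.phi_deg < 90:
            raise GeometryError("phi must lie in (0°, 90°)")
        if not 0 < self.indenter_half_angle_deg < 90:
            raise GeometryError("indenter half-angle must lie in (0°, 90°)")

    @property
    def theta_deg(self) -> float:
        return 90.0 - self.indenter_half_angle_deg

    @property
    def phi_rad(self) -> float:
        return np.deg2rad(self.phi_deg)

    @property
    def theta_rad(self) -> float:
        return np.deg2rad(self.theta_deg)

    @property
    def sphere_radius_um(self) -> float:
        """Radius of the undeformed cap sphere, R1/sin φ."""
        return self.R1_um / np.sin(self.phi_rad)

    @property
    def cap_height_um(self) -> float:
        """Undeformed cap height h0 = R1 (1 − cos φ)/sin φ."""
        return self.R1_um * (1 - np.cos(self.phi_rad)) / np.sin(self.phi_rad)

    @property
    def cap_volume_um3(self) -> float:
        h = self.cap_height_um
        return np.pi * h * h * (3.0 * self.sphere_radius_um - h) / 3.0

    @property
    def cap_area_um2(self) -> float:
        return 2.0 * np.pi * self.sphere_radius_um * self.cap_height_um


#: Cell-line presets for the apical cap (radius at base, contact angle).
GEOMETRY_PRESETS: dict[str, ShellGeometry] = {
    "wt": ShellGeometry(10.0, 10.0),
    "ko": ShellGeometry(8.0, 20.0),
    "dkd-small": ShellGeometry(5.0, 31.0),
    "dkd-large": ShellGeometry(8.0, 2.0),
}


@dataclass
class MechParams:
    """Power-law shell rheology: T(t) = T0 + KA0 (t/t0)^(−β) ε."""

    T0_mN_per_m: float
    KA0_mN_per_m: float
    beta: float
    t0_s: float = 1.0

    def __post_init__(self) -> None:
        if self.T0_mN_per_m < 0 or self.KA0_mN_per_m < 0:
            raise ValueError("T0 and KA0 must be nonnegative")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.t0_s <= 0:
            raise ValueError("t0 must be positive")


@dataclass
class RelaxationCurve:
    """Force versus time during the constant-height dwell segment."""

    t_s: np.ndarray
    F_N: np.ndarray
    delta_um: float
    approach_speed_um_per_s: float = 2.0
    max_force_nN: float = 1.0
    dwell_s: float = 0.5

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.F_N = np.asarray(self.F_N, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.shape != self.F_N.shape:
            raise ValueError("t_s and F_N must be 1-D arrays of equal length")
        if np.any(self.t_s <= 0) or np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if not np.all(np.isfinite(self.F_N)):
            raise ValueError("forces must be finite")


@dataclass
class ShapeSolution:
    """Constant-volume deformed shape at a given indentation depth."""

    r1_um: float
    phi_eff_deg: float
    area_strain: float
    volume_residual: float
    rho_um: float  # radius of the deformed free spherical cap
    area_strain_free_cap: float = 0.0


@dataclass
class MechFit:
    """Result of fitting (T0, KA0, beta) to a relaxation curve."""

    params: MechParams | None
    residual_rms: float
    converged: bool
    collinear: bool = False
    Tt_mN_per_m: float | None = None
    n_points: int = 0


# ---------------------------------------------------------------------------
# forward model


def geometric_gain(geom: ShellGeometry, r1_um: float, phi_deg: float | None = None) -> float:
    """The length-valued bracket G(r1) with F = 2π T G; in µm.

    Vanishes identically at r1 = 0 and diverges as r1 → R1.
    """
    if not 0 <= r1_um < geom.R1_um:
        raise GeometryError("contact radius must satisfy 0 <= r1 < R1")
    R1 = geom.R1_um
    sphi = np.sin(np.deg2rad(phi_deg)) if phi_deg is not None else np.sin(geom.phi_rad)
    sth = np.sin(geom.theta_rad)
    # algebraically identical to R1²(R1 sinφ + r1 sinθ)/(R1² − r1²) − R1 sinφ
    # but exact at r1 = 0 in floating point
    return float(
        R1 * r1_um * (r1_um * sphi + R1 * sth) / (R1 * R1 - r1_um * r1_um)
    )


def force_from_tension(
    geom: ShellGeometry,
    r1_um: float,
    T_mN_per_m: float,
    phi_deg: float | None = None,
) -> float:
    """Tip force (N) carried by shell tension T at contact radius r1.

    F = 2π T [R1²(R1 sin φ + r1 sin θ)/(R1² − r1²) − R1 sin φ]; exactly 0
    at r1 = 0 and linear in T.  ``phi_deg`` overrides the geometry's
    contact angle (e.g. with the deformed angle from :func:`solve_shape`).
    """
    g_m = geometric_gain(geom, r1_um, phi_deg) * _UM_TO_M
    return 2.0 * np.pi * T_mN_per_m * _MN_PER_M_TO_N_PER_M * g_m


# ---------------------------------------------------------------------------
# constant-volume shape solution


def _deformed_state(geom: ShellGeometry, delta_um: float, r1: float):
    """Geometry of the deformed surface at contact radius r1.

    Returns (volume, rho, z_c, z1) of the composite surface: cone frustum
    from the apex (depth delta below the undeformed apex) out to r1, free
    spherical cap of radius rho from r1 to the fixed base circle R1.
    """
    R1 = geom.R1_um
    tan_theta = np.tan(geom.theta_rad)
    z_apex = geom.cap_height_um - delta_um
    z1 = z_apex + r1 * tan_theta  # height of the contact circle
    if z1 <= 0:
        return None
    rem = R1 * R1 - r1 * r1
    if rem <= 0 or z1 * z1 > rem:
        return None  # no sphere through base and contact circle
    # sphere through (R1, 0) and (r1, z1), center on the axis at z_c < z1:
    # sqrt(rho^2 - r1^2) - sqrt(rho^2 - R1^2) = z1  (closed form)
    sA = 0.5 * (z1 + rem / z1)  # sqrt(rho^2 - r1^2)
    rho2 = r1 * r1 + sA * sA
    rho = np.sqrt(rho2)
    z_c = z1 - sA
    sB = np.sqrt(max(rho2 - R1 * R1, 0.0))  # = -z_c
    # volume of revolution between the base plane and the surface
    v_cone = np.pi * r1 * r1 * z_apex + (2.0 * np.pi / 3.0) * tan_theta * r1**3
    v_cap = np.pi * z_c * (R1 * R1 - r1 * r1) + (2.0 * np.pi / 3.0) * (
        sA**3 - sB**3
    )
    return v_cone + v_cap, rho, z_c, z1


def solve_shape(geom: ShellGeometry, delta_um: float, tol: float = 1e-12) -> ShapeSolution:
    """Deformed cell shape at indentation depth ``delta_um``, constant volume.

    Solves for the cone contact radius ``r1`` such that the enclosed
    volume of the composite surface (cone frustum + free spherical cap
    through the fixed base circle) equals the undeformed cap volume; the
    free-cap curvature follows in closed form.  Returns the relative
    apical area dilation of the total surface (contact cone + free cap)
    and, separately, of the free cap alone.
    """
    h0 = geom.cap_height_um
    if delta_um < 0 or delta_um >= h0:
        raise ShapeSolverError(
            f"indentation {delta_um} µm outside solvable range [0, {h0:.4g}) µm"
        )
    if delta_um == 0:
        return ShapeSolution(0.0, geom.phi_deg, 0.0, 0.0, geom.sphere_radius_um, 0.0)
    V0 = geom.cap_volume_um3
    A0 = geom.cap_area_um2

    def vol_err(r1: float) -> float:
        st = _deformed_state(geom, delta_um, r1)
        if st is None:
            return np.inf
        return st[0] - V0

    # bracket: V(0+) < V0 (apex pushed down, no cone yet); V grows with r1
    R1 = geom.R1_um
    lo = 1e-9 * R1
    # upper bound: largest r1 with a valid sphere (z1 <= sqrt(R1^2 - r1^2))
    hi = R1 * (1.0 - 1e-12)
    if not np.isfinite(vol_err(hi)):
        tan_theta = np.tan(geom.theta_rad)
        z_apex = h0 - delta_um

        def edge(r1: float) -> float:
            return (z_apex + r1 * tan_theta) ** 2 - (R1 * R1 - r1 * r1)

        hi = brentq(edge, lo, R1 * (1.0 - 1e-12), xtol=1e-14) * (1.0 - 1e-9)
    f_lo, f_hi = vol_err(lo), vol_err(hi)
    if not (f_lo < 0 <= f_hi):
        raise ShapeSolverError(
            "volume constraint not bracketed: "
            f"V(r1={lo:.3g})-V0={f_lo:.3g}, V(r1={hi:.3g})-V0={f_hi:.3g} µm³"
        )
    r1 = brentq(vol_err, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    vol, rho, z_c, z1 = _deformed_state(geom, delta_um, r1)
    sA = np.sqrt(rho * rho - r1 * r1)
    sB = np.sqrt(max(rho * rho - R1 * R1, 0.0))
    a_cone = np.pi * r1 * r1 / np.sin(np.deg2rad(geom.indenter_half_angle_deg))
    a_cap = 2.0 * np.pi * rho * (sA - sB)
    phi_eff = np.rad2deg(np.arcsin(min(R1 / rho, 1.0)))
    return ShapeSolution(
        r1_um=float(r1),
        phi_eff_deg=float(phi_eff),
        area_strain=float((a_cone + a_cap - A0) / A0),
        volume_residual=float((vol - V0) / V0),
        rho_um=float(rho),
        area_strain_free_cap=float((a_cap - A0) / A0),
    )


# ---------------------------------------------------------------------------
# time dependence


def tension_at_time(
    params: MechParams, area_strain: float, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Shell tension T(t) = T0 + KA0 (t/t0)^(−β) ε, in mN/m."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be positive")
    if area_strain < 0:
        raise ValueError("area strain must be nonnegative")
    T = params.T0_mN_per_m + params.KA0_mN_per_m * (
        t / params.t0_s
    ) ** (-params.beta) * area_strain
    return float(T) if np.isscalar(t_s) else T


def forward_relaxation(
    geom: ShellGeometry,
    params: MechParams,
    delta_um: float,
    times_s: Sequence[float] | np.ndarray,
) -> RelaxationCurve:
    """Forward force-relaxation curve over the constant-height dwell.

    The deformed shape is solved once (the height, hence the shape, is
    held fixed during the dwell) and the force follows the decaying
    tension: monotonically decreasing for β > 0 and KA0 > 0, with the
    long-time limit set by the prestress T0 alone.  The force bracket is
    evaluated with the deformed contact angle φ_eff.
    """
    shape = solve_shape(geom, delta_um)
    t = np.asarray(times_s, dtype=float)
    T = tension_at_time(params, shape.area_strain, t)
    g_m = geometric_gain(geom, shape.r1_um, shape.phi_eff_deg) * _UM_TO_M
    F = 2.0 * np.pi * np.asarray(T) * _MN_PER_M_TO_N_PER_M * g_m
    return RelaxationCurve(t, F, delta_um=delta_um)


# ---------------------------------------------------------------------------
# fitting


def fit_relaxation(
    curve: RelaxationCurve,
    geom: ShellGeometry,
    t0_s: float = 1.0,
    delta_um: float | None = None,
    n_restarts: int = 4,
) -> MechFit:
    """Fit (T0, KA0, β) to a dwell-segment force-relaxation curve.

    Bounded nonlinear least squares (T0, KA0 ≥ 0, β ∈ [0, 1]) on
    F(t) = 2πG·[T0 + KA0 (t/t0)^(−β) ε] with G and ε fixed by the
    constant-volume shape solution at the known indentation depth.
    Initialization matches the curve's endpoints (T0 from the final
    force, KA0 from the initial drop, β = 0.5), plus deterministic
    perturbed restarts; the best converged run is kept.  When the fitted
    β is near 0, T0 and KA0·ε are only jointly identifiable and the fit
    is flagged ``collinear``.
    """
    if curve.t_s.size < 10:
        raise ValueError("need at least 10 dwell samples to fit")
    delta = curve.delta_um if delta_um is None else delta_um
    shape = solve_shape(geom, delta)
    eps = shape.area_strain
    if eps <= 0:
        raise ShapeSolverError("zero area strain: nothing to relax")
    g_m = geometric_gain(geom, shape.r1_um, shape.phi_eff_deg) * _UM_TO_M
    pref = 2.0 * np.pi * g_m * _MN_PER_M_TO_N_PER_M  # F = pref * T[mN/m]
    t = curve.t_s
    F = curve.F_N

    f_scale = float(np.max(np.abs(F)))
    if f_scale == 0:
        raise ValueError("all-zero force curve")

    def model(x: np.ndarray) -> np.ndarray:
        T0, KA0, beta = x
        return pref * (T0 + KA0 * (t / t0_s) ** (-beta) * eps)

    def resid(x: np.ndarray) -> np.ndarray:
        # scaled to O(1) so optimizer tolerances act on relative error
        return (model(x) - F) / f_scale

    T0_init = max(F[-1] / pref, 0.0)
    KA0_init = max((F[0] - F[-1]) / (pref * eps), 1e-6)
    base = np.array([T0_init, KA0_init, 0.5])
    starts = [base]
    for fac_k, b0 in ((0.5, 0.25), (2.0, 0.75), (0.25, 0.5), (4.0, 0.9)):
        starts.append(np.array([max(T0_init, 1e-6), KA0_init * fac_k, b0]))
    if len(starts) > 1 + n_restarts:
        starts = starts[: 1 + n_restarts]
    lb = np.array([0.0, 0.0, 0.0])
    ub = np.array([np.inf, np.inf, 1.0])
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, [1e6, 1e6, 1.0 - 1e-12])
        try:
            res = least_squares(
                resid,
                x0,
                bounds=(lb, ub),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                x_scale=np.maximum(np.abs(x0), 1e-4),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return MechFit(None, np.nan, converged=False, n_points=t.size)
    T0, KA0, beta = best.x
    # identifiability probe: at β = 0 the model is flat and only the lump
    # T0 + KA0·ε is determined; if the flat model fits as well as the best
    # power-law fit, report the lump (as T0) with the collinearity flag.
    flat_cost = 0.5 * float(np.sum(((np.mean(F) - F) / f_scale) ** 2))
    if flat_cost <= best.cost * (1.0 + 1e-6) + 1e-20:
        lump = float(np.mean(F) / pref)
        rms = float(np.sqrt(np.mean((np.mean(F) - F) ** 2)))
        return MechFit(
            params=MechParams(lump, 0.0, 0.0, t0_s),
            residual_rms=rms,
            converged=True,
            collinear=True,
            n_points=t.size,
        )
    rms = float(np.sqrt(np.mean((model(best.x) - F) ** 2)))
    return MechFit(
        params=MechParams(float(T0), float(KA0), float(beta), t0_s),
        residual_rms=rms,
        converged=True,
        collinear=bool(beta < 0.05),
        n_points=t.size,
    )


# ---------------------------------------------------------------------------
# membrane tension from tethers


def tether_tension(Ft_N: float, kappa_J: float = 2.7e-19) -> float:
    """Membrane tension (mN/m) from the tether rupture force.

    T_t = F_t² / (8π²κ) with bending modulus κ (default 2.7 × 10⁻¹⁹ J).
    """
    if Ft_N < 0:
        raise ValueError("tether force must be nonnegative")
    if kappa_J <= 0:
        raise ValueError("bending modulus must be positive")
    return Ft_N * Ft_N / (8.0 * np.pi**2 * kappa_J) / _MN_PER_M_TO_N_PER_M
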