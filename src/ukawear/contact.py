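"""Elastic-foundation (Winkler) contact solver for one compartment.

The deformable layer (polyethylene insert, or cartilage plus meniscus) is a
bed of independent springs: pressure at a node is ``k * penetration`` with
the bonded-layer foundation modulus

    k = E (1 - nu) / [(1 + nu) (1 - 2 nu) t]        [N/mm^3]

so the contact solve for a rigid femoral condyle reduces to finding the
axial approach at which the pressure integral balances the target load.
Friction never alters normal pressures; it only supplies Coulomb traction
bounds to the AP/IE quasi-static equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry_synth import CompartmentGeometry


@dataclass(frozen=True)
class FoundationParams:
    youngs_modulus: float            # MPa
    poisson_ratio: float
    layer_thickness: float           # mm
    friction_coefficient: float = 0.04

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5); the bonded-layer "
                             "modulus is singular at 0.5")
        if self.layer_thickness <= 0:
            raise ValueError("layer_thickness must be positive")
        if self.friction_coefficient < 0:
            raise ValueError("friction_coefficient must be >= 0")


def foundation_modulus(params: FoundationParams) -> float:
    """Bonded elastic-layer foundation modulus k (N/mm^3)."""
    e, nu, t = params.youngs_modulus, params.poisson_ratio, params.layer_thickness
    return e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * t)


@dataclass
class KinematicState:
    """Relative femoral-tibial pose at one gait instant."""

    flexion: float = 0.0          # deg
    ap_translation: float = 0.0   # mm, anterior tibial translation
    ie_rotation: float = 0.0      # deg, tibial internal-external rotation
    axial_approach: float = 0.0   # mm, femoral approach (penetration DOF)
    vv_tilt: float = 0.0          # deg, varus (+ = medial side down)


@dataclass
class ContactSolution:
    """Per-node pressures and summary contact metrics for one instant."""

    pressure: np.ndarray                     # MPa, (nx, nz), >= 0
    contact_area: float                      # mm^2
    peak_pressure: float                     # MPa
    total_force: float                       # N
    center_of_pressure: Tuple[float, float]  # (x, z) mm; (nan, nan) if unloaded
    axial_approach: float                    # mm
    vv_tilt: float = 0.0                     # deg
    t: float = float("nan")                  # cycle fraction, if applicable
    slide_increment: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dataframe(self, geom: CompartmentGeometry) -> pd.DataFrame:
        X, Z = geom.tibial_surface.meshgrid()
        slide = (np.zeros_like(self.pressure) if self.slide_increment is None
                 else self.slide_increment)
        return pd.DataFrame({"x": X.ravel(), "z": Z.ravel(),
                             "pressure": self.pressure.ravel(),
                             "slide": slide.ravel()})


class ContactError(RuntimeError):
    pass


def _pressure_field(geom: CompartmentGeometry, k: float, gap: np.ndarray,
                    approach: float, tilt_deg: float, pivot_z: float) -> np.ndarray:
    Z = geom.tibial_surface.meshgrid()[1]
    pen = approach + math.radians(tilt_deg) * (Z - pivot_z) - gap
    pen = np.where(np.isfinite(gap), pen, -np.inf)
    return k * np.maximum(0.0, pen)


def _summarize(geom: CompartmentGeometry, pressure: np.ndarray,
               approach: float, tilt: float, t: float = float("nan")) -> ContactSolution:
    area_w = geom.tibial_surface.nodal_area
    force_per_node = pressure * area_w
    total = float(force_per_node.sum())
    contact = pressure > 0.0
    if total > 0:
        X, Z = geom.tibial_surface.meshgrid()
        cop = (float((force_per_node * X).sum() / total),
               float((force_per_node * Z).sum() / total))
    else:
        cop = (float("nan"), float("nan"))
    return ContactSolution(
        pressure=pressure,
        contact_area=float(area_w[contact].sum()),
        peak_pressure=float(pressure.max(initial=0.0)),
        total_force=total,
        center_of_pressure=cop,
        axial_approach=approach,
        vv_tilt=tilt,
        t=t,
    )


def solve_contact(
    geom: CompartmentGeometry,
    foundation: FoundationParams,
    target_load: float,
    kin: KinematicState | None = None,
    pivot_z: float = 0.0,
    load_tol_rel: float = 1e-3,
    max_travel_factor: float = 5.0,
) -> ContactSolution:
    """Solve the axial approach so the foundation pressure integral matches
    ``target_load`` (N) at fixed flexion/AP/IE/tilt.

    The load-approach relation is monotone piecewise-linear; it is bracketed
    from first touch and solved with Brent's method to well inside 0.1 %.
    """
    if target_load < 0:
        raise ValueError("target_load must be >= 0")
    kin = kin or KinematicState()
    k = foundation_modulus(geom_foundation_check(geom, foundation))
    gap = geom.gap_field(kin.ap_translation, kin.ie_rotation)
    tilt_term = math.radians(kin.vv_tilt)
    Z = geom.tibial_surface.meshgrid()[1]
    g_eff = np.where(np.isfinite(gap), gap - tilt_term * (Z - pivot_z), np.inf)
    gmin = float(np.min(g_eff))
    if not np.isfinite(gmin):
        raise ContactError("surfaces share no overlap; contact impossible")

    if target_load == 0.0:
        pressure = np.zeros_like(geom.tibial_surface.height)
        sol = _summarize(geom, pressure, gmin, kin.vv_tilt)
        kin.axial_approach = gmin
        return sol

    area = geom.tibial_surface.nodal_area

    def load(delta):
        pen = np.maximum(0.0, delta - g_eff)
        return float((k * pen * area).sum()) - target_load

    dmax = gmin + max_travel_factor * geom.layer_thickness
    if load(dmax) < 0:
        raise ContactError(
            f"target load {target_load:.1f} N not reachable within travel bounds "
            f"({geom.label})")
    delta = brentq(load, gmin, dmax, xtol=1e-10, rtol=8.9e-16, maxiter=200)
    pressure = _pressure_field(geom, k, gap, delta, kin.vv_tilt, pivot_z)
    sol = _summarize(geom, pressure, delta, kin.vv_tilt)
    if abs(sol.total_force - target_load) > load_tol_rel * target_load:
        raise ContactError("contact solve did not meet the load tolerance")
    kin.axial_approach = delta
    return sol


def geom_foundation_check(geom: CompartmentGeometry,
                          foundation: FoundationParams) -> FoundationParams:
    """Foundation thickness is taken from the geometry's layer when they
    disagree, keeping the modulus consistent with the modeled layer."""
    if abs(foundation.layer_thickness - geom.layer_thickness) > 1e-9:
        return FoundationParams(
            youngs_modulus=foundation.youngs_modulus,
            poisson_ratio=foundation.poisson_ratio,
            layer_thickness=geom.layer_thickness,
            friction_coefficient=foundation.friction_coefficient)
    return foundation


def element_contact_stress(pressure: np.ndarray, x: np.ndarray, z: np.ndarray,
                           scale: float = 1.0) -> float:
    """Maximum contact stress averaged over ``scale`` x ``scale`` mm patches.

    The nodal maximum of a foundation pressure field is a noisy sup-estimator
    once the worn surface carries node-scale relief; averaging the bilinear
    field over patches at the reference element scale (1 mm, the mesh size
    at which FE contact stress is conventionally reported) gives the
    continuum-consistent peak.
    """
    dx = float(x[1] - x[0])
    n = max(1, int(round(scale / dx)))
    if pressure.shape[0] < n + 1 or pressure.shape[1] < n + 1:
        return float(pressure.max(initial=0.0))
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(pressure, (n + 1, n + 1))
    wt = np.ones(n + 1)
    wt[[0, -1]] = 0.5
    w2 = np.outer(wt, wt)
    w2 /= w2.sum()
    means = np.einsum("ijkl,kl->ij", win, w2)
    return float(means.max(initial=0.0))


def coulomb_capacities(sol: ContactSolution, geom: CompartmentGeometry,
                       friction_coefficient: float,
                       axis: Tuple[float, float] = (0.0, 0.0)) -> Tuple[float, float]:
    """Coulomb traction bounds from one contact solution.

    Returns ``(force_capacity_N, torque_capacity_Nm)``: mu * integral(p dA)
    and mu * integral(p r dA) about the vertical axis through ``axis``.
    """
    area = geom.tibial_surface.nodal_area
    f = float((sol.pressure * area).sum()) * friction_coefficient
    X, Z = geom.tibial_surface.meshgrid()
    r = np.hypot(X - axis[0], Z - axis[1])
    tq = float((sol.pressure * area * r).sum()) * friction_coefficient / 1000.0
    return f, tq


def sliding_increment(
    kin_t: KinematicState,
    kin_next: KinematicState,
    geom: CompartmentGeometry,
    contact_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Relative femoral-on-tibial sliding magnitude (mm) per node across one
    time increment.

    Three tangential contributions compose vectorially in the surface plane:
    flexion arc length (local femoral sagittal radius x increment of flexion),
    AP translation, and IE rotation (lever arm from the IE axis).  Convention
    is femoral motion relative to the insert surface.
    """
    d_th = math.radians(kin_next.flexion - kin_t.flexion)
    d_ap = kin_next.ap_translation - kin_t.ap_translation
    d_ie = math.radians(kin_next.ie_rotation - kin_t.ie_rotation)
    rs = geom.femoral_radii[0]
    X, Z = geom.tibial_surface.meshgrid()
    x0, z0 = geom.ie_axis
    vx = rs * d_th - d_ap + d_ie * (Z - z0)
    vz = -d_ie * (X - x0)
    slide = np.hypot(vx, vz)
    if contact_mask is not None:
        slide = np.where(contact_mask, slide, 0.0)
    return slide
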