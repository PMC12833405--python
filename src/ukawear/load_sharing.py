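"""Two-compartment load sharing with a free varus-valgus femur.

In the whole-joint scenario the axial gait force is applied at a femoral
load point offset 5 mm medial of the joint center, and the femur is free in
axial translation and varus-valgus (VV) rotation.  The compartment forces
then follow from a 2-DOF rigid-body equilibrium — no load-sharing ratio is
prescribed:

* force balance: medial + lateral foundation-pressure integrals equal the
  applied axial force;
* moment balance: the VV moment of both pressure fields about the femoral
  load point vanishes.

As the insert wears, the medial gap grows, the equilibrium tilt rotates
varus-ward, and both contact centroids migrate medially, which is precisely
the mechanism that transfers load onto the lateral cartilage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .contact import (ContactSolution, FoundationParams, _pressure_field,
                      _summarize, foundation_modulus, geom_foundation_check)
from .geometry_synth import CompartmentGeometry


@dataclass(frozen=True)
class JointConfig:
    femoral_load_offset: float = 5.0     # mm medial (+z) of the joint center
    medial_center_z: float = 25.0
    lateral_center_z: float = -25.0
    vv_free: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.femoral_load_offset):
            raise ValueError("femoral_load_offset must be finite")
        if not (self.medial_center_z > 0 > self.lateral_center_z):
            raise ValueError("compartment centers must straddle the joint center")


@dataclass
class LoadSplit:
    f_medial: float
    f_lateral: float
    medial_fraction: float
    vv_tilt: float                      # deg
    t: float = float("nan")


@dataclass
class LateralStressEstimate:
    peak_pressure: float                # MPa
    peak_von_mises: float               # MPa
    t: float


class JointSolverError(RuntimeError):
    pass


def cartilage_von_mises(pressure, poisson_ratio: float):
    """Von Mises stress of a laterally confined layer under pressure ``p``.

    Uniaxial-strain state: out-of-plane stress p, in-plane nu/(1-nu) p, so
    von Mises = p (1 - 2 nu) / (1 - nu).  Vanishes in the incompressible
    limit; equals p for nu = 0.
    """
    if not 0.0 <= poisson_ratio < 0.5:
        raise ValueError("poisson_ratio must lie in [0, 0.5)")
    factor = (1.0 - 2.0 * poisson_ratio) / (1.0 - poisson_ratio)
    out = np.asarray(pressure, dtype=float) * factor
    return float(out) if np.isscalar(pressure) else out


def solve_joint_equilibrium(
    medial: CompartmentGeometry,
    lateral: CompartmentGeometry,
    medial_foundation: FoundationParams,
    lateral_foundation: FoundationParams,
    axial_force: float,
    cfg: JointConfig | None = None,
    ap_translation: float = 0.0,
    ie_rotation: float = 0.0,
    t: float = float("nan"),
    warm_start: Tuple[float, float] | None = None,
    force_tol_rel: float = 1e-4,
    moment_tol: float = 0.01,
    max_iter: int = 60,
) -> Tuple[LoadSplit, ContactSolution, ContactSolution]:
    """Solve femoral approach and VV tilt for one gait instant.

    Returns the load split plus the medial and lateral contact solutions.
    With ``cfg.vv_free`` false the tilt is held at zero and only the force
    balance is enforced (parallel-foundation load division).
    """
    cfg = cfg or JointConfig()
    if axial_force < 0:
        raise ValueError("axial_force must be >= 0")
    zp = cfg.femoral_load_offset
    k_m = foundation_modulus(geom_foundation_check(medial, medial_foundation))
    k_l = foundation_modulus(geom_foundation_check(lateral, lateral_foundation))
    gap_m = medial.gap_field(ap_translation, ie_rotation)
    gap_l = lateral.gap_field(ap_translation, ie_rotation)
    Zm = medial.tibial_surface.meshgrid()[1]
    Zl = lateral.tibial_surface.meshgrid()[1]
    area_m = medial.tibial_surface.nodal_area
    area_l = lateral.tibial_surface.nodal_area

    def fields(delta: float, tilt_deg: float):
        phi = math.radians(tilt_deg)
        pen_m = np.where(np.isfinite(gap_m), delta + phi * (Zm - zp) - gap_m, 0.0)
        pen_l = np.where(np.isfinite(gap_l), delta + phi * (Zl - zp) - gap_l, 0.0)
        p_m = k_m * np.maximum(0.0, pen_m)
        p_l = k_l * np.maximum(0.0, pen_l)
        f_m = float((p_m * area_m).sum())
        f_l = float((p_l * area_l).sum())
        m = float((p_m * area_m * (Zm - zp)).sum()
                  + (p_l * area_l * (Zl - zp)).sum()) / 1000.0   # N m
        return p_m, p_l, f_m, f_l, m

    if axial_force == 0.0:
        gmin = min(float(np.min(gap_m)), float(np.min(gap_l)))
        p0 = np.zeros_like(medial.tibial_surface.height)
        p1 = np.zeros_like(lateral.tibial_surface.height)
        return (LoadSplit(0.0, 0.0, 0.0, 0.0, t),
                _summarize(medial, p0, gmin, 0.0, t),
                _summarize(lateral, p1, gmin, 0.0, t))

    def _nested_solve(phi_guess: float) -> Tuple[float, float]:
        """Fallback: outer bisection on tilt (moment), inner on approach
        (force).  Both maps are monotone, so this always converges; it is
        slower than Newton but immune to the piecewise-linear kinks."""
        gmin_all = min(float(np.min(gap_m)), float(np.min(gap_l)))
        span = 5.0 * max(medial.layer_thickness, lateral.layer_thickness)

        def delta_of(phi: float) -> float:
            def load(d):
                _, _, f_m, f_l, _ = fields(d, phi)
                return f_m + f_l - axial_force
            lo = gmin_all - abs(math.radians(phi)) * 100.0
            hi = lo + span
            for _ in range(40):
                if load(hi) > 0:
                    break
                hi += span
            else:
                raise JointSolverError("axial force not reachable in nested solve")
            return brentq(load, lo, hi, xtol=1e-11, maxiter=200)

        def moment(phi: float) -> float:
            return fields(delta_of(phi), phi)[4]

        lo, hi = phi_guess - 0.5, phi_guess + 0.5
        m_lo, m_hi = moment(lo), moment(hi)
        for _ in range(40):
            if m_lo * m_hi <= 0:
                break
            if abs(m_lo) < abs(m_hi):
                lo -= 2.0 * (hi - lo)
                m_lo = moment(lo)
            else:
                hi += 2.0 * (hi - lo)
                m_hi = moment(hi)
        else:
            raise JointSolverError("could not bracket VV moment balance")
        phi = brentq(moment, lo, hi, xtol=1e-10, maxiter=200)
        return delta_of(phi), phi

    if not cfg.vv_free:
        def load(delta):
            return fields(delta, 0.0)[2] + fields(delta, 0.0)[3] - axial_force
        gmin = min(float(np.min(gap_m)), float(np.min(gap_l)))
        dmax = gmin + 5.0 * max(medial.layer_thickness, lateral.layer_thickness)
        hi = dmax
        for _ in range(30):
            if load(hi) > 0:
                break
            hi += dmax - gmin
        else:
            raise JointSolverError("axial force not reachable with fixed tilt")
        delta = brentq(load, gmin, hi, xtol=1e-10, maxiter=200)
        tilt = 0.0
    else:
        # 2-D damped Newton with finite-difference Jacobian
        delta, tilt = warm_start if warm_start is not None else (
            min(float(np.min(gap_m)), float(np.min(gap_l))) + 0.05, 0.0)
        f_scale = max(axial_force, 1.0)
        m_scale = max(moment_tol * 10.0, 1.0)

        def residual(d, ph):
            _, _, f_m, f_l, m = fields(d, ph)
            return np.array([(f_m + f_l - axial_force) / f_scale, m / m_scale])

        r = residual(delta, tilt)
        h_d, h_p = 1e-4, 1e-4
        converged = False
        for _ in range(max_iter):
            if (abs(r[0]) * f_scale <= force_tol_rel * axial_force
                    and abs(r[1]) * m_scale <= moment_tol):
                converged = True
                break
            jac = np.column_stack([
                (residual(delta + h_d, tilt) - r) / h_d,
                (residual(delta, tilt + h_p) - r) / h_p,
            ])
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError as exc:
                raise JointSolverError(f"singular Jacobian at t={t}: {exc}") from exc
            # backtracking line search on the scaled residual norm
            lam = 1.0
            base = float(np.dot(r, r))
            for _ in range(30):
                r_new = residual(delta + lam * step[0], tilt + lam * step[1])
                if float(np.dot(r_new, r_new)) < base or lam < 1e-6:
                    break
                lam *= 0.5
            delta += lam * step[0]
            tilt += lam * step[1]
            r = r_new
        if not converged and not (abs(r[0]) * f_scale <= force_tol_rel * axial_force
                                  and abs(r[1]) * m_scale <= moment_tol):
            delta, tilt = _nested_solve(tilt)

    p_m, p_l, f_m, f_l, m_res = fields(delta, tilt)
    if (abs(f_m + f_l - axial_force) > max(force_tol_rel * axial_force, 1e-6)
            or (cfg.vv_free and abs(m_res) > moment_tol)):
        raise JointSolverError(
            f"joint equilibrium did not converge at t={t}: "
            f"force residual {f_m + f_l - axial_force:.3e} N, moment {m_res:.3e} N m")
    sol_m = _summarize(medial, p_m, delta, tilt, t)
    sol_l = _summarize(lateral, p_l, delta, tilt, t)
    total = f_m + f_l
    split = LoadSplit(
        f_medial=f_m, f_lateral=f_l,
        medial_fraction=f_m / total if total > 0 else 0.0,
        vv_tilt=tilt, t=t)
    return split, sol_m, sol_l


def lateral_stress_trajectory(
    lateral_solutions: Sequence[ContactSolution],
    poisson_ratio: float = 0.475,
) -> Tuple[List[LateralStressEstimate], LateralStressEstimate]:
    """Per-sample peak lateral pressure and its von Mises surrogate.

    Returns the trajectory and the cycle maximum (by von Mises, with its
    phase).
    """
    traj = [LateralStressEstimate(
        peak_pressure=s.peak_pressure,
        peak_von_mises=cartilage_von_mises(s.peak_pressure, poisson_ratio),
        t=s.t) for s in lateral_solutions]
    peak = max(traj, key=lambda e: e.peak_von_mises) if traj else LateralStressEstimate(0.0, 0.0, float("nan"))
    return traj, peak
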