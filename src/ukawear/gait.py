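"""ISO-14243-style gait waveforms and lumped soft-tissue restraints.

The wear-testing standard prescribes a force-controlled gait cycle: an axial
force with two stance peaks, a flexion-extension angle, an AP shear force and
an internal-external (IE) torque, plus spring-like soft-tissue restraints
with neutral zones.  Only the two axial peaks are pinned to published values
(2600 N at 13 % cycle, 2433.5 N at 45 %); every other shape parameter is an
explicit configuration default with an ISO-14243-like silhouette.

Axial force is a baseline plus two periodic von-Mises bumps whose amplitudes
are solved exactly so the configured peak values are met at the configured
phases.  Flexion, AP force and IE torque are periodic cubic splines through
anchor points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

Anchor = Tuple[float, float]

_FLEXION_ANCHORS: Tuple[Anchor, ...] = (
    (0.0, 0.0), (0.15, 18.0), (0.40, 8.0), (0.55, 25.0),
    (0.70, 58.0), (0.85, 20.0), (1.0, 0.0))
_AP_FORCE_ANCHORS: Tuple[Anchor, ...] = (
    (0.0, 0.0), (0.13, 120.0), (0.45, 265.0), (0.65, 50.0),
    (0.80, -40.0), (1.0, 0.0))
_IE_TORQUE_ANCHORS: Tuple[Anchor, ...] = (
    (0.0, 0.0), (0.13, -0.6), (0.45, 2.5), (0.70, 0.6),
    (0.85, -0.3), (1.0, 0.0))


@dataclass(frozen=True)
class WaveformConfig:
    """Shape parameters of the synthesized gait cycle.

    ``axial_width1/2`` are von-Mises concentration parameters (larger =
    narrower bump); anchors are (cycle fraction, value) pairs with equal
    first and last values (periodicity).
    """

    n_samples: int = 100
    axial_peak1: float = 2600.0
    axial_phase1: float = 0.13
    axial_peak2: float = 2433.5
    axial_phase2: float = 0.45
    axial_baseline: float = 168.0
    axial_width1: float = 40.0
    axial_width2: float = 40.0
    flexion_anchors: Tuple[Anchor, ...] = _FLEXION_ANCHORS
    ap_force_anchors: Tuple[Anchor, ...] = _AP_FORCE_ANCHORS
    ie_torque_anchors: Tuple[Anchor, ...] = _IE_TORQUE_ANCHORS

    def __post_init__(self) -> None:
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")
        for phase in (self.axial_phase1, self.axial_phase2):
            if not 0.0 < phase < 1.0:
                raise ValueError(f"axial peak phase {phase} outside (0, 1)")
        if self.axial_baseline < 0:
            raise ValueError("axial_baseline must be >= 0")
        for anchors in (self.flexion_anchors, self.ap_force_anchors, self.ie_torque_anchors):
            if anchors[0][1] != anchors[-1][1]:
                raise ValueError("anchor sequences must start and end at equal values")


@dataclass
class GaitWaveforms:
    """Sampled per-cycle traces plus the analytic generators behind them."""

    t: np.ndarray
    flexion: np.ndarray        # deg
    axial_force: np.ndarray    # N
    ap_force: np.ndarray       # N
    ie_torque: np.ndarray      # N m
    config: WaveformConfig | None = None
    _fns: dict = field(default_factory=dict, repr=False)

    def evaluate(self, channel: str, t) -> np.ndarray | float:
        """Evaluate a channel's analytic waveform at arbitrary cycle fraction."""
        return self._fns[channel](np.asarray(t, dtype=float) % 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "flexion_deg": self.flexion, "axial_N": self.axial_force,
            "ap_N": self.ap_force, "ie_Nm": self.ie_torque,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GaitWaveforms":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), flexion=df["flexion_deg"].to_numpy(),
                   axial_force=df["axial_N"].to_numpy(), ap_force=df["ap_N"].to_numpy(),
                   ie_torque=df["ie_Nm"].to_numpy())


def _von_mises_bump(phase: float, width: float) -> Callable[[np.ndarray], np.ndarray]:
    def g(t):
        return np.exp(width * (np.cos(2.0 * np.pi * (t - phase)) - 1.0))
    return g


def _periodic_spline(anchors: Sequence[Anchor]) -> Callable[[np.ndarray], np.ndarray]:
    ts = np.array([a[0] for a in anchors])
    vs = np.array([a[1] for a in anchors])
    spline = CubicSpline(ts, vs, bc_type="periodic")
    return lambda t: spline(np.asarray(t) % 1.0)


def make_iso14243_waveforms(
    n_samples: int | None = None,
    config: WaveformConfig | None = None,
    **peak_overrides,
) -> GaitWaveforms:
    """Build one gait cycle of waveforms.

    Keyword overrides replace any :class:`WaveformConfig` field, e.g.
    ``make_iso14243_waveforms(axial_peak1=2500.0)``.
    """
    base = config or WaveformConfig()
    updates = dict(peak_overrides)
    if n_samples is not None:
        updates["n_samples"] = n_samples
    if updates:
        base = WaveformConfig(**{**base.__dict__, **updates})

    g1 = _von_mises_bump(base.axial_phase1, base.axial_width1)
    g2 = _von_mises_bump(base.axial_phase2, base.axial_width2)
    # amplitudes solved so the curve passes exactly through both peaks
    mat = np.array([[g1(base.axial_phase1), g2(base.axial_phase1)],
                    [g1(base.axial_phase2), g2(base.axial_phase2)]])
    rhs = np.array([base.axial_peak1 - base.axial_baseline,
                    base.axial_peak2 - base.axial_baseline])
    a1, a2 = np.linalg.solve(mat, rhs)

    def axial(t):
        t = np.asarray(t, dtype=float)
        return base.axial_baseline + a1 * g1(t) + a2 * g2(t)

    fns = {
        "axial_force": axial,
        "flexion": _periodic_spline(base.flexion_anchors),
        "ap_force": _periodic_spline(base.ap_force_anchors),
        "ie_torque": _periodic_spline(base.ie_torque_anchors),
    }
    t = np.arange(base.n_samples) / base.n_samples
    wave = GaitWaveforms(
        t=t,
        flexion=np.asarray(fns["flexion"](t), dtype=float),
        axial_force=np.asarray(fns["axial_force"](t), dtype=float),
        ap_force=np.asarray(fns["ap_force"](t), dtype=float),
        ie_torque=np.asarray(fns["ie_torque"](t), dtype=float),
        config=base,
        _fns=fns,
    )
    if np.any(wave.axial_force < 0):
        raise ValueError("axial force waveform went negative; adjust peaks/baseline")
    return wave


# ---------------------------------------------------------------------------
# lumped soft-tissue restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintParams:
    """Neutral-zone spring restraints standing in for capsule and ligaments.

    The IE restraint is linear (0.6 N m/deg on the rotation in excess of the
    neutral zone); the AP restraint is cubic-plus-linear on the excess
    displacement.  Both are odd and restoring.
    """

    ie_spring_stiffness: float = 0.6     # N m / deg
    ap_linear_coefficient: float = 50.0  # N / mm
    ap_cubic_coefficient: float = 10.0   # N / mm^3
    ap_neutral_zone: float = 2.5         # mm
    ie_neutral_zone: float = 3.0         # deg

    def __post_init__(self) -> None:
        if self.ie_spring_stiffness < 0:
            raise ValueError("ie_spring_stiffness must be >= 0")
        if self.ap_neutral_zone < 0 or self.ie_neutral_zone < 0:
            raise ValueError("neutral zones must be >= 0")
        if self.ap_linear_coefficient < 0 or self.ap_cubic_coefficient < 0:
            raise ValueError("AP spring coefficients must be >= 0")


def restraint_torque(ie_rotation, params: RestraintParams):
    """Restoring IE torque (N m); zero inside the neutral zone, odd outside."""
    r = np.asarray(ie_rotation, dtype=float)
    excess = np.maximum(0.0, np.abs(r) - params.ie_neutral_zone)
    out = -np.sign(r) * params.ie_spring_stiffness * excess
    return float(out) if np.isscalar(ie_rotation) else out


def restraint_force_ap(ap_displacement, params: RestraintParams):
    """Restoring AP force (N); cubic-plus-linear on the excess displacement."""
    d = np.asarray(ap_displacement, dtype=float)
    e = np.maximum(0.0, np.abs(d) - params.ap_neutral_zone)
    out = -np.sign(d) * (params.ap_linear_coefficient * e
                         + params.ap_cubic_coefficient * e ** 3)
    return float(out) if np.isscalar(ap_displacement) else out


class EquilibriumError(RuntimeError):
    pass


def _stick_slip_step(applied: float, x_prev: float,
                     law: Callable[[float], float], capacity: float,
                     tol: float) -> Tuple[float, float]:
    """Advance one quasi-static Coulomb stick-slip DOF.

    ``law`` is the restoring restraint (odd, monotone non-increasing);
    ``capacity`` is the friction force/torque bound.  Returns the new state
    and the unbalanced residual after optimal static friction.
    """
    def net(x):
        return applied + law(x)

    g0 = net(x_prev)
    if abs(g0) <= capacity + tol:
        return x_prev, 0.0
    s = math.copysign(1.0, g0)

    def h(x):
        return net(x) - s * capacity

    # bracket in the slip direction; net() is monotone non-increasing in x
    step = 1.0
    lo, hi = (x_prev, x_prev + step) if s > 0 else (x_prev - step, x_prev)
    for _ in range(80):
        if h(lo) * h(hi) <= 0:
            break
        step *= 2.0
        if s > 0:
            hi = x_prev + step
        else:
            lo = x_prev - step
    else:
        raise EquilibriumError("could not bracket stick-slip equilibrium "
                               f"(applied={applied:.3f}, capacity={capacity:.3f})")
    x = brentq(h, lo, hi, xtol=1e-10, maxiter=200)
    return x, abs(h(x))


def quasi_static_ap_ie(
    waveforms: GaitWaveforms,
    params: RestraintParams,
    normal_force: np.ndarray,
    friction_coefficient: float = 0.04,
    friction_torque_capacity: np.ndarray | None = None,
    n_settle_cycles: int = 2,
    force_tol: float = 0.01,
    torque_tol: float = 0.001,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Solve tibial AP displacement (mm) and IE rotation (deg) over one cycle.

    At every sample the applied shear force/torque, the Coulomb friction
    traction of the articulation(s), and the neutral-zone restraint balance
    quasi-statically.  Friction is hysteretic, so the cycle is marched
    ``n_settle_cycles`` times and the last pass returned.

    ``normal_force`` is the per-sample total contact normal force (N);
    ``friction_torque_capacity`` the per-sample Coulomb torque bound (N m)
    about the IE axis (defaults to zero).

    Returns ``(ap_displacement, ie_rotation, force_residual, torque_residual)``.
    """
    n = len(waveforms.t)
    normal_force = np.asarray(normal_force, dtype=float)
    if normal_force.shape != (n,):
        raise ValueError("normal_force must have one entry per time sample")
    cap_t = (np.zeros(n) if friction_torque_capacity is None
             else np.asarray(friction_torque_capacity, dtype=float))

    ap = np.zeros(n)
    ie = np.zeros(n)
    res_f = np.zeros(n)
    res_t = np.zeros(n)
    d, r = 0.0, 0.0
    for _ in range(max(1, n_settle_cycles)):
        for i in range(n):
            cap_f = friction_coefficient * normal_force[i]
            try:
                d, res_f[i] = _stick_slip_step(
                    waveforms.ap_force[i], d,
                    lambda x: restraint_force_ap(x, params), cap_f, force_tol)
                r, res_t[i] = _stick_slip_step(
                    waveforms.ie_torque[i], r,
                    lambda x: restraint_torque(x, params), cap_t[i], torque_tol)
            except EquilibriumError as exc:
                raise EquilibriumError(f"sample {i} (t={waveforms.t[i]:.2f}): {exc}") from exc
            ap[i], ie[i] = d, r
    if np.any(res_f > force_tol) or np.any(res_t > torque_tol):
        bad = int(np.argmax(np.maximum(res_f / force_tol, res_t / torque_tol)))
        raise EquilibriumError(f"equilibrium residual above tolerance at sample {bad}")
    return ap, ie, res_f, res_t
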