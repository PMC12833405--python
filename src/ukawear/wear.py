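"""Archard wear accumulation and adaptive surface update.

Linear wear depth follows Archard's law ``H = Kw * sigma * S`` with wear
factor Kw in mm^3/(N m), contact stress sigma in MPa (= N/mm^2) and sliding
distance S in m, giving H directly in mm.  Depth accumulated over one
representative gait cycle is scaled by the cycles per analysis step
(default 0.5 million) and the insert surface nodes recede along their
current outward normal; on a height field this is a vertical height drop of
recession divided by the normal's vertical component.  Volume loss is the
exact prism volume (vertical drop x plan nodal area, equivalently recession
x true surface area) and mass loss is density x volume with the
conventional polyethylene density 0.93 mg/mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .contact import ContactSolution
from .geometry_synth import CompartmentGeometry


@dataclass(frozen=True)
class ArchardParams:
    wear_factor_kw: float = 3.3e-7     # mm^3 / (N m)
    density: float = 0.93              # mg / mm^3
    cycles_per_step: float = 5.0e5
    n_steps: int = 10
    smoothing_passes: int = 0          # optional Laplacian smoothing of the step depth field

    def __post_init__(self) -> None:
        if self.wear_factor_kw < 0:
            raise ValueError("wear_factor_kw must be >= 0")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.cycles_per_step <= 0 or self.n_steps < 0:
            raise ValueError("schedule must be non-negative")

    @property
    def total_cycles(self) -> float:
        return self.n_steps * self.cycles_per_step


@dataclass
class StepRecord:
    step: int
    cycles: float                       # cumulative cycles after this step
    volume_mm3: float                   # cumulative
    mass_mg: float                      # cumulative
    max_depth_mm: float                 # cumulative
    peak_pressure_MPa: float            # cycle max of the nodal peak, step-start geometry
    contact_area_mm2: float             # cycle max at step-start geometry
    element_stress_MPa: float = float("nan")   # cycle max of 1-mm element-averaged stress
    medial_fraction_first_peak: float = float("nan")
    lateral_peak_vm_MPa: float = float("nan")


@dataclass
class WearState:
    """Cumulative nodal wear depth plus volumetric/gravimetric bookkeeping."""

    depth: np.ndarray                   # mm per node, along the surface normal
    volume_loss: float = 0.0            # mm^3
    mass_loss: float = 0.0              # mg
    per_step_history: List[StepRecord] = field(default_factory=list)

    @classmethod
    def zeros_like(cls, geom: CompartmentGeometry) -> "WearState":
        return cls(depth=np.zeros_like(geom.tibial_surface.height))

    @property
    def max_depth(self) -> float:
        return float(self.depth.max(initial=0.0))

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.per_step_history])


class ThicknessExhaustedError(RuntimeError):
    pass


def archard_depth_increment(pressure, slide, params: ArchardParams):
    """Linear wear depth (mm) for contact stress (MPa) and sliding (m)."""
    p = np.asarray(pressure, dtype=float)
    s = np.asarray(slide, dtype=float)
    if np.any(p < 0) or np.any(s < 0):
        raise ValueError("pressure and slide must be non-negative")
    out = params.wear_factor_kw * p * s
    return float(out) if np.isscalar(pressure) and np.isscalar(slide) else out


def accumulate_cycle(solutions: Sequence[ContactSolution],
                     params: ArchardParams) -> np.ndarray:
    """Per-node wear depth (mm) over one gait cycle.

    Each increment contributes Kw x pressure at the increment start x the
    sliding magnitude across the increment; the attached ``slide_increment``
    arrays are in mm and converted to m here.
    """
    if not solutions:
        raise ValueError("need at least one contact solution")
    shape = solutions[0].pressure.shape
    depth = np.zeros(shape)
    for sol in solutions:
        if sol.pressure.shape != shape:
            raise ValueError("contact solutions use inconsistent node sets")
        if sol.slide_increment is None:
            raise ValueError("contact solution lacks a sliding increment field")
        depth += archard_depth_increment(sol.pressure,
                                         sol.slide_increment / 1000.0, params)
    return depth


def _laplacian_smooth(fld: np.ndarray, passes: int) -> np.ndarray:
    out = fld.copy()
    for _ in range(passes):
        padded = np.pad(out, 1, mode="edge")
        out = 0.5 * out + 0.125 * (padded[:-2, 1:-1] + padded[2:, 1:-1]
                                   + padded[1:-1, :-2] + padded[1:-1, 2:])
    return out


def apply_wear_step(state: WearState, cycle_depth: np.ndarray,
                    geom: CompartmentGeometry, params: ArchardParams) -> None:
    """Advance one analysis step: recede the tibial surface and update totals.

    Recession = per-cycle depth x cycles per step, applied along the current
    outward normal.  Raises :class:`ThicknessExhaustedError` if any node
    would wear through the remaining insert thickness.
    """
    if np.any(cycle_depth < 0):
        raise ValueError("cycle depth field must be non-negative")
    recession = cycle_depth * params.cycles_per_step
    if params.smoothing_passes:
        recession = _laplacian_smooth(recession, params.smoothing_passes)
    surf = geom.tibial_surface
    n_up = surf.normal[..., 2]
    drop = recession / n_up
    remaining = surf.height - drop
    if np.any(remaining <= 0.0):
        i, j = np.unravel_index(int(np.argmin(remaining)), remaining.shape)
        raise ThicknessExhaustedError(
            f"wear would exhaust the insert thickness at node "
            f"(x={surf.x[i]:.1f}, z={surf.z[j]:.1f}); remaining "
            f"{surf.height[i, j]:.3f} mm, recession {drop[i, j]:.3f} mm")
    vol_inc = float((drop * surf.nodal_area).sum())
    surf.height = remaining
    surf.recompute_normals()
    state.depth = state.depth + recession
    state.volume_loss += vol_inc
    state.mass_loss = params.density * state.volume_loss


def run_wear_schedule(
    evaluate_cycle: Callable[[], "CycleResult"],
    geom: CompartmentGeometry,
    params: ArchardParams,
) -> tuple[WearState, Optional["CycleResult"]]:
    """Run the adaptive wear loop: evaluate a representative gait cycle on
    the current geometry, accumulate Archard depth, recede the surface, and
    repeat for ``n_steps`` analysis steps.

    Pressures within a step are frozen at the step-start geometry.  Returns
    the wear state (with per-step history at step-start geometry) and a
    final post-wear cycle evaluation (None when ``n_steps == 0``).
    """
    state = WearState.zeros_like(geom)
    for step in range(params.n_steps):
        try:
            cyc = evaluate_cycle()
            depth_cycle = accumulate_cycle(cyc.medial_solutions, params)
            apply_wear_step(state, depth_cycle, geom, params)
        except Exception as exc:
            raise type(exc)(f"wear step {step}: {exc}") from exc
        m = cyc.metrics
        state.per_step_history.append(StepRecord(
            step=step,
            cycles=(step + 1) * params.cycles_per_step,
            volume_mm3=state.volume_loss,
            mass_mg=state.mass_loss,
            max_depth_mm=state.max_depth,
            peak_pressure_MPa=m["peak_pressure_MPa"],
            contact_area_mm2=m["contact_area_mm2"],
            element_stress_MPa=m.get("element_stress_MPa", float("nan")),
            medial_fraction_first_peak=m.get("medial_fraction_first_peak", float("nan")),
            lateral_peak_vm_MPa=m.get("lateral_peak_vm_MPa", float("nan")),
        ))
    final_cycle = evaluate_cycle() if params.n_steps > 0 else None
    return state, final_cycle


@dataclass
class CycleResult:
    """One representative gait cycle evaluated on fixed geometry."""

    medial_solutions: List[ContactSolution]
    lateral_solutions: List[ContactSolution]
    metrics: dict
    samples: pd.DataFrame


def wear_centroid(state: WearState, geom: CompartmentGeometry) -> tuple[float, float]:
    """Depth-weighted centroid (x, z) of the worn region (nan if unworn)."""
    w = state.depth * geom.tibial_surface.nodal_area
    total = float(w.sum())
    if total == 0.0:
        return (float("nan"), float("nan"))
    X, Z = geom.tibial_surface.meshgrid()
    return (float((w * X).sum() / total), float((w * Z).sum() / total))
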