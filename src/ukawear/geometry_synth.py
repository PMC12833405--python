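"""Synthetic articular geometry for a fixed-bearing medial UKA and the
lateral tibiofemoral compartment.

All surfaces are analytic spherical-arc (torus-like) height fields sampled
on regular lattices — the standard idealization of a unicompartmental
articulation: a biconvex femoral condyle on a dished polyethylene insert,
and a femoral condyle on a shallow-dished tibial cartilage layer laterally.

Coordinate convention (all lengths mm):

* ``x``      anterior (+) / posterior (-)
* ``z``      medial (+) / lateral (-)
* ``height`` proximal (+), the articular direction

Because every surface is a height field, contact detection reduces to a
one-dimensional gap computation per lattice node, which is what keeps the
downstream foundation-contact solver desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np
import pandas as pd


def _sagitta(offset: np.ndarray, radius: float) -> np.ndarray:
    """Circular sagitta ``R - sqrt(R^2 - r^2)`` (0 for an infinite radius)."""
    offset = np.asarray(offset, dtype=float)
    if math.isinf(radius):
        return np.zeros_like(offset)
    if np.any(np.abs(offset) > radius):
        raise ValueError(
            f"offset extent {np.max(np.abs(offset)):.3f} mm exceeds arc radius {radius} mm"
        )
    return radius - np.sqrt(radius * radius - offset * offset)


@dataclass(frozen=True)
class ImplantSpec:
    """Nominal dimensions of the fixed-bearing medial implant.

    Footprints follow physical component measurements of a contemporary
    partial-knee system (femoral component ~20 mm ML x 45 mm AP, insert
    ~26 mm ML x 41 mm AP, 8 mm minimum insert thickness).  Articular radii
    are representative of a low-conformity fixed-bearing design, not
    manufacturer values, and are freely overridable.
    """

    femoral_ml_width: float = 20.0
    femoral_ap_length: float = 45.0
    insert_ml: float = 26.0
    insert_ap: float = 41.0
    insert_thickness: float = 8.0
    femoral_sagittal_radius: float = 28.0
    femoral_coronal_radius: float = 22.0
    insert_sagittal_radius: float = 45.0
    insert_coronal_radius: float = 30.0

    def __post_init__(self) -> None:
        for name in ("femoral_ml_width", "femoral_ap_length", "insert_ml", "insert_ap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.insert_thickness <= 0:
            raise ValueError("insert_thickness must be positive")
        if self.femoral_sagittal_radius <= 0 or self.femoral_coronal_radius <= 0:
            raise ValueError("femoral radii must be positive")
        # Non-negative clearance: the dish may not be tighter than the condyle.
        if self.insert_sagittal_radius < self.femoral_sagittal_radius:
            raise ValueError("insert_sagittal_radius must be >= femoral_sagittal_radius")
        if self.insert_coronal_radius < self.femoral_coronal_radius:
            raise ValueError("insert_coronal_radius must be >= femoral_coronal_radius")


@dataclass
class SurfaceGrid:
    """A regular-grid height-field surface with per-node area and normal.

    ``nodal_area`` carries trapezoid quadrature weights (half weight on
    edges, quarter on corners) so that ``nodal_area.sum()`` equals the
    footprint area exactly.  ``normal`` has components ``(n_x, n_z, n_up)``
    and unit length.
    """

    x: np.ndarray                      # (nx,) anterior-posterior positions
    z: np.ndarray                      # (nz,) medial-lateral positions
    height: np.ndarray                 # (nx, nz)
    nodal_area: np.ndarray             # (nx, nz) plan (x-z) area weights
    normal: np.ndarray                 # (nx, nz, 3)
    footprint: Tuple[float, float]     # (ap_length, ml_width)

    @classmethod
    def from_height_function(
        cls,
        fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
        center: Tuple[float, float],
        ap_length: float,
        ml_width: float,
        resolution: float,
    ) -> "SurfaceGrid":
        """Sample an analytic height function on a regular lattice.

        ``resolution`` is in nodes per mm; a footprint of L mm at r nodes/mm
        yields ``round(L * r) + 1`` lattice lines along that axis.
        """
        nx = int(round(ap_length * resolution)) + 1
        nz = int(round(ml_width * resolution)) + 1
        if nx < 2 or nz < 2:
            raise ValueError("resolution too coarse: need at least 2 nodes per axis")
        cx, cz = center
        x = cx + np.linspace(-ap_length / 2.0, ap_length / 2.0, nx)
        z = cz + np.linspace(-ml_width / 2.0, ml_width / 2.0, nz)
        X, Z = np.meshgrid(x, z, indexing="ij")
        height = np.asarray(fn(X, Z), dtype=float)
        dx = ap_length / (nx - 1)
        dz = ml_width / (nz - 1)
        wx = np.full(nx, dx)
        wx[[0, -1]] *= 0.5
        wz = np.full(nz, dz)
        wz[[0, -1]] *= 0.5
        area = np.outer(wx, wz)
        grid = cls(x=x, z=z, height=height, nodal_area=area,
                   normal=np.empty((nx, nz, 3)), footprint=(ap_length, ml_width))
        grid.recompute_normals()
        return grid

    # -- derived quantities -------------------------------------------------

    def recompute_normals(self) -> None:
        """Refresh outward unit normals from the current height field."""
        hx, hz = np.gradient(self.height, self.x, self.z)
        inv = 1.0 / np.sqrt(1.0 + hx * hx + hz * hz)
        self.normal = np.stack([-hx * inv, -hz * inv, inv], axis=-1)

    def meshgrid(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.z, indexing="ij")

    @property
    def spacing(self) -> Tuple[float, float]:
        return (float(self.x[1] - self.x[0]), float(self.z[1] - self.z[0]))

    # -- export -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        X, Z = self.meshgrid()
        return pd.DataFrame({
            "x": X.ravel(), "z": Z.ravel(),
            "height": self.height.ravel(), "area": self.nodal_area.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def _vertices_faces(self) -> Tuple[np.ndarray, np.ndarray]:
        X, Z = self.meshgrid()
        verts = np.column_stack([X.ravel(), Z.ravel(), self.height.ravel()])
        nx, nz = self.height.shape
        idx = np.arange(nx * nz).reshape(nx, nz)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[1:, 1:].ravel()
        d = idx[:-1, 1:].ravel()
        faces = np.concatenate([np.column_stack([a, b, c]),
                                np.column_stack([a, c, d])])
        return verts, faces

    def to_trimesh(self):
        import trimesh
        verts, faces = self._vertices_faces()
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    def to_solid_trimesh(self, base_height: float = 0.0):
        """Close the surface into a watertight solid down to ``base_height``."""
        import trimesh
        verts, top = self._vertices_faces()
        n = len(verts)
        bottom_verts = verts.copy()
        bottom_verts[:, 2] = base_height
        nx, nz = self.height.shape
        idx = np.arange(n).reshape(nx, nz)
        # boundary loop (counter-clockwise in plan view)
        loop = np.concatenate([idx[0, :], idx[1:, -1], idx[-1, -2::-1], idx[-2:0:-1, 0]])
        walls = []
        for i in range(len(loop)):
            p, q = loop[i], loop[(i + 1) % len(loop)]
            walls.append([p, q, q + n])
            walls.append([p, q + n, p + n])
        faces = np.concatenate([top, top[:, ::-1] + n, np.asarray(walls)])
        mesh = trimesh.Trimesh(vertices=np.vstack([verts, bottom_verts]),
                               faces=faces, process=True)
        mesh.fix_normals()
        return mesh

    def export_ply(self, path) -> None:
        mesh = self.to_trimesh()
        with open(path, "wb") as fh:
            fh.write(trimesh_export_ply(mesh))

    def export_vtk(self, path) -> None:
        """Write the triangulated surface as ASCII legacy-VTK polydata."""
        verts, faces = self._vertices_faces()
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("ukawear surface\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(verts)} float\n")
            for v in verts:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
            fh.write(f"POINT_DATA {len(verts)}\n")
            fh.write("SCALARS height float 1\nLOOKUP_TABLE default\n")
            for h in self.height.ravel():
                fh.write(f"{h:.6f}\n")


def trimesh_export_ply(mesh) -> bytes:
    return mesh.export(file_type="ply", encoding="ascii")


# ---------------------------------------------------------------------------
# surface factories
# ---------------------------------------------------------------------------

def make_femoral_surface(
    spec: ImplantSpec,
    resolution: float,
    center: Tuple[float, float] = (0.0, 0.0),
    apex_height: float = 0.0,
) -> SurfaceGrid:
    """Biconvex femoral condyle height field.

    The stored height is expressed with the articular prominence positive:
    ``h(x, z) = h0 - sag_s(x) - sag_c(z)`` with apex value ``h0`` at the
    footprint center.  Contact code converts to sagitta via
    ``apex_height - height``.
    """
    rs, rc = spec.femoral_sagittal_radius, spec.femoral_coronal_radius
    if spec.femoral_ap_length / 2.0 > rs:
        raise ValueError("femoral AP half-length exceeds sagittal radius")
    if spec.femoral_ml_width / 2.0 > rc:
        raise ValueError("femoral ML half-width exceeds coronal radius")
    cx, cz = center

    def fn(X, Z):
        return apex_height - _sagitta(X - cx, rs) - _sagitta(Z - cz, rc)

    return SurfaceGrid.from_height_function(
        fn, center, spec.femoral_ap_length, spec.femoral_ml_width, resolution)


def make_insert_surface(
    spec: ImplantSpec,
    resolution: float,
    center: Tuple[float, float] = (0.0, 0.0),
) -> SurfaceGrid:
    """Dished (biconcave) insert articular surface.

    The height field is the material thickness measured from the flat insert
    base at height 0; its minimum over the dish bottom equals
    ``insert_thickness``.
    """
    ris, ric = spec.insert_sagittal_radius, spec.insert_coronal_radius
    if not math.isinf(ris) and spec.insert_ap / 2.0 > ris:
        raise ValueError("insert AP half-length exceeds sagittal radius")
    if not math.isinf(ric) and spec.insert_ml / 2.0 > ric:
        raise ValueError("insert ML half-width exceeds coronal radius")
    cx, cz = center

    def fn(X, Z):
        return spec.insert_thickness + _sagitta(X - cx, ris) + _sagitta(Z - cz, ric)

    return SurfaceGrid.from_height_function(
        fn, center, spec.insert_ap, spec.insert_ml, resolution)


@dataclass
class CompartmentGeometry:
    """One articulation: a rigid analytic femoral condyle over a deformable
    tibial height field resting on an elastic-foundation layer.

    ``datum`` is the vertical offset placing the femoral apex in touching
    contact with the as-built tibial surface minimum at zero approach, so the
    initial apex-aligned gap field is non-negative with minimum zero.  Wear
    deepens the tibial height field; the datum stays fixed, so the gap grows
    where material is removed.
    """

    femoral_surface: SurfaceGrid
    tibial_surface: SurfaceGrid
    layer_thickness: float
    label: str
    femoral_center: Tuple[float, float]
    femoral_radii: Tuple[float, float]          # (sagittal, coronal)
    femoral_halfspan: Tuple[float, float]       # (ap/2, ml/2)
    datum: float = field(default=0.0)
    ie_axis: Tuple[float, float] = (0.0, 0.0)   # vertical axis through tibial control point

    def __post_init__(self) -> None:
        if self.layer_thickness <= 0:
            raise ValueError("layer_thickness must be positive")

    def gap_field(self, ap_translation: float = 0.0, ie_rotation: float = 0.0) -> np.ndarray:
        """Vertical femoral-tibial gap (mm) at every tibial node at zero approach.

        ``ap_translation`` is the anterior tibial translation (mm) and
        ``ie_rotation`` the tibial internal-external rotation (deg) about the
        vertical axis through ``ie_axis``; both move the tibia under the
        fixed femoral condyle.  Nodes outside the femoral footprint map to
        ``inf`` (no contact possible).
        """
        X, Z = self.tibial_surface.meshgrid()
        x0, z0 = self.ie_axis
        th = math.radians(ie_rotation)
        c, s = math.cos(th), math.sin(th)
        # tibial material point expressed in the fixed femoral frame
        xr = c * (X - x0) - s * (Z - z0) + x0 + ap_translation
        zr = s * (X - x0) + c * (Z - z0) + z0
        dx = xr - self.femoral_center[0]
        dz = zr - self.femoral_center[1]
        rs, rc = self.femoral_radii
        half_ap, half_ml = self.femoral_halfspan
        inside = (np.abs(dx) <= half_ap) & (np.abs(dz) <= half_ml)
        sf = (_sagitta(np.clip(dx, -half_ap, half_ap), rs)
              + _sagitta(np.clip(dz, -half_ml, half_ml), rc))
        gap = self.datum + sf - self.tibial_surface.height
        gap = np.where(inside, gap, np.inf)
        return gap


def make_medial_compartment(
    spec: ImplantSpec,
    resolution: float,
    center_z: float = 25.0,
) -> CompartmentGeometry:
    """Medial implant articulation: femoral component over the insert dish.

    ``center_z`` places the compartment center medial (+z) of the joint
    center; the foundation layer is the insert itself (thickness = minimum
    material thickness).
    """
    center = (0.0, center_z)
    fem = make_femoral_surface(spec, resolution, center=center)
    tib = make_insert_surface(spec, resolution, center=center)
    return CompartmentGeometry(
        femoral_surface=fem,
        tibial_surface=tib,
        layer_thickness=spec.insert_thickness,
        label="medial_implant",
        femoral_center=center,
        femoral_radii=(spec.femoral_sagittal_radius, spec.femoral_coronal_radius),
        femoral_halfspan=(spec.femoral_ap_length / 2.0, spec.femoral_ml_width / 2.0),
        datum=spec.insert_thickness,   # analytic dish minimum
    )


@dataclass(frozen=True)
class LateralConfig:
    """Lateral-compartment geometry: native femoral condyle over the tibial
    cartilage surface, with the meniscus folded into an effective extra layer
    thickness.  Radii and footprints are representative of a lateral tibial
    plateau; the dish is much shallower than the implant dish."""

    footprint_ap: float = 40.0
    footprint_ml: float = 26.0
    center_z: float = -25.0
    tibial_sagittal_radius: float = 32.0
    tibial_coronal_radius: float = 24.0
    femoral_sagittal_radius: float = 28.0
    femoral_coronal_radius: float = 22.0
    femoral_ap_length: float = 45.0
    femoral_ml_width: float = 20.0
    cartilage_thickness: float = 3.0
    meniscus_equivalent_thickness: float = 3.0

    def __post_init__(self) -> None:
        if self.cartilage_thickness <= 0:
            raise ValueError("cartilage thickness must be positive")
        if self.meniscus_equivalent_thickness < 0:
            raise ValueError("meniscus_equivalent_thickness must be >= 0")


def make_lateral_cartilage_surface(
    config: LateralConfig | None = None,
    resolution: float = 1.0,
) -> CompartmentGeometry:
    """Lateral tibial cartilage articulation as a CompartmentGeometry.

    The effective foundation layer thickness is the cartilage thickness plus
    the meniscus-equivalent contribution.
    """
    cfg = config or LateralConfig()
    center = (0.0, cfg.center_z)
    layer = cfg.cartilage_thickness + cfg.meniscus_equivalent_thickness
    fem_spec = ImplantSpec(
        femoral_ap_length=cfg.femoral_ap_length,
        femoral_ml_width=cfg.femoral_ml_width,
        femoral_sagittal_radius=cfg.femoral_sagittal_radius,
        femoral_coronal_radius=cfg.femoral_coronal_radius,
        insert_sagittal_radius=max(cfg.tibial_sagittal_radius, cfg.femoral_sagittal_radius),
        insert_coronal_radius=max(cfg.tibial_coronal_radius, cfg.femoral_coronal_radius),
    )
    fem = make_femoral_surface(fem_spec, resolution, center=center)

    def dish(X, Z):
        return (layer + _sagitta(X - center[0], cfg.tibial_sagittal_radius)
                + _sagitta(Z - center[1], cfg.tibial_coronal_radius))

    tib = SurfaceGrid.from_height_function(
        dish, center, cfg.footprint_ap, cfg.footprint_ml, resolution)
    return CompartmentGeometry(
        femoral_surface=fem,
        tibial_surface=tib,
        layer_thickness=layer,
        label="lateral_cartilage",
        femoral_center=center,
        femoral_radii=(cfg.femoral_sagittal_radius, cfg.femoral_coronal_radius),
        femoral_halfspan=(cfg.femoral_ap_length / 2.0, cfg.femoral_ml_width / 2.0),
        datum=layer,                   # analytic dish minimum
    )
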