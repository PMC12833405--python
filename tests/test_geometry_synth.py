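"""Height-field geometry: construction, quadrature, normals, conformity."""

import math

import numpy as np
import pytest

import ukawear as uw
from ukawear.geometry_synth import _sagitta


def sagitta(r, radius):
    return radius - math.sqrt(radius * radius - r * r)


class TestFemoralSurface:
    def test_apex_height_at_center(self, implant_spec):
        spec = uw.ImplantSpec(femoral_sagittal_radius=28.0, femoral_coronal_radius=28.0)
        grid = uw.make_femoral_surface(spec, resolution=2.0, apex_height=3.5)
        i = int(np.argmin(np.abs(grid.x)))
        j = int(np.argmin(np.abs(grid.z)))
        assert grid.x[i] == 0.0 and grid.z[j] == 0.0
        assert grid.height[i, j] == pytest.approx(3.5, abs=1e-12)

    def test_near_flat_radius_bounds_height_drop(self):
        # independent oracle: biaxial sagitta sum at the footprint corner
        spec = uw.ImplantSpec(femoral_sagittal_radius=1000.0, femoral_coronal_radius=1000.0,
                              insert_sagittal_radius=1000.0, insert_coronal_radius=1000.0)
        expected_max_drop = sagitta(22.5, 1000.0) + sagitta(10.0, 1000.0)
        grid = uw.make_femoral_surface(spec, resolution=1.0, apex_height=0.0)
        drop = -grid.height
        assert drop.max() == pytest.approx(expected_max_drop, rel=1e-9)
        assert drop.max() < 0.31

    def test_lattice_node_counts(self, implant_spec):
        grid = uw.make_femoral_surface(implant_spec, resolution=1.0)
        assert grid.height.shape == (46, 21)   # 45 x 20 mm footprint at 1 node/mm

    def test_footprint_exceeding_radius_raises(self):
        spec = uw.ImplantSpec(femoral_sagittal_radius=22.0)  # AP half-length 22.5 > 22
        with pytest.raises(ValueError, match="radius"):
            uw.make_femoral_surface(spec, resolution=1.0)


class TestSurfaceGridInvariants:
    @pytest.mark.parametrize("maker, footprint", [
        (uw.make_femoral_surface, (45.0, 20.0)),
        (uw.make_insert_surface, (41.0, 26.0)),
    ])
    def test_nodal_area_integrates_to_footprint(self, implant_spec, maker, footprint):
        grid = maker(implant_spec, resolution=1.0)
        assert grid.nodal_area.sum() == pytest.approx(footprint[0] * footprint[1],
                                                      rel=1e-3)

    def test_normals_unit_length(self, implant_spec):
        grid = uw.make_insert_surface(implant_spec, resolution=1.0)
        norms = np.linalg.norm(grid.normal, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_heights_analytic_across_resolutions(self, implant_spec):
        coarse = uw.make_insert_surface(implant_spec, resolution=1.0)
        fine = uw.make_insert_surface(implant_spec, resolution=2.0)
        # coarse lattice lines are every second fine lattice line
        assert np.allclose(fine.x[::2], coarse.x)
        assert np.array_equal(fine.height[::2, ::2], coarse.height)


class TestInsertSurface:
    def test_minimum_thickness_is_insert_thickness(self, implant_spec):
        grid = uw.make_insert_surface(implant_spec, resolution=2.0)
        assert grid.height.min() == pytest.approx(8.0, abs=1e-12)

    def test_full_conformity_nests_with_zero_gap(self):
        spec = uw.ImplantSpec(insert_sagittal_radius=28.0, insert_coronal_radius=22.0)
        geom = uw.make_medial_compartment(spec, resolution=1.0)
        gap = geom.gap_field()
        inside = np.isfinite(gap)
        assert inside.any()
        assert np.allclose(gap[inside], 0.0, atol=1e-10)

    def test_flat_insert_gap_equals_femoral_sagitta(self, implant_spec):
        spec = uw.ImplantSpec(insert_sagittal_radius=float("inf"),
                              insert_coronal_radius=float("inf"))
        geom = uw.make_medial_compartment(spec, resolution=2.0)  # apex is a node
        gap = geom.gap_field()
        X, Z = geom.tibial_surface.meshgrid()
        inside = np.isfinite(gap)
        expected = (_sagitta(X - 0.0, 28.0) + _sagitta(Z - 25.0, 22.0))
        assert np.allclose(gap[inside], expected[inside], atol=1e-10)
        assert gap[inside].min() == pytest.approx(0.0, abs=1e-10)

    def test_conformity_monotonicity(self):
        tight = uw.make_medial_compartment(
            uw.ImplantSpec(insert_sagittal_radius=45.0, insert_coronal_radius=30.0), 1.0)
        loose = uw.make_medial_compartment(
            uw.ImplantSpec(insert_sagittal_radius=55.0, insert_coronal_radius=36.0), 1.0)
        g_tight, g_loose = tight.gap_field(), loose.gap_field()
        inside = np.isfinite(g_tight) & (g_tight > 1e-9)
        assert np.all(g_loose[inside] > g_tight[inside])

    def test_invalid_clearance_rejected(self):
        with pytest.raises(ValueError, match="insert_sagittal_radius"):
            uw.ImplantSpec(insert_sagittal_radius=20.0)


class TestLateralCompartment:
    def test_footprint_area_comparable_to_insert(self, implant_spec, lateral_geometry):
        lat_area = lateral_geometry.tibial_surface.nodal_area.sum()
        med_area = implant_spec.insert_ap * implant_spec.insert_ml
        assert 0.7 * med_area <= lat_area <= 1.3 * med_area

    def test_zero_meniscus_contribution(self):
        cfg = uw.LateralConfig(cartilage_thickness=3.0, meniscus_equivalent_thickness=0.0)
        geom = uw.make_lateral_cartilage_surface(cfg, resolution=1.0)
        assert geom.layer_thickness == pytest.approx(3.0)

    def test_symmetric_config_gives_equal_foundation_stiffness(self, cartilage_foundation):
        # mirrored compartment with identical materials and layer: same modulus
        geom = uw.make_lateral_cartilage_surface(uw.LateralConfig(), resolution=1.0)
        k_lat = uw.foundation_modulus(uw.FoundationParams(
            15.0, 0.475, geom.layer_thickness, 0.04))
        k_ref = uw.foundation_modulus(uw.FoundationParams(15.0, 0.475, 6.0, 0.04))
        assert k_lat == pytest.approx(k_ref, rel=1e-12)


class TestExports:
    def test_csv_dump_roundtrips_lattice(self, tmp_path, implant_spec):
        import pandas as pd
        grid = uw.make_insert_surface(implant_spec, resolution=1.0)
        path = tmp_path / "insert.csv"
        grid.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["x", "z", "height", "area"]
        assert len(df) == grid.height.size
        assert df["area"].sum() == pytest.approx(41.0 * 26.0, rel=1e-9)

    def test_ply_and_vtk_exports(self, tmp_path, implant_spec):
        grid = uw.make_insert_surface(implant_spec, resolution=1.0)
        ply, vtk = tmp_path / "s.ply", tmp_path / "s.vtk"
        grid.export_ply(ply)
        grid.export_vtk(vtk)
        assert ply.read_bytes().startswith(b"ply")
        head = vtk.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert "POLYDATA" in head[3]

    def test_solid_mesh_is_watertight_with_correct_volume(self, implant_spec):
        grid = uw.make_insert_surface(implant_spec, resolution=1.0)
        solid = grid.to_solid_trimesh(base_height=0.0)
        assert solid.is_watertight
        expected = float((grid.height * grid.nodal_area).sum())
        assert abs(solid.volume) == pytest.approx(expected, rel=5e-3)
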