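"""Archard wear law, cycle accumulation, adaptive surface update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ukawear as uw
from ukawear.contact import ContactSolution
from ukawear.wear import ThicknessExhaustedError


def flat_insert_geometry(resolution=1.0, ap=19.0, ml=19.0):
    spec = uw.ImplantSpec(
        femoral_ap_length=ap, femoral_ml_width=ml, insert_ap=ap, insert_ml=ml,
        insert_sagittal_radius=float("inf"), insert_coronal_radius=float("inf"),
        femoral_sagittal_radius=1e6, femoral_coronal_radius=1e6)
    return uw.make_medial_compartment(spec, resolution)


def make_solution(pressure, slide):
    return ContactSolution(
        pressure=pressure, contact_area=0.0, peak_pressure=float(pressure.max()),
        total_force=0.0, center_of_pressure=(0.0, 0.0), axial_approach=0.0,
        slide_increment=slide)


class TestArchardLaw:
    def test_reference_depth_increment(self):
        params = uw.ArchardParams()
        assert uw.archard_depth_increment(10.0, 0.01, params) == pytest.approx(
            3.3e-8, rel=1e-12)

    def test_zero_stress_zero_wear(self):
        assert uw.archard_depth_increment(0.0, 5.0, uw.ArchardParams()) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.0, 100.0), st.floats(0.0, 1.0))
    def test_linearity_in_sliding_distance(self, p, s):
        params = uw.ArchardParams()
        assert uw.archard_depth_increment(p, 2.0 * s, params) == pytest.approx(
            2.0 * uw.archard_depth_increment(p, s, params), rel=1e-12, abs=1e-300)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            uw.archard_depth_increment(-1.0, 0.1, uw.ArchardParams())


class TestAccumulateCycle:
    def test_single_increment_single_node(self):
        p = np.zeros((5, 5))
        s = np.zeros((5, 5))
        p[2, 2] = 20.0
        s[2, 2] = 5.0          # mm -> 0.005 m
        depth = uw.accumulate_cycle([make_solution(p, s)], uw.ArchardParams())
        assert depth[2, 2] == pytest.approx(3.3e-7 * 20.0 * 0.005, rel=1e-12)
        assert depth.sum() == pytest.approx(depth[2, 2])

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        sols = [make_solution(rng.uniform(0, 40, (6, 6)), rng.uniform(0, 1, (6, 6)))
                for _ in range(5)]
        d1 = uw.accumulate_cycle(sols, uw.ArchardParams())
        d2 = uw.accumulate_cycle(sols[::-1], uw.ArchardParams())
        assert np.allclose(d1, d2, rtol=1e-12)

    def test_unloaded_cycle_wears_nothing(self):
        zeros = np.zeros((4, 4))
        sols = [make_solution(zeros.copy(), zeros.copy()) for _ in range(10)]
        assert np.all(uw.accumulate_cycle(sols, uw.ArchardParams()) == 0.0)

    def test_inconsistent_node_sets_rejected(self):
        sols = [make_solution(np.zeros((4, 4)), np.zeros((4, 4))),
                make_solution(np.zeros((5, 5)), np.zeros((5, 5)))]
        with pytest.raises(ValueError, match="inconsistent"):
            uw.accumulate_cycle(sols, uw.ArchardParams())


class TestApplyWearStep:
    def test_uniform_recession_removes_slab_volume(self):
        geom = flat_insert_geometry()
        state = uw.WearState.zeros_like(geom)
        params = uw.ArchardParams(cycles_per_step=1.0)
        depth = np.full_like(geom.tibial_surface.height, 0.05)
        uw.apply_wear_step(state, depth, geom, params)
        area = 19.0 * 19.0
        assert state.volume_loss == pytest.approx(0.05 * area, rel=1e-9)

    def test_density_converts_volume_to_mass(self):
        geom = flat_insert_geometry()
        state = uw.WearState.zeros_like(geom)
        params = uw.ArchardParams(cycles_per_step=1.0)
        d = 10.0 / (19.0 * 19.0)     # exactly 10 mm^3 removed
        uw.apply_wear_step(state, np.full_like(geom.tibial_surface.height, d),
                           geom, params)
        assert state.volume_loss == pytest.approx(10.0, rel=1e-9)
        assert state.mass_loss == pytest.approx(9.3, rel=1e-9)
        # exact bookkeeping invariant
        assert state.mass_loss == 0.93 * state.volume_loss

    def test_volume_increment_matches_mesh_volume_oracle(self):
        # independent oracle: watertight-mesh volume difference before/after
        geom = flat_insert_geometry(resolution=1.0, ap=19.0, ml=19.0)
        assert geom.tibial_surface.height.shape == (20, 20)
        before = abs(geom.tibial_surface.to_solid_trimesh().volume)
        X, Z = geom.tibial_surface.meshgrid()
        r2 = X ** 2 + (Z - 25.0) ** 2
        bump = 0.2 * np.exp(-r2 / 18.0)       # interior wear patch
        state = uw.WearState.zeros_like(geom)
        uw.apply_wear_step(state, bump, geom, uw.ArchardParams(cycles_per_step=1.0))
        after = abs(geom.tibial_surface.to_solid_trimesh().volume)
        assert state.volume_loss == pytest.approx(before - after, rel=5e-3)

    def test_wear_through_thickness_raises(self):
        geom = flat_insert_geometry()
        state = uw.WearState.zeros_like(geom)
        depth = np.full_like(geom.tibial_surface.height, 9.0)  # > 8 mm insert
        with pytest.raises(ThicknessExhaustedError):
            uw.apply_wear_step(state, depth, geom, uw.ArchardParams(cycles_per_step=1.0))

    def test_recession_follows_current_normal(self, implant_spec):
        # on a dished surface the vertical drop exceeds the normal recession
        geom = uw.make_medial_compartment(implant_spec, 1.0)
        h_before = geom.tibial_surface.height.copy()
        n_up = geom.tibial_surface.normal[..., 2].copy()
        state = uw.WearState.zeros_like(geom)
        depth = np.full_like(h_before, 0.01)
        uw.apply_wear_step(state, depth, geom, uw.ArchardParams(cycles_per_step=1.0))
        drop = h_before - geom.tibial_surface.height
        assert np.allclose(drop, 0.01 / n_up, atol=1e-12)
        assert np.all(drop >= 0.01 - 1e-12)


class TestWearSchedule:
    def test_zero_steps_leaves_geometry_untouched(self, medial_geometry):
        h0 = medial_geometry.tibial_surface.height.copy()
        calls = []

        def evaluator():
            calls.append(1)
            raise AssertionError("must not evaluate with an empty schedule")

        state, final = uw.run_wear_schedule(
            evaluator, medial_geometry, uw.ArchardParams(n_steps=0))
        assert final is None
        assert state.volume_loss == 0.0
        assert np.array_equal(medial_geometry.tibial_surface.height, h0)
        assert not calls

    def test_mass_loss_non_decreasing_over_steps(self, ukak_result):
        mass = ukak_result.steps["mass_mg"].to_numpy()
        assert np.all(np.diff(mass) >= 0.0)

    def test_wear_centroid_weighted_by_depth(self):
        geom = flat_insert_geometry()
        state = uw.WearState.zeros_like(geom)
        assert np.isnan(uw.wear_centroid(state, geom)[0])
        state.depth[3, 4] = 1.0
        cx, cz = uw.wear_centroid(state, geom)
        assert cx == pytest.approx(float(geom.tibial_surface.x[3]))
        assert cz == pytest.approx(float(geom.tibial_surface.z[4]))
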