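"""Finite-volume conduction: analytic oracles, conservation, physiology."""

import numpy as np
import pytest

from leatherback import presets
from leatherback.heatbalance import (
    CORE_K_ANCHORS,
    BodyMorphometrics,
    BoundaryCondition,
    MaterialProps,
    SolveOptions,
    build_body,
    core_conductivity,
    sensitivity_quadruple_k47,
    solve,
    uniform_sphere,
)

WATER = MaterialProps(density=1000.0, heat_capacity=4000.0, conductivity=0.5)


@pytest.fixture(scope="module")
def juvenile_body(materials):
    return build_body(BodyMorphometrics(), materials=materials)


@pytest.fixture(scope="module")
def steady_19bpm(juvenile_body, metabolic_model):
    bc = presets.boundary_condition("juvenile_19bpm", 24.0)
    return solve(juvenile_body, bc, metabolism=metabolic_model, p_hydro=0.371)


class TestCoreConductivity:
    @pytest.mark.parametrize(
        "t, k", [(17.0, 0.531), (28.0, 0.622), (47.0, 50.0), (22.5, 0.5765)]
    )
    def test_anchor_and_interpolated_values(self, t, k):
        assert core_conductivity(t) == pytest.approx(k, rel=1e-12)

    def test_clamped_outside_anchor_range(self):
        assert core_conductivity(5.0) == 0.531
        assert core_conductivity(60.0) == 50.0

    def test_continuous_and_non_decreasing(self):
        t = np.linspace(0.0, 60.0, 601)
        k = core_conductivity(t)
        assert np.all(np.diff(k) >= 0)
        assert np.max(np.abs(np.diff(k))) < 0.6  # no jumps at 0.1 °C steps


class TestBuildBody:
    def test_sphere_volume_matches_geometry(self):
        r = 0.15
        body = uniform_sphere(r, WATER, n_shells=50)
        assert body.total_volume == pytest.approx(4 / 3 * np.pi * r**3, rel=1e-9)

    def test_juvenile_total_volume(self, juvenile_body):
        assert juvenile_body.total_volume == pytest.approx(0.036, rel=0.01)

    def test_juvenile_mass_from_region_densities(self, juvenile_body):
        assert juvenile_body.mass == pytest.approx(36.9, rel=0.01)

    def test_patch_areas_sum_to_total_surface(self, juvenile_body):
        total = juvenile_body.patch_area("body_surface") + juvenile_body.patch_area(
            "flipper_surface"
        )
        assert total == pytest.approx(0.89, rel=0.01)

    def test_all_regions_present(self, juvenile_body):
        assert set(np.unique(juvenile_body.region)) == {
            "core", "blubber", "che", "flipper",
        }

    def test_inconsistent_morphometrics_rejected(self):
        with pytest.raises(ValueError, match="inconsistent|too large"):
            build_body(BodyMorphometrics(total_surface=0.3))


class TestSolverOracles:
    def test_zero_source_equilibrates_to_water_temperature(self, juvenile_body):
        bc = BoundaryCondition(h_body=300.0, h_flipper=800.0, t_water_c=22.0)
        res = solve(juvenile_body, bc)
        assert np.max(np.abs(res.t_c - 22.0)) < 1e-6

    def test_uniform_source_sphere_matches_analytic_profile(self):
        """Center excess of S·R²/(6k) for a fixed-temperature sphere, ≤1 %."""
        r, k, total_w = 0.1, 0.5, 5.0
        body = uniform_sphere(r, WATER, n_shells=200)
        bc = BoundaryCondition(h_body=1e9, h_flipper=0.0, t_water_c=20.0)
        res = solve(body, bc, uniform_source_w=total_w)
        s_v = total_w / body.total_volume
        rc = body.meta["cell_radius"]
        analytic = 20.0 + s_v * (r**2 - rc**2) / (6 * k)
        center_exact = s_v * r**2 / (6 * k)
        assert res.t_c[0] - 20.0 == pytest.approx(
            analytic[0] - 20.0, rel=0.01
        )
        assert res.t_c[0] - 20.0 == pytest.approx(center_exact, rel=0.01)

    def test_steady_global_energy_balance(self, steady_19bpm):
        res = steady_19bpm
        assert res.boundary_loss == pytest.approx(res.source_total, rel=0.005)

    def test_transient_energy_bookkeeping_closes(self, juvenile_body, metabolic_model):
        bc = presets.boundary_condition("juvenile_25bpm", 20.0)
        res = solve(
            juvenile_body, bc, metabolism=metabolic_model, p_hydro=0.904,
            options=SolveOptions(mode="transient", dt=120.0, t_end=7200.0),
        )
        e = res.energy
        closure = abs(e["stored"] + e["lost"] - e["generated"])
        assert closure <= 0.001 * max(abs(e["generated"]), 1e-12)

    def test_maximum_principle_without_source(self, juvenile_body):
        bc = BoundaryCondition(h_body=300.0, h_flipper=800.0, t_water_c=15.0)
        res = solve(
            juvenile_body, bc,
            options=SolveOptions(mode="transient", dt=300.0, t_end=6000.0,
                                 t_init_c=30.0),
        )
        assert np.all(res.history <= 30.0 + 1e-9)
        assert np.all(res.history >= 15.0 - 1e-9)

    def test_nonconvergence_raises_with_residual(self, juvenile_body, metabolic_model):
        bc = presets.boundary_condition("juvenile_19bpm", 24.0)
        with pytest.raises(RuntimeError, match="residual"):
            solve(
                juvenile_body, bc, metabolism=metabolic_model, p_hydro=0.371,
                options=SolveOptions(max_steps=2, dt0=0.1, dt_growth=1.0),
            )


class TestPhysiologicalBehavior:
    def test_core_warms_with_water_temperature(self, juvenile_body, metabolic_model):
        bc_cold = presets.boundary_condition("juvenile_19bpm", 18.0)
        bc_warm = presets.boundary_condition("juvenile_19bpm", 28.0)
        t_cold = solve(juvenile_body, bc_cold, metabolic_model, 0.371).summary.mean
        t_warm = solve(juvenile_body, bc_warm, metabolic_model, 0.371).summary.mean
        assert t_warm > t_cold

    def test_thicker_blubber_raises_core_excess(self, materials, metabolic_model):
        bc = presets.boundary_condition("juvenile_19bpm", 20.0)
        excess = []
        for t_blub in (0.008, 0.016):
            body = build_body(
                BodyMorphometrics(blubber_thickness=t_blub), materials=materials
            )
            res = solve(body, bc, metabolism=metabolic_model, p_hydro=0.371)
            excess.append(res.summary.mean - 20.0)
        assert excess[1] > excess[0]

    def test_mesh_refinement_changes_mean_below_half_percent(
        self, materials, metabolic_model
    ):
        bc = presets.boundary_condition("juvenile_19bpm", 24.0)
        means = []
        for f in (1, 2):
            body = build_body(
                BodyMorphometrics(
                    n_core_shells=24 * f, n_blubber_shells=6 * f,
                    n_flipper_cells=12 * f,
                ),
                materials=materials,
            )
            means.append(
                solve(body, bc, metabolism=metabolic_model, p_hydro=0.371).summary.mean
            )
        assert abs(means[1] - means[0]) / abs(means[0]) < 0.005

    def test_vasodilation_flattens_core_gradients(self, materials, metabolic_model):
        """With k(T) ramping up when warm, the core spread shrinks vs constant k."""
        bc = presets.boundary_condition("juvenile_29bpm", 28.0)
        body_var = build_body(BodyMorphometrics(), materials=materials)
        const_mats = dict(materials)
        const_mats["core"] = MaterialProps(
            density=1035.0, heat_capacity=4180.0, conductivity=0.531
        )
        body_const = build_body(BodyMorphometrics(), materials=const_mats)
        res_v = solve(body_var, bc, metabolism=metabolic_model, p_hydro=1.418)
        res_c = solve(body_const, bc, metabolism=metabolic_model, p_hydro=1.418)
        spread_v = res_v.summary.max - res_v.summary.min
        spread_c = res_c.summary.max - res_c.summary.min
        assert spread_v < spread_c

    def test_summary_quantiles_ordered(self, steady_19bpm):
        s = steady_19bpm.summary
        assert s.min <= s.q12_5 <= s.q25 <= s.q75 <= s.q87_5 <= s.max
        assert s.min <= s.mean <= s.max


class TestConductivitySensitivity:
    def test_constant_anchors_give_zero_change(self, metabolic_model):
        bc = presets.boundary_condition("juvenile_19bpm", 24.0)
        flat = tuple((t, 0.6) for t, _ in CORE_K_ANCHORS)
        from dataclasses import replace

        from leatherback.heatbalance import CORE

        morph = BodyMorphometrics()
        base = solve(
            build_body(morph, {"core": replace(CORE, conductivity=flat)}),
            bc, metabolism=metabolic_model, p_hydro=0.371,
        )
        quad = solve(
            build_body(morph, {"core": replace(CORE, conductivity=flat)}),
            bc, metabolism=metabolic_model, p_hydro=0.371,
        )
        assert base.summary.mean == pytest.approx(quad.summary.mean, abs=1e-9)

    def test_quadrupling_hot_anchor_changes_core_below_4_percent(
        self, metabolic_model
    ):
        bc = presets.boundary_condition("juvenile_29bpm", 28.0)
        sens = sensitivity_quadruple_k47(bc, metabolic_model, p_hydro=1.418)
        assert 0.0 <= sens["percent_mean_c"] < 4.0
        assert abs(sens["percent_max_c"]) < 4.0
        assert abs(sens["percent_point_c"]) < 4.0

    def test_halving_acts_opposite_or_smaller(self, metabolic_model):
        bc = presets.boundary_condition("juvenile_29bpm", 28.0)
        quad = sensitivity_quadruple_k47(bc, metabolic_model, 1.418, factor=4.0)
        half = sensitivity_quadruple_k47(bc, metabolic_model, 1.418, factor=0.5)
        opposite = np.sign(half["percent_mean_c"]) != np.sign(quad["percent_mean_c"])
        smaller = abs(half["percent_mean_c"]) < abs(quad["percent_mean_c"])
        assert opposite or smaller
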