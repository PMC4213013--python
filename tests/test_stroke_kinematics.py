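"""Stroke kinematics: zone weights, phase angles, rotations, animation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leatherback.meshes import tapered_flipper
from leatherback.stroke import (
    DofWeights,
    StrokePhase,
    StrokeProgram,
    angle_rates,
    animate,
    node_transform,
    phase_angles,
    zone_weights,
)


def still_program(setup: float = 0.0) -> StrokeProgram:
    phases = tuple(
        StrokePhase(name=n, duration=d)
        for n, d in zip(("down", "bottom", "up", "top"), (0.3, 0.2, 0.3, 0.2))
    )
    return StrokeProgram(phases=phases, setup_time=setup)


class TestZoneWeights:
    def test_shoulder_is_motionless(self, juvenile_program):
        w = zone_weights(0.0, juvenile_program)
        assert w.as_matrix().max() == 0.0

    def test_constant_zone_has_full_roll_yaw_pitch_no_bend(self, juvenile_program):
        w = zone_weights(0.45, juvenile_program)
        assert w.roll_w == w.yaw_w == w.pitch_w == 1.0
        assert w.bend_w == 0.0

    def test_linear_ramp_midpoint_of_first_zone(self, juvenile_program):
        w = zone_weights(0.07, juvenile_program)
        assert w.roll_w == pytest.approx(0.5)
        assert w.yaw_w == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_out_of_range_span_rejected(self, bad, juvenile_program):
        with pytest.raises(ValueError):
            zone_weights(bad, juvenile_program)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_weights_monotone_in_span(self, s1, s2):
        from leatherback import presets

        prog = presets.stroke_program("juvenile", bpm=19)
        lo, hi = min(s1, s2), max(s1, s2)
        wl = zone_weights(lo, prog).as_matrix()
        wh = zone_weights(hi, prog).as_matrix()
        assert np.all(wh >= wl - 1e-12)

    @given(st.floats(1e-6, 1.0 - 1e-6))
    def test_weights_continuous_in_span(self, s):
        from leatherback import presets

        prog = presets.stroke_program("juvenile", bpm=19)
        eps = 1e-7
        w0 = zone_weights(max(s - eps, 0.0), prog).as_matrix()
        w1 = zone_weights(min(s + eps, 1.0), prog).as_matrix()
        assert np.max(np.abs(w1 - w0)) < 1e-5


class TestPhaseAngles:
    def test_neonate_phase_amplitudes_accumulate_exactly(self, neonate_program):
        """Each phase accrues exactly its printed net angle."""
        edges = np.cumsum(neonate_program.durations)
        expected = np.cumsum(neonate_program.amplitudes, axis=0)
        for t_end, exp in zip(edges, expected):
            assert phase_angles(t_end, neonate_program) == pytest.approx(
                exp, abs=1e-12
            )

    def test_neonate_down_stroke_roll(self, neonate_program):
        roll = phase_angles(0.384, neonate_program)[0]
        assert roll == pytest.approx(-1.15, abs=1e-9)

    def test_juvenile_returns_to_start_after_one_period(self, juvenile_program):
        a0 = phase_angles(0.0, juvenile_program)
        a1 = phase_angles(juvenile_program.period, juvenile_program)
        assert np.max(np.abs(a1 - a0)) <= 1e-9

    def test_juvenile_down_stroke_roll(self, juvenile_program):
        t_down = juvenile_program.durations[0]
        assert phase_angles(t_down, juvenile_program)[0] == pytest.approx(
            -0.95, abs=1e-9
        )

    def test_angle_rate_continuous_across_phase_boundaries(self, juvenile_program):
        """Cosine blending keeps the angular rate continuous at boundaries."""
        eps = 1e-4
        for t_edge in np.cumsum(juvenile_program.durations)[:-1]:
            r_before = angle_rates(t_edge - eps, juvenile_program)
            r_after = angle_rates(t_edge + eps, juvenile_program)
            steady = np.max(np.abs(juvenile_program.steady_rates()))
            assert np.max(np.abs(r_after - r_before)) < 0.05 * steady

    def test_angles_continuous_across_period_wrap(self, neonate_program):
        """Non-periodic programs keep accumulating instead of jumping back."""
        p = neonate_program.period
        eps = 1e-7
        a0 = phase_angles(p - eps, neonate_program)
        a1 = phase_angles(p + eps, neonate_program)
        assert np.max(np.abs(a1 - a0)) < 1e-4

    def test_negative_time_rejected(self, juvenile_program):
        with pytest.raises(ValueError):
            phase_angles(-0.1, juvenile_program)


class TestNodeTransform:
    def _unit_weights(self, n):
        one = np.ones(n)
        return DofWeights(roll_w=one, yaw_w=one.copy(), pitch_w=one.copy(), bend_w=one.copy())

    def test_zero_angles_is_identity(self, rng):
        p = rng.normal(size=(10, 3))
        w = self._unit_weights(10)
        out = node_transform(p, np.zeros(4), w)
        assert np.allclose(out, p, atol=1e-15)

    def test_pure_roll_matches_explicit_rotation(self):
        """Roll through pi/2 about the swim axis maps +x to +y."""
        w = self._unit_weights(1)
        out = node_transform(np.array([[1.0, 0.0, 0.0]]), [np.pi / 2, 0, 0, 0], w)
        assert np.allclose(out, [[0.0, 1.0, 0.0]], atol=1e-15)

    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=4, max_size=4),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_equal_weights_preserve_pairwise_distance(self, angles, wr, wy, wp, wb):
        p = np.array([[0.3, -0.1, 0.8], [-0.5, 0.2, 0.1]])
        w = DofWeights(
            roll_w=np.full(2, wr), yaw_w=np.full(2, wy),
            pitch_w=np.full(2, wp), bend_w=np.full(2, wb),
        )
        out = node_transform(p, angles, w, bend_hinge=[0.2, 0.0, 0.0])
        d0 = np.linalg.norm(p[0] - p[1])
        d1 = np.linalg.norm(out[0] - out[1])
        assert d1 == pytest.approx(d0, rel=1e-12)

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=4, max_size=4))
    def test_composition_is_orthonormal(self, angles):
        """The linear part of the map has determinant 1 and preserves norms."""
        w = self._unit_weights(4)
        basis = np.vstack([np.zeros(3), np.eye(3)])
        out = node_transform(basis, angles, w)
        lin = (out[1:] - out[0]).T
        assert np.linalg.det(lin) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(lin.T @ lin, np.eye(3), atol=1e-12)


class TestAnimate:
    def test_zero_amplitude_program_is_still(self, small_mesh):
        anim = animate(small_mesh, still_program(), dt=0.05)
        assert np.allclose(anim.velocities, 0.0)
        assert anim.max_step_displacement == 0.0

    def test_neonate_period_is_sum_of_phase_durations(self, neonate_program):
        assert neonate_program.period == pytest.approx(1.243, abs=1e-12)

    def test_juvenile_durations_scale_with_beat_frequency(self, juvenile_program):
        assert juvenile_program.period == pytest.approx(60.0 / 19.0)
        fr = np.array([0.323, 0.170, 0.337, 0.170])
        assert juvenile_program.durations == pytest.approx(fr * 60.0 / 19.0)

    def test_velocities_match_position_central_differences(self, juvenile_program):
        """Central differences of positions converge to the velocities at O(dt²)."""
        mesh = tapered_flipper(n_span=5, n_chord=4)

        def stencil_error(dt):
            anim = animate(mesh, juvenile_program, dt=dt, include_setup=False)
            v_fd = (anim.positions[2:] - anim.positions[:-2]) / (2 * dt)
            return np.abs(anim.velocities[1:-1] - v_fd).max(), np.abs(
                anim.velocities
            ).max()

        err1, vmax = stencil_error(0.005)
        err2, _ = stencil_error(0.0025)
        assert err1 < 0.01 * vmax
        assert err2 < 0.35 * err1  # quadratic, not linear, convergence

    def test_juvenile_pose_periodicity(self, juvenile_program):
        mesh = tapered_flipper(n_span=5, n_chord=4)
        p0 = juvenile_program.period
        anim = animate(
            mesh, juvenile_program, dt=p0, include_setup=False, run_time=p0
        )
        assert np.max(np.abs(anim.positions[-1] - anim.positions[0])) < 1e-9

    def test_body_nodes_never_move(self, small_mesh, juvenile_program):
        anim = animate(
            small_mesh, juvenile_program, dt=0.2, include_setup=False
        )
        still = small_mesh.span_fraction == 0.0
        assert np.allclose(anim.positions[:, still], small_mesh.nodes[still])

    def test_displacement_continuous_in_span(self, juvenile_program):
        """Adjacent spanwise nodes displace nearly identically."""
        mesh = tapered_flipper(n_span=40, n_chord=2)
        anim = animate(mesh, juvenile_program, dt=1.0, include_setup=False,
                       run_time=1.0)
        disp = anim.positions[-1] - mesh.nodes
        mid = np.abs(mesh.nodes[:, 2]) < 1e-9  # centerline nodes
        order = np.argsort(mesh.span_fraction[mid])
        d = disp[mid][order]
        steps = np.linalg.norm(np.diff(d, axis=0), axis=1)
        assert steps.max() < 0.08 * mesh.span_length

    def test_degenerate_mesh_rejected(self, juvenile_program):
        from leatherback.meshes import FlipperMesh

        bad = FlipperMesh(
            nodes=np.zeros((3, 3)),
            faces=np.array([[0, 1, 2]]),
            span_fraction=np.zeros(3),
            part=np.array(["flipper"]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            animate(bad, juvenile_program, dt=0.1)


class TestProgramValidation:
    def test_blend_fraction_bounds(self):
        with pytest.raises(ValueError):
            StrokeProgram(phases=still_program().phases, blend_fraction=0.5)

    def test_fraction_programs_must_sum_to_one(self):
        phases = tuple(
            StrokePhase(name=n, duration=0.3)
            for n in ("down", "bottom", "up", "top")
        )
        with pytest.raises(ValueError, match="summing to 1"):
            StrokeProgram(phases=phases, beat_frequency=19.0)
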