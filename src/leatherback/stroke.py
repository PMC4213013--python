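"""Flipper-stroke kinematics.

A leatherback's flipper beat is described as four phases (down stroke, turn
at the bottom, up stroke, turn at the top), each accruing a printed amount of
roll, pitch, yaw and bend over a printed duration.  The flipper surface is
split spanwise into four zones that progressively activate the degrees of
freedom: the 14 % of span nearest the shoulder ramps roll and yaw in from
zero, the next 22 % ramps pitch in, the next 21 % moves with constant roll,
yaw and pitch, and the outer 43 % additionally ramps in bend.

Node motion composes rotation matrices: roll acts in the global frame, yaw in
the rolled frame, pitch in the rolled-and-yawed frame, and bend in the local
flipper frame about a spanwise hinge.  Axes: +z is the swimming direction
(toward the head), +y dorsal, +x lateral along the extended flipper; roll and
bend rotate about z, yaw about y, pitch about x, all counterclockwise
positive when viewed from the front, bottom and side respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StrokePhase",
    "StrokeProgram",
    "DofWeights",
    "zone_weights",
    "phase_angles",
    "angle_rates",
    "node_transform",
    "animate",
    "Animation",
]

_DOFS = ("roll", "pitch", "yaw", "bend")


@dataclass(frozen=True)
class StrokePhase:
    """One stroke phase: a duration and the net angle accrued per DOF.

    ``duration`` is seconds when the program has no beat frequency, otherwise
    a fraction of the stroke period.  Angles are radians (net accumulated
    over the phase, signed).
    """

    name: str
    duration: float
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    bend: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("down", "bottom", "up", "top"):
            raise ValueError(f"unknown phase name {self.name!r}")
        if not self.duration > 0:
            raise ValueError("phase duration must be positive")
        for dof in _DOFS:
            if not np.isfinite(getattr(self, dof)):
                raise ValueError(f"non-finite {dof} angle in phase {self.name!r}")

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.roll, self.pitch, self.yaw, self.bend])


@dataclass(frozen=True)
class StrokeProgram:
    """A four-phase stroke program with zone bounds and phase blending.

    ``zone_bounds`` are cumulative span fractions delimiting the four
    activation zones (shoulder at span 0).  ``blend_fraction`` is the share
    of each phase spent transitioning from the previous phase's angular
    rate.  With ``beat_frequency`` (beats/minute) set, phase durations are
    fractions of the period 60/BPM; otherwise they are seconds.
    """

    phases: tuple[StrokePhase, ...]
    blend_fraction: float = 0.10
    zone_bounds: tuple[float, float, float, float] = (0.14, 0.36, 0.57, 1.00)
    setup_time: float = 0.0
    beat_frequency: float | None = None
    ramp: str = "linear"  # zone-weight ramp: "linear" or "smoothstep"

    def __post_init__(self) -> None:
        if len(self.phases) != 4:
            raise ValueError("a stroke program has exactly four phases")
        zb = np.asarray(self.zone_bounds, dtype=float)
        if not (np.all(np.diff(zb) > 0) and zb[-1] == 1.0 and zb[0] > 0):
            raise ValueError("zone_bounds must be strictly increasing and end at 1.0")
        if not 0.0 <= self.blend_fraction < 0.5:
            raise ValueError("blend_fraction must lie in [0, 0.5)")
        if self.setup_time < 0:
            raise ValueError("setup_time must be non-negative")
        if self.beat_frequency is not None:
            if not self.beat_frequency > 0:
                raise ValueError("beat_frequency must be positive")
            fr = sum(p.duration for p in self.phases)
            if abs(fr - 1.0) > 1e-9:
                raise ValueError(
                    "phase durations must be fractions summing to 1 when a "
                    f"beat frequency is set (got sum {fr})"
                )
        if self.ramp not in ("linear", "smoothstep"):
            raise ValueError("ramp must be 'linear' or 'smoothstep'")

    @property
    def durations(self) -> np.ndarray:
        """Phase durations in seconds."""
        d = np.array([p.duration for p in self.phases], dtype=float)
        if self.beat_frequency is not None:
            d = d * (60.0 / self.beat_frequency)
        return d

    @property
    def period(self) -> float:
        return float(self.durations.sum())

    @property
    def amplitudes(self) -> np.ndarray:
        """(4 phases, 4 DOFs) signed net angles, DOF order roll/pitch/yaw/bend."""
        return np.stack([p.angles for p in self.phases])

    def with_bpm(self, bpm: float) -> "StrokeProgram":
        return replace(self, beat_frequency=bpm)

    def steady_rates(self) -> np.ndarray:
        """Per-phase steady angular rates (rad/s), shape (4 phases, 4 DOFs).

        Within each phase the angular rate is constant except over the first
        ``blend_fraction`` of the phase, where it eases (cosine) from the
        previous phase's steady rate.  The steady rates solve the cyclic
        linear system that makes each phase accrue exactly its printed net
        angle; cyclic closure also makes the rate periodic and continuous
        across the period wrap.
        """
        d = self.durations
        a = self.amplitudes / d[:, None]  # required mean rates
        b = self.blend_fraction
        if b == 0.0:
            return a
        alpha, beta = b / 2.0, 1.0 - b / 2.0
        # beta * r_i + alpha * r_{i-1} = a_i, indices mod 4
        m = beta * np.eye(4) + alpha * np.roll(np.eye(4), 1, axis=1).T
        return np.linalg.solve(m, a)


@dataclass(frozen=True)
class DofWeights:
    """Per-node activation weights in [0, 1] for each degree of freedom."""

    roll_w: np.ndarray
    yaw_w: np.ndarray
    pitch_w: np.ndarray
    bend_w: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """(N, 4) in DOF order roll/pitch/yaw/bend."""
        return np.stack(
            [self.roll_w, self.pitch_w, self.yaw_w, self.bend_w], axis=-1
        )


def _ramp(x: np.ndarray, kind: str) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    if kind == "smoothstep":
        return x * x * (3.0 - 2.0 * x)
    return x


def zone_weights(span_fraction, program: StrokeProgram) -> DofWeights:
    """Activation weights of each DOF at given span fractions.

    Roll and yaw ramp from 0 to 1 over the shoulder zone, pitch over the
    second zone, and bend over the outer zone; all are 1 past their zone.
    """
    s = np.atleast_1d(np.asarray(span_fraction, dtype=float))
    if np.any((s < 0) | (s > 1)) or not np.all(np.isfinite(s)):
        raise ValueError("span_fraction must lie in [0, 1]")
    z1, z2, z3, _ = program.zone_bounds
    rw = _ramp(s / z1, program.ramp)
    pw = _ramp((s - z1) / (z2 - z1), program.ramp)
    bw = _ramp((s - z3) / (1.0 - z3), program.ramp)
    return DofWeights(roll_w=rw, yaw_w=rw.copy(), pitch_w=pw, bend_w=bw)


def _locate_phase(t: float, program: StrokeProgram) -> tuple[int, float, int]:
    """Return (phase index, time into phase, completed whole periods)."""
    d = program.durations
    edges = np.concatenate([[0.0], np.cumsum(d)])
    period = edges[-1]
    n_cycles, t = (int(t // period), t % period) if t >= period else (0, t)
    i = int(np.searchsorted(edges, t, side="right") - 1)
    i = min(i, 3)
    return i, t - edges[i], n_cycles


def _blend_integral(x: np.ndarray | float) -> np.ndarray | float:
    # integral of the cosine ease (1 - cos(pi u))/2 from 0 to x
    return x / 2.0 - np.sin(np.pi * np.asarray(x)) / (2.0 * np.pi)


def phase_angles(t: float, program: StrokeProgram) -> np.ndarray:
    """Accumulated (roll, pitch, yaw, bend) at time ``t`` into the stroke.

    ``t`` is measured from the start of the stroke proper (after any setup
    time).  Past one period the stroke repeats and angles keep accumulating,
    so the trajectory stays continuous even for programs with a non-zero net
    angle per beat.  Angles are relative to the pose at ``t = 0``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    d = program.durations
    rates = program.steady_rates()
    amps = program.amplitudes
    i, tau, n_cycles = _locate_phase(float(t), program)
    start = n_cycles * amps.sum(axis=0) + amps[:i].sum(axis=0)
    r_prev = rates[(i - 1) % 4]
    r_i = rates[i]
    bd = program.blend_fraction * d[i]
    if bd == 0.0 or tau >= bd:
        blended = r_prev * bd / 2.0 + r_i * bd / 2.0 if bd > 0 else 0.0
        return start + blended + r_i * (tau - bd)
    x = tau / bd
    return start + r_prev * tau + (r_i - r_prev) * bd * _blend_integral(x)


def angle_rates(t: float, program: StrokeProgram) -> np.ndarray:
    """Instantaneous angular rates (rad/s) of the four DOFs at time ``t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    d = program.durations
    rates = program.steady_rates()
    i, tau, _ = _locate_phase(float(t), program)
    r_prev, r_i = rates[(i - 1) % 4], rates[i]
    bd = program.blend_fraction * d[i]
    if bd == 0.0 or tau >= bd:
        return r_i.copy()
    w = (1.0 - np.cos(np.pi * tau / bd)) / 2.0
    return r_prev + (r_i - r_prev) * w


def _rot_x(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)],
        axis=-2,
    )


def _rot_y(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)],
        axis=-2,
    )


def _rot_z(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)],
        axis=-2,
    )


def node_transform(
    nodes: np.ndarray,
    angles: np.ndarray,
    weights: DofWeights,
    bend_hinge: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the weighted roll/yaw/pitch/bend composition to node positions.

    Bend rotates about the z axis through ``bend_hinge`` (the start of the
    bend zone on the flipper long axis) in the local flipper frame; the
    result is then rolled (global z), yawed (rolled frame, y) and pitched
    (rolled-and-yawed frame, x).  The intrinsic sequence is the matrix
    product Rz(roll) @ Ry(yaw) @ Rx(pitch), each angle scaled by the node's
    activation weight.  Nodes sharing identical weights move rigidly.
    """
    p = np.atleast_2d(np.asarray(nodes, dtype=float))
    roll, pitch, yaw, bend = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite([roll, pitch, yaw, bend])):
        raise ValueError("angles must be finite")
    if bend_hinge is None:
        bend_hinge = np.zeros(3)
    h = np.asarray(bend_hinge, dtype=float)

    bent = np.einsum(
        "nij,nj->ni", _rot_z(weights.bend_w * bend), p - h
    ) + h
    rot = (
        _rot_z(weights.roll_w * roll)
        @ _rot_y(weights.yaw_w * yaw)
        @ _rot_x(weights.pitch_w * pitch)
    )
    out = np.einsum("nij,nj->ni", rot, bent)
    return out if np.asarray(nodes).ndim == 2 else out[0]


@dataclass
class Animation:
    """Time-resolved node positions and velocities of an animated mesh."""

    times: np.ndarray  # (T,), seconds from the start of the run (incl. setup)
    positions: np.ndarray  # (T, N, 3) m
    velocities: np.ndarray  # (T, N, 3) m/s
    program: StrokeProgram
    max_step_displacement: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.times)


def animate(
    mesh,
    program: StrokeProgram,
    dt: float,
    run_time: float | None = None,
    include_setup: bool = True,
    velocity_step: float = 1e-5,
) -> Animation:
    """Animate a flipper mesh through the stroke program.

    ``run_time`` defaults to setup time plus one period.  During the setup
    interval the mesh holds the stroke-start pose.  Velocities are central
    differences of the pose at a fine internal step (``velocity_step``),
    independent of ``dt``.
    """
    from .meshes import FlipperMesh  # local import to avoid a cycle

    if dt <= 0:
        raise ValueError("dt must be positive")
    if not isinstance(mesh, FlipperMesh):
        raise TypeError("mesh must be a FlipperMesh")
    mesh.validate()

    setup = program.setup_time if include_setup else 0.0
    if run_time is None:
        run_time = setup + program.period
    times = np.arange(0.0, run_time + dt / 2, dt)
    weights = zone_weights(mesh.span_fraction, program)
    hinge = mesh.bend_hinge(program)

    def pose(t: float) -> np.ndarray:
        ts = max(t - setup, 0.0)
        ang = phase_angles(ts, program)
        return node_transform(mesh.nodes, ang, weights, hinge)

    positions = np.empty((len(times), len(mesh.nodes), 3))
    velocities = np.empty_like(positions)
    for k, t in enumerate(times):
        positions[k] = pose(t)
        if t < setup:  # mesh is frozen during setup
            velocities[k] = 0.0
        else:
            velocities[k] = (
                pose(t + velocity_step) - pose(max(t - velocity_step, setup))
            ) / (velocity_step + min(velocity_step, t - setup))

    max_disp = 0.0
    if len(times) > 1:
        max_disp = float(
            np.max(np.linalg.norm(np.diff(positions, axis=0), axis=-1))
        )
    return Animation(
        times=times,
        positions=positions,
        velocities=velocities,
        program=program,
        max_step_displacement=max_disp,
    )
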