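"""Synthetic surface flow fields standing in for a Navier–Stokes solver.

This module generates per-face pressure, shear and heat-flux fields on the
animated mesh with the qualitative structure of a flapping-flipper flow —
quadratic dynamic pressure on faces moving into the water, an added-mass
pressure term proportional to normal acceleration that spikes at the stroke
turning points, quadratic skin friction along the tangential velocity, and a
speed-dependent convective heat flux that is larger on the fast-moving
flipper than on the body.

It makes no claim of hydrodynamic fidelity: published heat-transfer
coefficients and stroke powers are used as authoritative inputs downstream,
while these fields exist to exercise the surface integrators end to end.
Exact analytic field modes with closed-form integrals are provided for
oracle testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import SurfaceFieldFrame
from .meshes import FlipperMesh, face_geometry

__all__ = ["FlowModelParams", "quasi_steady_fields", "analytic_field", "SEAWATER"]


@dataclass(frozen=True)
class FlowModelParams:
    """Seawater properties and the free coefficients of the synthetic flow.

    Density, specific heat, conductivity and viscosity default to the
    seawater property set used throughout the swimming simulations.  Note
    the viscosity default (9.68e-3 kg/m·s) is carried verbatim from that
    set although it is roughly an order of magnitude above typical seawater
    (~1.1e-3); it only affects the synthetic Reynolds number scale.
    """

    rho: float = 1015.0  # kg/m^3
    specific_heat: float = 4053.0  # J/kg·K
    conductivity: float = 0.6  # W/m·K
    viscosity: float = 9.68e-3  # kg/m·s
    c_pressure: float = 1.0  # dynamic-pressure coefficient
    c_friction: float = 5e-3  # skin-friction coefficient
    c_added_mass: float = 1.0  # added-mass coefficient
    nusselt_coeff: float = 0.0296  # turbulent flat-plate Nu = C Re^m Pr^(1/3)
    nusselt_exp: float = 0.8
    h_floor: float = 50.0  # W/K·m^2, still-water transfer floor
    length_scale: float = 0.1  # m, reference length for Re and added mass
    t_skin: float = 303.15  # K
    t_water: float = 297.15  # K
    noise_sigma: float = 0.0  # relative multiplicative noise on the fields
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho", "specific_heat", "conductivity", "viscosity",
                     "c_pressure", "c_friction", "length_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def prandtl(self) -> float:
        return self.viscosity * self.specific_heat / self.conductivity


SEAWATER = FlowModelParams()


def _face_fields(
    mesh: FlipperMesh, positions: np.ndarray, node_vel: np.ndarray
):
    cen, n, a = face_geometry(positions, mesh.faces)
    v = node_vel[mesh.faces].mean(axis=1)
    return cen, n, a, v


def quasi_steady_fields(
    animation,
    mesh: FlipperMesh,
    params: FlowModelParams = SEAWATER,
    sample_every: float = 0.01,
) -> list[SurfaceFieldFrame]:
    """Synthesize field frames from an animation, sampled every 0.01 s.

    Per face: pressure = ½ρ C_p |v·n| (v·n) + ρ C_am L d(v·n)/dt,
    shear = ½ρ C_f |v_t| v_t, heat flux q = h_loc (T_skin − T_water) with a
    local turbulent flat-plate transfer law h_loc = h0 + C (k/L) Re^0.8
    Pr^{1/3}.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    times = animation.times
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    stride = max(int(round(sample_every / dt)), 1)

    # normal velocity of every face at every step, for the added-mass rate
    n_frames = len(times)
    geom = [
        _face_fields(mesh, animation.positions[k], animation.velocities[k])
        for k in range(n_frames)
    ]
    vn = np.stack([np.einsum("fi,fi->f", g[3], g[1]) for g in geom])
    dvn = np.gradient(vn, times, axis=0) if n_frames > 1 else np.zeros_like(vn)

    pr = params.prandtl
    frames: list[SurfaceFieldFrame] = []
    for k in range(0, n_frames, stride):
        _, n, a, v = geom[k]
        v_n = vn[k]
        p_dyn = 0.5 * params.rho * params.c_pressure * np.abs(v_n) * v_n
        p_am = params.rho * params.c_added_mass * params.length_scale * dvn[k]
        v_t = v - v_n[:, None] * n
        speed_t = np.linalg.norm(v_t, axis=-1)
        tau = 0.5 * params.rho * params.c_friction * speed_t[:, None] * v_t
        speed = np.linalg.norm(v, axis=-1)
        re = params.rho * speed * params.length_scale / params.viscosity
        h_loc = params.h_floor + params.nusselt_coeff * (
            params.conductivity / params.length_scale
        ) * re**params.nusselt_exp * pr ** (1.0 / 3.0)
        q = h_loc * (params.t_skin - params.t_water)
        pressure = p_dyn + p_am
        if params.noise_sigma > 0:
            pressure = pressure * (1 + params.noise_sigma * rng.standard_normal(len(a)))
            tau = tau * (1 + params.noise_sigma * rng.standard_normal((len(a), 1)))
            q = q * (1 + params.noise_sigma * rng.standard_normal(len(a)))
        frames.append(
            SurfaceFieldFrame(
                time=float(times[k]),
                pressure=pressure,
                shear=tau,
                heat_flux=q,
                normal=n,
                area=a,
                part=mesh.part,
                velocity=v,
            )
        )
    return frames


_ANALYTIC_MODES = ("uniform_pressure", "linear_pressure", "uniform_flux", "rigid_rotation")


def analytic_field(
    mesh: FlipperMesh,
    mode: str,
    positions: np.ndarray | None = None,
    magnitude: float = 100.0,
    gradient_axis: int = 2,
    omega=(0.0, 0.0, 1.0),
) -> SurfaceFieldFrame:
    """Exact field modes whose surface integrals have closed forms.

    - ``uniform_pressure``: p = magnitude everywhere; zero net force on a
      closed mesh.
    - ``linear_pressure``: p = magnitude · x_axis; by the divergence theorem
      the net force on a closed mesh is magnitude · volume along the axis
      (the Archimedes identity, exact for flat faces).
    - ``uniform_flux``: q = magnitude; h = q/ΔT on any mesh.
    - ``rigid_rotation``: face velocities ω × r with zero loads.
    """
    if mode not in _ANALYTIC_MODES:
        raise ValueError(f"unknown analytic mode {mode!r}; choose from {_ANALYTIC_MODES}")
    pos = mesh.nodes if positions is None else positions
    cen, n, a = face_geometry(pos, mesh.faces)
    f = len(a)
    zeros, zeros3 = np.zeros(f), np.zeros((f, 3))
    p, q, vel = zeros, zeros, None
    if mode == "uniform_pressure":
        p = np.full(f, magnitude)
    elif mode == "linear_pressure":
        p = magnitude * cen[:, gradient_axis]
    elif mode == "uniform_flux":
        q = np.full(f, magnitude)
    elif mode == "rigid_rotation":
        vel = np.cross(np.asarray(omega, dtype=float), cen)
    return SurfaceFieldFrame(
        time=0.0,
        pressure=p,
        shear=zeros3,
        heat_flux=q,
        normal=n,
        area=a,
        part=mesh.part,
        velocity=vel,
    )
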