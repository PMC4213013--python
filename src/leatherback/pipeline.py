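"""End-to-end pipeline: kinematics → synthetic flow → integrals → heat balance.

The pipeline animates the stroke on a parameterized turtle mesh, synthesizes
surface loads, integrates thrust/power/heat-transfer time series, converts
stroke power to metabolic heat, and solves the internal conduction problem.
Published per-run heat-transfer coefficients and powers from the shipped
presets are the authoritative inputs to the thermal stage; the synthetic
flow exists to exercise the integration chain and its diagnostics are
reported alongside.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import yaml
from pydantic import BaseModel, ConfigDict

from . import bioenergetics as bio
from . import presets
from .heatbalance import BodyMorphometrics, SolveOptions, build_body, solve
from .integrals import integrate_frames, time_average
from .meshes import turtle_mesh
from .stroke import animate
from .synthflow import FlowModelParams, quasi_steady_fields

__all__ = ["PipelineConfig", "run_pipeline"]


class MeshConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    span: float = 0.45  # m
    root_chord: float = 0.18  # m
    thickness: float = 0.02  # m
    n_span: int = 12
    n_chord: int = 6
    body_subdivisions: int = 1


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    run_preset: str = "juvenile_19bpm"  # physical preset with HTCs/power
    t_water_c: float = 24.0
    dt: float = 0.002  # s, kinematic time step
    sample_every: float = 0.01  # s, flow-field sampling cadence
    seed: int = 0
    mesh: MeshConfig = MeshConfig()
    flow: dict = {}  # overrides for FlowModelParams fields
    source_mode: str = "local"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a JSON-serializable run report."""
    report: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "preset": config.run_preset,
        "stages": {},
    }
    phys = presets.load_preset(config.run_preset)

    def stage(name):
        t0 = time.perf_counter()

        def done(**kw):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4), **kw}

        return done

    # --- kinematics -------------------------------------------------------
    end = stage("kinematics")
    program = presets.stroke_program(phys["stroke"], bpm=phys.get("bpm"))
    mesh = turtle_mesh(
        span=config.mesh.span,
        root_chord=config.mesh.root_chord,
        thickness=config.mesh.thickness,
        n_span=config.mesh.n_span,
        n_chord=config.mesh.n_chord,
        body_subdivisions=config.mesh.body_subdivisions,
    )
    anim = animate(mesh, program, dt=config.dt)
    end(
        period_s=program.period,
        setup_s=program.setup_time,
        n_frames=len(anim),
        n_faces=int(len(mesh.faces)),
        max_step_displacement_m=anim.max_step_displacement,
    )

    # --- synthetic flow ---------------------------------------------------
    end = stage("synthetic_flow")
    flow_kwargs = dict(config.flow)
    flow_kwargs.setdefault("seed", config.seed)
    flow_kwargs.setdefault("t_water", config.t_water_c + 273.15)
    flow_kwargs.setdefault("t_skin", config.t_water_c + 273.15 + 2.0)
    params = FlowModelParams(**flow_kwargs)
    frames = quasi_steady_fields(anim, mesh, params, sample_every=config.sample_every)
    end(n_sampled_frames=len(frames))

    # --- surface integrals ------------------------------------------------
    end = stage("integrals")
    series = integrate_frames(
        frames, t_skin=params.t_skin, t_inf=params.t_water
    )
    means = time_average(series, discard_before=program.setup_time)
    end(**{f"mean_{k}": float(v) for k, v in means.items()})

    # --- bioenergetics ----------------------------------------------------
    end = stage("bioenergetics")
    metab = presets.metabolic_model()
    mass = phys["mass"]
    p_hydro = float(phys.get("power", max(means.get("power", 0.0), 0.0)))
    rmr30 = bio.rmr_allometric(mass, metab)
    rmr = bio.boltzmann_scale(
        rmr30, metab.t_ref_k, config.t_water_c + 273.15, metab
    )
    cost, heat = bio.work_energy(p_hydro, metab)
    frac_rmr, frac_work = bio.partition(rmr, cost)
    end(
        mass_kg=mass,
        p_hydro_w=p_hydro,
        rmr30_w=rmr30,
        rmr_at_water_t_w=float(rmr),
        work_cost_w=cost,
        work_heat_w=heat,
        fraction_rmr=frac_rmr,
        fraction_work=frac_work,
    )

    # --- internal conduction ---------------------------------------------
    if "flipper_htc" in phys:
        end = stage("heat_balance")
        bc = presets.boundary_condition(config.run_preset, config.t_water_c)
        body = build_body(BodyMorphometrics(), materials=presets.materials())
        res = solve(
            body,
            bc,
            metabolism=metab,
            p_hydro=p_hydro,
            options=SolveOptions(source_mode=config.source_mode),
        )
        end(
            t_water_c=config.t_water_c,
            h_flipper=bc.h_flipper,
            h_body=bc.h_body,
            converged=res.converged,
            steps=res.steps,
            source_w=res.source_total,
            boundary_loss_w=res.boundary_loss,
            core=res.summary.as_dict(),
        )
        report["core_temperature_c"] = res.summary.as_dict()

    report["inputs"] = {
        k: phys[k]
        for k in ("surface_area", "volume", "mass", "average_thrust",
                  "flipper_htc", "body_htc", "power", "bpm")
        if k in phys
    }

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        series.to_csv(os.path.join(config.out_dir, "series.csv"), index=False)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
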