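"""Preset registry: named stroke programs and physical parameter sets.

Presets carry the printed stroke angles and durations, the published
swimming-simulation outputs (thrusts, powers, heat-transfer coefficients),
material properties and metabolic constants, each with a citation string.
They are frozen: tests pin a checksum that must be bumped together with the
``version`` field on any edit.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import yaml

from .bioenergetics import MetabolicModel
from .heatbalance import BoundaryCondition, MaterialProps
from .stroke import StrokePhase, StrokeProgram

__all__ = [
    "load_preset",
    "available_presets",
    "stroke_program",
    "boundary_condition",
    "metabolic_model",
    "materials",
    "preset_checksum",
]

_FILES = ("strokes.yaml", "physical.yaml")


@lru_cache(maxsize=None)
def _registry() -> dict:
    reg: dict = {}
    for fname in _FILES:
        text = resources.files("leatherback").joinpath("_data", fname).read_text()
        data = yaml.safe_load(text)
        data.pop("version", None)
        for key, val in data.items():
            if key in reg:
                # stroke and physical presets may share a turtle name; their
                # fields are disjoint apart from the citation string
                for sub, v in val.items():
                    if sub in reg[key] and sub != "citation":
                        raise RuntimeError(
                            f"conflicting field {sub!r} in preset {key!r}"
                        )
                    if sub == "citation" and "citation" in reg[key]:
                        v = reg[key]["citation"] + " " + v
                    reg[key][sub] = v
            else:
                reg[key] = dict(val)
    return reg


def available_presets() -> list[str]:
    return sorted(_registry())


def load_preset(name: str) -> dict:
    """Return a preset's raw (validated) parameter dictionary."""
    reg = _registry()
    if name not in reg:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name]


def preset_checksum() -> str:
    """SHA-256 over the canonical serialization of all shipped presets."""
    blob = yaml.safe_dump(_registry(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def stroke_program(name: str, bpm: float | None = None) -> StrokeProgram:
    """Build a :class:`StrokeProgram` from a stroke preset.

    For fraction-based programs (juvenile) a beat frequency is required.
    """
    p = load_preset(name)
    if "phases" not in p:
        raise KeyError(f"preset {name!r} is not a stroke program")
    phases = tuple(
        StrokePhase(
            name=ph["name"],
            duration=ph["duration"],
            roll=ph["roll"],
            pitch=ph["pitch"],
            yaw=ph["yaw"],
            bend=ph["bend"],
        )
        for ph in p["phases"]
    )
    fractions = p.get("durations_are_fractions", False)
    if fractions and bpm is None:
        raise ValueError(
            f"stroke preset {name!r} uses phase fractions; a beat frequency "
            "(bpm) is required"
        )
    return StrokeProgram(
        phases=phases,
        blend_fraction=p.get("blend_fraction", 0.10),
        setup_time=p.get("setup_time", 0.0),
        beat_frequency=bpm if fractions else None,
    )


def boundary_condition(name: str, t_water_c: float) -> BoundaryCondition:
    """Convective boundary condition from a physical run preset."""
    p = load_preset(name)
    if "flipper_htc" not in p:
        raise KeyError(f"preset {name!r} carries no heat-transfer coefficients")
    return BoundaryCondition(
        h_body=p["body_htc"], h_flipper=p["flipper_htc"], t_water_c=t_water_c
    )


def metabolic_model() -> MetabolicModel:
    """The default, citation-backed metabolic model."""
    p = load_preset("metabolism")
    return MetabolicModel(
        allometric_scale=p["allometric_scale"],
        allometric_exponent=p["allometric_exponent"],
        activation_energy=p["activation_energy"],
        t_ref_c=p["reference_temperature_c"],
        efficiency=p["aerobic_efficiency"],
        citation=p["citation"],
    )


def materials() -> dict[str, MaterialProps]:
    """Region materials from the shipped property preset."""
    p = load_preset("materials")
    core = p["core"]
    return {
        "blubber": MaterialProps(**p["blubber"]),
        "che": MaterialProps(**p["che"]),
        "core": MaterialProps(
            density=core["density"],
            heat_capacity=core["heat_capacity"],
            conductivity=tuple(tuple(a) for a in core["conductivity_anchors"]),
        ),
        "flipper": MaterialProps(
            density=core["density"], heat_capacity=core["heat_capacity"],
            conductivity=0.622,
        ),
    }
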