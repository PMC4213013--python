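"""Metabolic heat production of a swimming turtle.

Resting metabolic rate (RMR) follows a mass allometry for the per-mass rate
at 30 °C,

    M(30 °C) = a · m^b   [W/kg],  whole-body RMR = m · M(30 °C),

scaled to other core temperatures by a Boltzmann–Arrhenius factor

    M(T) = M(T_ref) · exp[(E/K)(1/T_ref − 1/T)],

with activation energy E = 0.76 eV and K = 8.617×10⁻⁵ eV/K.  The metabolic
cost of flipper movement converts the hydrodynamic power P the flipper puts
into the water through a muscle aerobic efficiency η = 0.35: cost = P/η.
How much of that cost ends up as internal heat is configurable: either all
of it (``all_internal``) or the cost net of the external work, P/η − P
(``net_of_external_work``, the default — useful work leaves the body into
the water).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MetabolicModel",
    "rmr_allometric",
    "boltzmann_scale",
    "work_energy",
    "partition",
    "celsius_to_kelvin",
]

BOLTZMANN_EV = 8.617e-5  # eV/K


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


@dataclass(frozen=True)
class MetabolicModel:
    """Allometric and thermal parameters of the metabolic rate.

    ``allometric_scale`` (W/kg at mass 1 kg) and ``allometric_exponent``
    (per-mass exponent; −0.25 corresponds to whole-body ∝ m^0.75) have no
    defaults: the allometry must be supplied with a citation-backed value.
    """

    allometric_scale: float | None = None  # a, W/kg
    allometric_exponent: float | None = None  # b, dimensionless
    activation_energy: float = 0.76  # eV
    boltzmann: float = BOLTZMANN_EV  # eV/K
    t_ref_c: float = 30.0  # °C reference for the allometry
    efficiency: float = 0.35  # aerobic efficiency of the muscle
    work_heat_mode: str = "net_of_external_work"  # or "all_internal"
    citation: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("aerobic efficiency must lie in (0, 1]")
        if not self.activation_energy > 0:
            raise ValueError("activation energy must be positive")
        if self.work_heat_mode not in ("all_internal", "net_of_external_work"):
            raise ValueError("unknown work_heat_mode")

    @property
    def t_ref_k(self) -> float:
        return self.t_ref_c + 273.15

    def configured(self, **kw) -> "MetabolicModel":
        return replace(self, **kw)


def rmr_allometric(mass: float, model: MetabolicModel) -> float:
    """Whole-body resting metabolic rate at the 30 °C reference, W."""
    if not mass > 0:
        raise ValueError("mass must be positive")
    if model.allometric_scale is None or model.allometric_exponent is None:
        raise ValueError(
            "allometric coefficients are not configured; supply citation-backed "
            "values for the per-mass rate a·m^b (W/kg) before computing RMR"
        )
    return mass * model.allometric_scale * mass**model.allometric_exponent


def boltzmann_scale(m_ref: float, t_ref_k, t_k, model: MetabolicModel):
    """Metabolic rate at temperature ``t_k`` given its value at ``t_ref_k``.

    Temperatures in Kelvin.  Strictly increasing in T.  Accepts arrays.
    """
    t_ref_k = np.asarray(t_ref_k, dtype=float)
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_ref_k <= 0) or np.any(t_k <= 0):
        raise ValueError("absolute temperatures must be positive")
    ek = model.activation_energy / model.boltzmann
    out = m_ref * np.exp(ek * (1.0 / t_ref_k - 1.0 / t_k))
    return float(out) if out.ndim == 0 else out


def work_energy(p_hydro: float, model: MetabolicModel) -> tuple[float, float]:
    """(metabolic cost, internal heat) in W of producing hydrodynamic power.

    cost = P/η; internal heat is the cost (``all_internal``) or the cost
    minus the external work P (``net_of_external_work``).
    """
    if p_hydro < 0:
        raise ValueError("hydrodynamic power must be non-negative")
    cost = p_hydro / model.efficiency
    heat = cost if model.work_heat_mode == "all_internal" else cost - p_hydro
    return cost, heat


def partition(rmr: float, metabolic_cost: float) -> tuple[float, float]:
    """Fractions (RMR share, work-energy share) of the total metabolic rate."""
    if rmr < 0 or metabolic_cost < 0:
        raise ValueError("rates must be non-negative")
    total = rmr + metabolic_cost
    if total == 0:
        raise ValueError("RMR and work cost are both zero; no partition exists")
    return rmr / total, metabolic_cost / total
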