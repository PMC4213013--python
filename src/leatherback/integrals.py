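"""Surface integrals of flow loads: thrust, power and heat-transfer coefficients.

Instantaneous thrust is the surface integral of the swimming-direction
component of the traction (pressure plus shear) over flipper and body;
power is the traction–velocity product integrated over the flipper alone;
the convective heat-transfer coefficient h of a part is its area-averaged
heat flux divided by the skin–water temperature difference:

    F_z = sum_faces (p n + tau) . e_z  A
    P   = sum_flipper (p n + tau) . v  A
    h   = (1/A_part) sum_part  q / (T_skin - T_inf)  A

Integration is per-face with face-centroid values (finite-volume surface
quadrature).  Sign conventions: thrust positive along the swimming
direction, power positive when the flipper does work on the water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceFieldFrame",
    "thrust",
    "power",
    "htc",
    "integrate_frames",
    "time_average",
]


@dataclass
class SurfaceFieldFrame:
    """Per-face flow quantities on the surface at one instant."""

    time: float  # s
    pressure: np.ndarray  # (F,) Pa
    shear: np.ndarray  # (F, 3) Pa
    heat_flux: np.ndarray  # (F,) W/m^2, positive out of the animal
    normal: np.ndarray  # (F, 3) outward unit normals
    area: np.ndarray  # (F,) m^2
    part: np.ndarray  # (F,) str, "flipper" or "body"
    velocity: np.ndarray | None = None  # (F, 3) m/s surface velocity

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.shear = np.asarray(self.shear, dtype=float)
        self.heat_flux = np.asarray(self.heat_flux, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.part = np.asarray(self.part)
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
        f = len(self.pressure)
        shapes_ok = (
            self.shear.shape == (f, 3)
            and self.heat_flux.shape == (f,)
            and self.normal.shape == (f, 3)
            and self.area.shape == (f,)
            and self.part.shape == (f,)
            and (self.velocity is None or self.velocity.shape == (f, 3))
        )
        if not shapes_ok:
            raise ValueError("field arrays must share one face count")
        if np.any(self.area <= 0):
            raise ValueError("face areas must be positive")
        norms = np.linalg.norm(self.normal, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("normals must be unit length")

    def traction(self) -> np.ndarray:
        """(F, 3) surface traction p·n + τ."""
        return self.pressure[:, None] * self.normal + self.shear

    def mask(self, part: str | None) -> np.ndarray:
        if part is None:
            return np.ones(len(self.area), dtype=bool)
        m = self.part == part
        if not m.any():
            raise ValueError(f"no faces labeled {part!r}")
        return m


def thrust(frame: SurfaceFieldFrame, swim_axis=(0.0, 0.0, 1.0)) -> float:
    """Instantaneous force along the swimming direction, N (flipper + body)."""
    axis = np.asarray(swim_axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("swim_axis must be a unit vector")
    return float(np.sum((frame.traction() @ axis) * frame.area))


def power(frame: SurfaceFieldFrame) -> float:
    """Instantaneous power the flipper puts into the water, W."""
    if frame.velocity is None:
        raise ValueError("frame carries no velocity field; power needs it")
    m = frame.mask("flipper")
    return float(
        np.sum(
            np.einsum("fi,fi->f", frame.traction()[m], frame.velocity[m])
            * frame.area[m]
        )
    )


def htc(frame: SurfaceFieldFrame, t_skin: float, t_inf: float, part: str) -> float:
    """Area-averaged convective heat-transfer coefficient of a part, W/K·m²."""
    if t_skin == t_inf:
        raise ZeroDivisionError(
            "skin and free-stream temperatures are equal; h = q/(T_skin - T_inf) "
            "is undefined"
        )
    m = frame.mask(part)
    a = frame.area[m]
    return float(np.sum(frame.heat_flux[m] * a) / (a.sum() * (t_skin - t_inf)))


def integrate_frames(
    frames,
    swim_axis=(0.0, 0.0, 1.0),
    t_skin: float = 303.15,
    t_inf: float = 297.15,
) -> pd.DataFrame:
    """Thrust/power/h time series over a sequence of field frames."""
    rows = []
    for fr in frames:
        rows.append(
            {
                "time": fr.time,
                "thrust": thrust(fr, swim_axis),
                "power": power(fr) if fr.velocity is not None else np.nan,
                "h_flipper": htc(fr, t_skin, t_inf, "flipper"),
                "h_body": htc(fr, t_skin, t_inf, "body")
                if (fr.part == "body").any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def time_average(series: pd.DataFrame, discard_before: float = 0.0) -> pd.Series:
    """Arithmetic mean of each channel after discarding an initial window."""
    kept = series[series["time"] >= discard_before]
    if kept.empty:
        raise ValueError(
            f"no samples at or after t = {discard_before}; cannot average"
        )
    return kept.drop(columns="time").mean()


def frame_to_csv(frame: SurfaceFieldFrame, path: str) -> None:
    """Write one field frame as tidy CSV (one row per face)."""
    df = pd.DataFrame(
        {
            "face_id": np.arange(len(frame.area)),
            "time": frame.time,
            "p": frame.pressure,
            "tau_x": frame.shear[:, 0],
            "tau_y": frame.shear[:, 1],
            "tau_z": frame.shear[:, 2],
            "q": frame.heat_flux,
            "n_x": frame.normal[:, 0],
            "n_y": frame.normal[:, 1],
            "n_z": frame.normal[:, 2],
            "area": frame.area,
            "part": frame.part,
        }
    )
    if frame.velocity is not None:
        df[["v_x", "v_y", "v_z"]] = frame.velocity
    df.to_csv(path, index=False)


def frame_from_csv(path: str) -> SurfaceFieldFrame:
    df = pd.read_csv(path)
    vel = (
        df[["v_x", "v_y", "v_z"]].to_numpy()
        if {"v_x", "v_y", "v_z"} <= set(df.columns)
        else None
    )
    return SurfaceFieldFrame(
        time=float(df["time"].iloc[0]),
        pressure=df["p"].to_numpy(),
        shear=df[["tau_x", "tau_y", "tau_z"]].to_numpy(),
        heat_flux=df["q"].to_numpy(),
        normal=df[["n_x", "n_y", "n_z"]].to_numpy(),
        area=df["area"].to_numpy(),
        part=df["part"].to_numpy(),
        velocity=vel,
    )
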