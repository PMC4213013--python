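"""Triangulated turtle surface meshes.

The anatomical NURBS models behind the original simulations are not
available, so meshes here are parameterized idealizations: the flipper is a
tapered, elliptically-thick plate extending laterally (+x) from the shoulder,
the body an ellipsoid.  Spanwise position (``span_fraction``, 0 at the
shoulder, 1 at the tip) drives the zone-weighted stroke kinematics; body
nodes carry span 0 and therefore never move.

OBJ/STL input and output go through :mod:`trimesh`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh


@dataclass
class FlipperMesh:
    """A surface mesh with per-node span fractions and per-face part labels.

    ``part`` entries are ``"flipper"`` or ``"body"``.
    """

    nodes: np.ndarray  # (N, 3) m, body frame; shoulder at the origin
    faces: np.ndarray  # (F, 3) int node indices
    span_fraction: np.ndarray  # (N,) in [0, 1]
    part: np.ndarray  # (F,) str
    span_length: float = 0.0  # m, shoulder to tip along +x

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.span_fraction = np.asarray(self.span_fraction, dtype=float)
        self.part = np.asarray(self.part)
        if self.span_length == 0.0 and len(self.nodes):
            self.span_length = float(self.nodes[:, 0].max())

    def validate(self) -> None:
        if len(self.faces) == 0 or len(self.nodes) == 0:
            raise ValueError("degenerate mesh: no nodes or faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.nodes):
            raise ValueError("faces reference invalid node indices")
        if np.any((self.span_fraction < 0) | (self.span_fraction > 1)):
            raise ValueError("span_fraction must lie in [0, 1]")
        if len(self.part) != len(self.faces):
            raise ValueError("one part label per face required")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("degenerate mesh: non-finite node positions")
        if np.any(face_areas(self.nodes, self.faces) <= 0):
            raise ValueError("degenerate mesh: zero-area faces")

    def bend_hinge(self, program) -> np.ndarray:
        """Hinge point of the bend DOF: start of the outermost zone."""
        return np.array([program.zone_bounds[2] * self.span_length, 0.0, 0.0])

    @property
    def n_flipper_faces(self) -> int:
        return int(np.sum(self.part == "flipper"))

    def as_trimesh(self, positions: np.ndarray | None = None) -> trimesh.Trimesh:
        p = self.nodes if positions is None else positions
        return trimesh.Trimesh(vertices=p, faces=self.faces, process=False)


def face_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[faces[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


def face_geometry(
    nodes: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-face (centroid, outward unit normal, area) for given positions."""
    a, b, c = (nodes[faces[:, k]] for k in range(3))
    cen = (a + b + c) / 3.0
    cr = np.cross(b - a, c - a)
    nrm = np.linalg.norm(cr, axis=-1)
    n = cr / np.where(nrm > 0, nrm, 1.0)[:, None]
    return cen, n, 0.5 * nrm


def tapered_flipper(
    span: float = 0.45,
    root_chord: float = 0.18,
    thickness: float = 0.02,
    n_span: int = 14,
    n_chord: int = 8,
    taper: float = 0.75,
) -> FlipperMesh:
    """A tapered plate flipper with elliptic thickness, closed at the rim.

    The flipper lies in the x–z plane (span along +x, chord along z, the
    swimming direction), thickness along y.  Chord shrinks linearly by
    ``taper`` toward the tip.  Nodes on the rim are shared between the upper
    and lower surfaces, so the mesh closes.
    """
    xi = np.linspace(0.0, 1.0, n_span + 1)
    eta = np.linspace(-1.0, 1.0, n_chord + 1)
    verts: list[np.ndarray] = []
    span_fr: list[float] = []
    top_idx = np.full((n_span + 1, n_chord + 1), -1, dtype=int)
    bot_idx = np.full_like(top_idx, -1)
    for i, u in enumerate(xi):
        chord = root_chord * (1.0 - taper * u)
        for j, v in enumerate(eta):
            x = u * span
            z = 0.5 * chord * v
            # elliptic thickness, zero on the rim (chord edges and tip)
            h = 0.5 * thickness * np.sqrt(max(1.0 - v * v, 0.0)) * np.sqrt(
                max(1.0 - u * u, 0.0)
            )
            verts.append(np.array([x, h, z]))
            span_fr.append(u)
            top_idx[i, j] = len(verts) - 1
            if h > 0.0:
                verts.append(np.array([x, -h, z]))
                span_fr.append(u)
                bot_idx[i, j] = len(verts) - 1
            else:
                bot_idx[i, j] = top_idx[i, j]
    faces: list[tuple[int, int, int]] = []
    for i in range(n_span):
        for j in range(n_chord):
            t00, t01 = top_idx[i, j], top_idx[i, j + 1]
            t10, t11 = top_idx[i + 1, j], top_idx[i + 1, j + 1]
            faces += [(t00, t10, t11), (t00, t11, t01)]
            b00, b01 = bot_idx[i, j], bot_idx[i, j + 1]
            b10, b11 = bot_idx[i + 1, j], bot_idx[i + 1, j + 1]
            if (b00, b01, b10, b11) != (t00, t01, t10, t11):
                faces += [(b00, b11, b10), (b00, b01, b11)]
    faces_arr = np.array(faces, dtype=int)
    keep = face_areas(np.array(verts), faces_arr) > 1e-14
    faces_arr = faces_arr[keep]
    return FlipperMesh(
        nodes=np.array(verts),
        faces=faces_arr,
        span_fraction=np.array(span_fr),
        part=np.array(["flipper"] * len(faces_arr)),
        span_length=span,
    )


def ellipsoid_body(
    length: float = 0.72,
    width: float = 0.40,
    height: float = 0.26,
    subdivisions: int = 2,
    offset: np.ndarray | None = None,
) -> FlipperMesh:
    """An ellipsoidal body shell (rigid; all span fractions zero)."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = sphere.vertices * np.array([width / 2, height / 2, length / 2])
    if offset is not None:
        v = v + np.asarray(offset)
    return FlipperMesh(
        nodes=v,
        faces=np.array(sphere.faces, dtype=int),
        span_fraction=np.zeros(len(v)),
        part=np.array(["body"] * len(sphere.faces)),
        span_length=0.0,
    )


def turtle_mesh(
    span: float = 0.45,
    root_chord: float = 0.18,
    thickness: float = 0.02,
    body_length: float = 0.72,
    body_width: float = 0.40,
    body_height: float = 0.26,
    n_span: int = 14,
    n_chord: int = 8,
    body_subdivisions: int = 2,
) -> FlipperMesh:
    """Combined flipper + body mesh with the shoulder at the origin.

    The body sits inboard of the flipper (centered at −x), mimicking the
    flipper emerging from the shoulder.  Body faces are labeled ``body``
    and never move.
    """
    fl = tapered_flipper(span, root_chord, thickness, n_span, n_chord)
    body = ellipsoid_body(
        body_length,
        body_width,
        body_height,
        body_subdivisions,
        offset=np.array([-body_width / 2, 0.0, 0.0]),
    )
    n0 = len(fl.nodes)
    mesh = FlipperMesh(
        nodes=np.vstack([fl.nodes, body.nodes]),
        faces=np.vstack([fl.faces, body.faces + n0]),
        span_fraction=np.concatenate([fl.span_fraction, body.span_fraction]),
        part=np.concatenate([fl.part, body.part]),
        span_length=span,
    )
    return mesh


def save_mesh(mesh: FlipperMesh, path: str, positions: np.ndarray | None = None) -> None:
    """Write to OBJ or STL (by extension) via trimesh."""
    mesh.as_trimesh(positions).export(path)


def load_mesh(path: str, part: str = "flipper", span_axis: int = 0) -> FlipperMesh:
    """Read an OBJ/STL surface; span fractions from extent along ``span_axis``."""
    tm = trimesh.load(path, force="mesh")
    coords = np.asarray(tm.vertices[:, span_axis], dtype=float)
    lo, hi = coords.min(), coords.max()
    span = np.zeros_like(coords) if hi == lo else (coords - lo) / (hi - lo)
    return FlipperMesh(
        nodes=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=int),
        span_fraction=span,
        part=np.array([part] * len(tm.faces)),
        span_length=float(hi - lo),
    )


def export_animation_obj(mesh: FlipperMesh, animation, out_dir: str) -> list[str]:
    """Write one numbered OBJ per frame; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k in range(len(animation)):
        p = os.path.join(out_dir, f"frame_{k:05d}.obj")
        save_mesh(mesh, p, positions=animation.positions[k])
        paths.append(p)
    return paths
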