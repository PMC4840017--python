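"""Canonical scalp surfaces and channel placement.

Two representations of the scalp are supported: a planar circular grid in the
spirit of 10-20 topographic displays (azimuthal-equidistant projection about
the vertex) and a spherical triangular mesh (subdivided icosahedron).  Channel
positions are given in MNI mm; a head sphere is fitted (or supplied) and
channels are projected radially onto it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ProbeLayout",
    "ScalpGrid2D",
    "ScalpMesh",
    "fit_head_sphere",
    "make_canonical_mesh",
    "project_channels_sphere",
    "project_channels_disc",
    "disc_to_sphere",
    "make_search_mask",
]


@dataclass
class ProbeLayout:
    """Optode/channel geometry in MNI coordinates [mm].

    A channel is the midpoint measurement site between one source and one
    detector; when ``channel_pairs`` are given and ``channel_pos`` is not,
    midpoints are filled in automatically.
    """

    source_pos: np.ndarray | None = None
    detector_pos: np.ndarray | None = None
    channel_pairs: list[tuple[int, int]] | None = None
    channel_pos: np.ndarray | None = None
    channel_ids: list[str] = field(default_factory=list)
    separation: float = 3.0  # cm

    def __post_init__(self) -> None:
        for name in ("source_pos", "detector_pos", "channel_pos"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.atleast_2d(np.asarray(v, dtype=float)))
        if self.channel_pos is None:
            if self.channel_pairs is None:
                raise ValueError("need channel_pos or channel_pairs")
            self.channel_pos = np.array(
                [
                    0.5 * (self.source_pos[s] + self.detector_pos[d])
                    for s, d in self.channel_pairs
                ]
            )
        elif self.channel_pairs is not None:
            mid = np.array(
                [
                    0.5 * (self.source_pos[s] + self.detector_pos[d])
                    for s, d in self.channel_pairs
                ]
            )
            if np.max(np.linalg.norm(mid - self.channel_pos, axis=1)) > 1.0:
                raise ValueError(
                    "channel_pos deviates more than 1 mm from source/detector midpoints"
                )
        if not self.channel_ids:
            self.channel_ids = [f"CH{j + 1}" for j in range(len(self.channel_pos))]
        if len(self.channel_ids) != len(self.channel_pos):
            raise ValueError("channel_ids must match channel_pos")

    @property
    def n_channels(self) -> int:
        return len(self.channel_pos)

    def to_tsv(self, path) -> None:
        rows = []
        for i, p in enumerate(self.source_pos if self.source_pos is not None else []):
            rows.append((f"S{i + 1}", "source", *p))
        for i, p in enumerate(self.detector_pos if self.detector_pos is not None else []):
            rows.append((f"D{i + 1}", "detector", *p))
        for cid, p in zip(self.channel_ids, self.channel_pos):
            rows.append((cid, "channel", *p))
        pd.DataFrame(rows, columns=["label", "type", "x", "y", "z"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, separation: float = 3.0) -> "ProbeLayout":
        df = pd.read_csv(path, sep="\t")
        ch = df[df["type"] == "channel"]
        src = df[df["type"] == "source"]
        det = df[df["type"] == "detector"]
        return cls(
            source_pos=src[["x", "y", "z"]].to_numpy(float) if len(src) else None,
            detector_pos=det[["x", "y", "z"]].to_numpy(float) if len(det) else None,
            channel_pos=ch[["x", "y", "z"]].to_numpy(float),
            channel_ids=[str(s) for s in ch["label"]],
            separation=separation,
        )


def fit_head_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere (center [mm], radius [mm]) through points.

    Linearises ||p - c||^2 = R^2 as 2 c.p + (R^2 - ||c||^2) = ||p||^2.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = np.sum(p**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


@dataclass
class ScalpGrid2D:
    """Square pixel grid over the circular 10-20 disc.

    ``extent`` is the disc radius in mm; pixels outside the disc are masked.
    """

    n: int = 64
    extent: float = 130.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 16:
            raise ValueError("grid must be at least 16 pixels per side")
        if self.mask is None:
            xx, yy = self.pixel_centers()
            self.mask = xx**2 + yy**2 <= self.extent**2
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n, self.n):
            raise ValueError("mask shape must be (n, n)")

    @property
    def pixel_size(self) -> float:
        return 2.0 * self.extent / self.n

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ps = 2.0 * self.extent / self.n
        coords = -self.extent + ps * (np.arange(self.n) + 0.5)
        return np.meshgrid(coords, coords, indexing="ij")


@dataclass
class ScalpMesh:
    """Spherical triangular mesh of the canonical scalp.

    ``vertices`` are unit vectors; physical coordinates are
    ``radius * vertices + center``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    radius: float = 85.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    channel_vertex_map: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        norms = np.linalg.norm(self.vertices, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("mesh vertices must be unit-norm")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def scaled_vertices(self) -> np.ndarray:
        return self.center + self.radius * self.vertices

    def edges(self) -> np.ndarray:
        """Unique undirected edges [E x 2]."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        """Planar triangle areas [mm^2] of the scaled mesh."""
        v = self.scaled_vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def map_channels(self, channel_dirs: np.ndarray) -> np.ndarray:
        """Nearest mesh vertex per channel direction (max dot product)."""
        self.channel_vertex_map = np.argmax(channel_dirs @ self.vertices.T, axis=1)
        return self.channel_vertex_map


def make_canonical_mesh(
    subdivisions: int = 4, radius: float = 85.0, center: np.ndarray | None = None
) -> ScalpMesh:
    """Icosphere scalp mesh: 10 * 4^s + 2 vertices, 20 * 4^s faces.

    The default of four subdivisions yields the 2562-vertex canonical surface.
    """
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in [0, 6]")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return ScalpMesh(
        vertices=verts,
        faces=np.asarray(ico.faces, dtype=int),
        radius=radius,
        center=np.zeros(3) if center is None else np.asarray(center, dtype=float),
    )


def project_channels_sphere(
    layout: ProbeLayout | np.ndarray,
    head_center: np.ndarray | None = None,
    head_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Radially project channel positions onto the head sphere.

    Returns (unit directions [J x 3], center, radius).  When center/radius are
    omitted a least-squares sphere is fitted through the channel (and optode)
    positions.
    """
    if isinstance(layout, ProbeLayout):
        pts = [layout.channel_pos]
        if layout.source_pos is not None:
            pts.append(layout.source_pos)
        if layout.detector_pos is not None:
            pts.append(layout.detector_pos)
        cloud = np.vstack(pts)
        channels = layout.channel_pos
    else:
        channels = np.atleast_2d(np.asarray(layout, dtype=float))
        cloud = channels
    if head_center is None or head_radius is None:
        fit_c, fit_r = fit_head_sphere(cloud)
        head_center = fit_c if head_center is None else np.asarray(head_center, float)
        head_radius = fit_r if head_radius is None else float(head_radius)
    head_center = np.asarray(head_center, dtype=float)
    rays = channels - head_center
    norms = np.linalg.norm(rays, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("channel coincides with head center; projection undefined")
    return rays / norms[:, None], head_center, float(head_radius)


def project_channels_disc(
    dirs: np.ndarray, head_radius: float = 85.0, max_polar_deg: float = 115.0
) -> np.ndarray:
    """Azimuthal-equidistant projection about the vertex (+z).

    Planar radius is the arc length head_radius * polar angle; azimuth is
    preserved.  The vertex maps to the origin.
    """
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    z = np.clip(d[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    if np.any(np.degrees(theta) > max_polar_deg + 1e-9):
        raise ValueError(
            f"channel polar angle exceeds {max_polar_deg} deg; "
            "below-horizon channels cannot be shown on the 10-20 disc"
        )
    az = np.arctan2(d[:, 1], d[:, 0])
    r = head_radius * theta
    return np.column_stack([r * np.cos(az), r * np.sin(az)])


def disc_to_sphere(xy: np.ndarray, head_radius: float = 85.0) -> np.ndarray:
    """Inverse of :func:`project_channels_disc` (unit directions)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    r = np.linalg.norm(xy, axis=1)
    theta = r / head_radius
    az = np.arctan2(xy[:, 1], xy[:, 0])
    sin_t = np.sin(theta)
    return np.column_stack(
        [sin_t * np.cos(az), sin_t * np.sin(az), np.cos(theta)]
    )


def make_search_mask(
    geometry: ScalpGrid2D | ScalpMesh,
    channel_coords: np.ndarray,
    support_radius: float = 30.0,
) -> np.ndarray:
    """Pixels/vertices within ``support_radius`` mm of any channel.

    On the grid the distance is Euclidean in disc coordinates (``channel_coords``
    are [J x 2] mm); on the mesh it is the great-circle distance
    (``channel_coords`` are [J x 3] unit directions).  Since every channel lies
    in the channel convex hull, this union of balls is automatically contained
    in the hull dilated by the same radius.  Monotone in ``support_radius``.
    """
    if support_radius <= 0:
        raise ValueError("support_radius must be > 0")
    coords = np.atleast_2d(np.asarray(channel_coords, dtype=float))
    if isinstance(geometry, ScalpGrid2D):
        xx, yy = geometry.pixel_centers()
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d2 = np.min(
            np.sum((pts[:, None, :] - coords[None, :, :]) ** 2, axis=2), axis=1
        )
        mask = (d2 <= support_radius**2).reshape(xx.shape) & geometry.mask
    else:
        cosang = np.clip(geometry.vertices @ coords.T, -1.0, 1.0)
        geo = geometry.radius * np.arccos(cosang)  # [V x J] great-circle mm
        mask = np.min(geo, axis=1) <= support_radius
    if not mask.any():
        raise ValueError("search mask is empty; increase support_radius")
    return mask
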