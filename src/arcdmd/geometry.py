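"""Beam geometry: arcs, beam's-eye-view projection, MLC aperture fitting.

Conventions
-----------
World axes are (x: left-right, y: posterior-anterior, z: inferior-superior).
The gantry rotates in the x-y plane about the z axis through the isocenter
(coplanar delivery, couch and collimator fixed at 0).  At gantry angle g the
source sits at ``iso + SAD * (sin g, cos g, 0)`` (g = 0: anterior).

The BEV plane is the plane through the isocenter perpendicular to the beam
axis, with in-plane axes e1 (MLC leaf-travel direction, horizontal) and
e2 = z (leaf stacking, cranio-caudal).  Apertures are expressed at this
plane; a point at world position p maps to BEV coordinates by central
projection from the source (SAD magnification).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._raytrace import ray_hits
from .phantom import ImageGrid

__all__ = [
    "BeamGeometry",
    "ArcSpec",
    "ControlPointAperture",
    "BEVImage",
    "GeometryError",
    "make_arc",
    "bev_project",
    "fit_mlc",
    "aperture_transmission",
]


class GeometryError(ValueError):
    """Raised for invalid beam geometry or degenerate projections."""


@dataclass(frozen=True)
class BeamGeometry:
    """Isocentric C-arm machine description.

    ``leaf_width_iso_mm`` is the MLC leaf width projected to the isocenter
    plane; leaf pair k spans the e2 band centred at
    ``leaf_width * (k - n_leaf_pairs // 2)`` so one band straddles the axis.
    """

    sad_mm: float = 1000.0
    leaf_width_iso_mm: float = 5.0
    n_leaf_pairs: int = 60
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    couch_angle_deg: float = 0.0
    collimator_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.sad_mm <= 0 or self.leaf_width_iso_mm <= 0:
            raise GeometryError("SAD and leaf width must be positive")
        if self.couch_angle_deg != 0.0 or self.collimator_angle_deg != 0.0:
            raise GeometryError("only couch 0 / collimator 0 (coplanar DCA) is supported")

    def source_position(self, gantry_deg: float) -> np.ndarray:
        g = np.deg2rad(gantry_deg)
        iso = np.asarray(self.isocenter_mm, dtype=float)
        return iso + self.sad_mm * np.array([np.sin(g), np.cos(g), 0.0])

    def beam_axes(self, gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit vectors (u, e1, e2): beam direction, leaf travel, leaf stacking."""
        g = np.deg2rad(gantry_deg)
        u = -np.array([np.sin(g), np.cos(g), 0.0])
        e1 = np.array([np.cos(g), -np.sin(g), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        return u, e1, e2

    def leaf_centers(self) -> np.ndarray:
        """BEV e2 coordinate of each leaf-pair band centre (mm)."""
        k = np.arange(self.n_leaf_pairs)
        return self.leaf_width_iso_mm * (k - self.n_leaf_pairs // 2)

    def with_isocenter(self, isocenter: np.ndarray) -> "BeamGeometry":
        return dataclasses.replace(self, isocenter_mm=tuple(float(v) for v in isocenter))


@dataclass(frozen=True)
class ArcSpec:
    """A single coplanar arc: uniform control points over a 340 deg span.

    The unused ``360 - span`` sector (20 deg by default) is centred on
    ``gap_center_deg``; by convention that gap faces the contralateral lung.
    ``gantry_start/stop`` are the first/last delivered angles.
    """

    span_deg: float = 340.0
    control_point_spacing_deg: float = 2.0
    gap_center_deg: float = 90.0
    direction: str = "CW"

    def __post_init__(self) -> None:
        if not (0 < self.span_deg <= 360):
            raise GeometryError("arc span must lie in (0, 360]")
        if self.control_point_spacing_deg <= 0:
            raise GeometryError("control point spacing must be positive")
        n = self.span_deg / self.control_point_spacing_deg
        if abs(n - round(n)) > 1e-9:
            raise GeometryError(
                f"spacing {self.control_point_spacing_deg} deg does not divide span {self.span_deg} deg"
            )
        if self.direction not in ("CW", "CCW"):
            raise GeometryError("direction must be 'CW' or 'CCW'")

    @property
    def gap_width_deg(self) -> float:
        return 360.0 - self.span_deg

    @property
    def gantry_start_deg(self) -> float:
        return (self.gap_center_deg + self.gap_width_deg / 2.0) % 360.0

    @property
    def gantry_stop_deg(self) -> float:
        return (self.gap_center_deg - self.gap_width_deg / 2.0) % 360.0

    @property
    def n_control_points(self) -> int:
        n = int(round(self.span_deg / self.control_point_spacing_deg))
        return n if self.gap_width_deg == 0 else n + 1


def make_arc(spec: ArcSpec) -> np.ndarray:
    """Ordered gantry angles (deg, in [0, 360)) of the arc's control points.

    Angles are uniform over the span and exclude the gap sector.  For a full
    360 deg arc the duplicate closing angle is dropped.
    """
    n = spec.n_control_points
    angles = (spec.gantry_start_deg + spec.control_point_spacing_deg * np.arange(n)) % 360.0
    if spec.direction == "CCW":
        angles = angles[::-1]
    return angles


@dataclass
class ControlPointAperture:
    """MLC opening at one control point, at the isocenter plane (mm)."""

    gantry_deg: float
    left_edges: np.ndarray  # (n_leaf_pairs,) e1 coordinate of left leaf tip
    right_edges: np.ndarray
    is_open: np.ndarray  # (n_leaf_pairs,) bool; closed pairs give zero fluence

    def __post_init__(self) -> None:
        self.left_edges = np.asarray(self.left_edges, dtype=float)
        self.right_edges = np.asarray(self.right_edges, dtype=float)
        self.is_open = np.asarray(self.is_open, dtype=bool)
        bad = self.is_open & (self.left_edges > self.right_edges)
        if bad.any():
            raise GeometryError("open leaf pair with left edge beyond right edge")

    def to_dict(self) -> dict:
        return {
            "gantry_deg": float(self.gantry_deg),
            "left_edges_mm": self.left_edges.tolist(),
            "right_edges_mm": self.right_edges.tolist(),
            "is_open": self.is_open.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControlPointAperture":
        return cls(d["gantry_deg"], d["left_edges_mm"], d["right_edges_mm"], d["is_open"])


def apertures_to_json(apertures: list[ControlPointAperture], path: str | Path) -> None:
    Path(path).write_text(json.dumps([a.to_dict() for a in apertures]))


def apertures_from_json(path: str | Path) -> list[ControlPointAperture]:
    return [ControlPointAperture.from_dict(d) for d in json.loads(Path(path).read_text())]


@dataclass
class BEVImage:
    """2-D image in the isocenter plane: axis 0 = e1 (leaf travel), axis 1 = e2."""

    values: np.ndarray
    pitch_mm: float
    x0_mm: float  # e1 coordinate of pixel (0, j) centre
    y0_mm: float  # e2 coordinate of pixel (i, 0) centre

    @property
    def x_axis(self) -> np.ndarray:
        return self.x0_mm + self.pitch_mm * np.arange(self.values.shape[0])

    @property
    def y_axis(self) -> np.ndarray:
        return self.y0_mm + self.pitch_mm * np.arange(self.values.shape[1])

    def save_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(np.asarray(self.values, dtype=float).T, origin="lower", cmap="gray",
                  extent=(self.x_axis[0], self.x_axis[-1], self.y_axis[0], self.y_axis[-1]))
        ax.set_xlabel("e1 / mm")
        ax.set_ylabel("e2 / mm")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _mask_bev_extent(
    mask: np.ndarray, grid: ImageGrid, geometry: BeamGeometry, gantry_deg: float
) -> tuple[float, float]:
    """Half-extents (e1, e2) of the mask's divergent silhouette, padded."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) - 1.0
    hi = idx.max(axis=0) + 1.0
    corners = np.array([[lo[a] if b & (1 << a) == 0 else hi[a] for a in range(3)]
                        for b in range(8)])
    world = np.asarray(grid.origin) + corners * np.asarray(grid.spacing)
    src = geometry.source_position(gantry_deg)
    u, e1, e2 = geometry.beam_axes(gantry_deg)
    w = world - src
    zb = w @ u
    if np.any(zb <= 0):
        raise GeometryError("target extends behind the source")
    mag = geometry.sad_mm / zb
    bx = (w @ e1) * mag
    by = (w @ e2) * mag
    return float(np.abs(bx).max()), float(np.abs(by).max())


def bev_project(
    mask: np.ndarray,
    grid: ImageGrid,
    geometry: BeamGeometry,
    gantry_deg: float,
    pitch_mm: float = 1.0,
    half_extent_mm: tuple[float, float] | None = None,
) -> BEVImage:
    """Divergent beam's-eye-view silhouette of a mask at one gantry angle.

    A BEV pixel is open iff the ray from the source through the pixel centre
    (in the isocenter plane) intersects at least one mask voxel -- i.e. the
    pixel centre lies inside the point-source projected footprint of some
    voxel.  Computed exactly by DDA ray traversal; no sampling step.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty target")
    if pitch_mm > 1.0:
        raise GeometryError("BEV pixel pitch must be <= 1 mm")

    if half_extent_mm is None:
        hx, hy = _mask_bev_extent(mask, grid, geometry, gantry_deg)
        hx += 2 * pitch_mm
        hy += 2 * pitch_mm
    else:
        hx, hy = half_extent_mm

    nx = max(3, int(np.ceil(2 * hx / pitch_mm)) + 1)
    ny = max(3, int(np.ceil(2 * hy / pitch_mm)) + 1)
    x0 = -pitch_mm * (nx - 1) / 2.0
    y0 = -pitch_mm * (ny - 1) / 2.0
    xs = x0 + pitch_mm * np.arange(nx)
    ys = y0 + pitch_mm * np.arange(ny)

    src = geometry.source_position(gantry_deg)
    u, e1, e2 = geometry.beam_axes(gantry_deg)
    iso = np.asarray(geometry.isocenter_mm)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    targets = iso + gx[..., None] * e1 + gy[..., None] * e2
    dirs = (targets - src).reshape(-1, 3)

    hits = ray_hits(
        mask.view(np.uint8) if mask.dtype == np.bool_ else mask.astype(np.uint8),
        np.asarray(grid.spacing),
        np.asarray(grid.origin),
        src.astype(np.float64),
        np.ascontiguousarray(dirs, dtype=np.float64),
    )
    return BEVImage(hits.reshape(nx, ny), pitch_mm, x0, y0)


def fit_mlc(
    aperture: BEVImage, geometry: BeamGeometry, margin_mm: float = 0.0, gantry_deg: float = 0.0
) -> ControlPointAperture:
    """Fit MLC leaf-pair edges to a binary BEV aperture.

    For each leaf band (height = projected leaf width), the leaf edges are
    the min/max open-pixel extent within the band (pixel outer edges),
    pushed outward by ``margin_mm``.  Bands without open pixels are closed.
    """
    open_px = np.asarray(aperture.values, dtype=bool)
    if not open_px.any():
        raise GeometryError("empty aperture")
    w = geometry.leaf_width_iso_mm
    centers = geometry.leaf_centers()
    xs = aperture.x_axis
    ys = aperture.y_axis
    half_px = aperture.pitch_mm / 2.0

    n = geometry.n_leaf_pairs
    left = np.zeros(n)
    right = np.zeros(n)
    is_open = np.zeros(n, dtype=bool)
    # Pixel row -> leaf band membership by pixel-centre inclusion [lo, hi).
    band_idx = np.floor((ys - (centers[0] - w / 2.0)) / w).astype(int)
    for k in range(n):
        cols = np.nonzero(band_idx == k)[0]
        if cols.size == 0:
            continue
        any_open = open_px[:, cols].any(axis=1)
        if not any_open.any():
            continue
        open_rows = np.nonzero(any_open)[0]
        left[k] = xs[open_rows[0]] - half_px - margin_mm
        right[k] = xs[open_rows[-1]] + half_px + margin_mm
        is_open[k] = True
    return ControlPointAperture(gantry_deg, left, right, is_open)


def aperture_transmission(
    cpa: ControlPointAperture,
    geometry: BeamGeometry,
    pitch_mm: float = 1.0,
    pad_mm: float = 15.0,
) -> BEVImage:
    """Render a leaf aperture to a binary transmission image (isocenter plane)."""
    if not cpa.is_open.any():
        hx = hy = pad_mm
    else:
        hx = max(np.abs(cpa.left_edges[cpa.is_open]).max(),
                 np.abs(cpa.right_edges[cpa.is_open]).max()) + pad_mm
        centers = geometry.leaf_centers()[cpa.is_open]
        hy = np.abs(centers).max() + geometry.leaf_width_iso_mm / 2.0 + pad_mm
    # Pixel centres sit on absolute multiples of the pitch, so enlarging the
    # window only extends the image with zeros (keeps dose monotone in the
    # aperture and independent of window size).
    nhx = int(np.ceil(hx / pitch_mm))
    nhy = int(np.ceil(hy / pitch_mm))
    nx, ny = 2 * nhx + 1, 2 * nhy + 1
    x0 = -pitch_mm * nhx
    y0 = -pitch_mm * nhy
    xs = x0 + pitch_mm * np.arange(nx)
    ys = y0 + pitch_mm * np.arange(ny)

    img = np.zeros((nx, ny))
    w = geometry.leaf_width_iso_mm
    centers = geometry.leaf_centers()
    band_idx = np.floor((ys - (centers[0] - w / 2.0)) / w).astype(int)
    for k in np.nonzero(cpa.is_open)[0]:
        cols = np.nonzero(band_idx == k)[0]
        if cols.size == 0:
            continue
        rows = (xs >= cpa.left_edges[k]) & (xs <= cpa.right_edges[k])
        img[np.ix_(rows, cols)] = 1.0
    return BEVImage(img, pitch_mm, x0, y0)
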