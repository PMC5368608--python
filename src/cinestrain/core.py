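"""Shared containers: cine sequences, contours, grids, displacement fields.

Coordinate conventions used throughout the package
--------------------------------------------------
* Image arrays are indexed ``[row, col]`` (numpy order); physical
  coordinates are ``x = col * spacing_x``, ``y = row * spacing_y`` in mm,
  with the pixel *center* of index ``(0, 0)`` at the physical origin.
* Contours and displacement vectors are stored in physical mm.
* Displacement fields live on the reference-frame grid (Lagrangian
  convention): a material point at reference position ``x`` sits at
  ``x + u(x)`` in the target frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely


@dataclass(frozen=True)
class GridSpec:
    """Pixel grid: ``shape=(rows, cols)``, isotropic-or-not spacing in mm."""

    shape: tuple[int, int]
    spacing: tuple[float, float] = (1.0, 1.0)  # (sx, sy) mm per pixel

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 2:
            raise ValueError(f"grid shape must be 2-D with >=2 pixels per axis, got {self.shape}")
        if min(self.spacing) <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of every pixel center, each (rows, cols)."""
        rows, cols = self.shape
        sx, sy = self.spacing
        ys, xs = np.meshgrid(np.arange(rows) * sy, np.arange(cols) * sx, indexing="ij")
        return xs, ys

    def to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) array indices of physical points."""
        sx, sy = self.spacing
        return np.asarray(y) / sy, np.asarray(x) / sx


@dataclass
class CineSequence:
    """One slice's cine loop: T frames on a common grid.

    ``frames`` is ``(T, rows, cols)`` float; ``frame_times`` are in ms from
    the reference (end-diastolic) frame; ``view`` tags the acquisition plane
    (``"sax-basal"``, ``"sax-mid"``, ``"sax-apical"`` or ``"lax-4ch"``).
    """

    frames: np.ndarray
    grid: GridSpec
    frame_times: np.ndarray
    view: str = "sax-mid"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, rows, cols)")
        if self.frames.shape[1:] != self.grid.shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match grid {self.grid.shape}"
            )
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def _as_closed_ring(poly: np.ndarray) -> shapely.LinearRing:
    pts = np.asarray(poly, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be an (N, 2) array with N >= 3")
    return shapely.LinearRing(pts)


@dataclass
class ContourPair:
    """End-diastolic endocardial and epicardial contours of one slice (mm).

    Both polylines must be simple (non-self-intersecting) and the
    endocardium strictly inside the epicardium.
    """

    endo: np.ndarray
    epi: np.ndarray
    view: str = "sax-mid"
    slice_index: int = 0
    slice_thickness: float = 8.0  # mm
    slice_gap: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        endo_ring = _as_closed_ring(self.endo)
        epi_ring = _as_closed_ring(self.epi)
        if not endo_ring.is_simple or not epi_ring.is_simple:
            raise ValueError("contours must be simple (non-self-intersecting) polylines")
        endo_poly = shapely.Polygon(endo_ring)
        epi_poly = shapely.Polygon(epi_ring)
        if not shapely.contains_properly(epi_poly, endo_poly) or endo_poly.area <= 0:
            raise ValueError("endocardial contour must lie strictly inside the epicardial contour")

    @property
    def endo_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.endo)

    @property
    def epi_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.epi)

    @property
    def myocardial_area(self) -> float:
        """Annular wall area in mm^2."""
        return float(self.epi_polygon.area - self.endo_polygon.area)


@dataclass
class PixelGeometry:
    """Per-pixel myocardial geometry on a grid.

    ``depth`` is the transmural coordinate d in [0, 1] (0 = endocardium),
    ``theta`` the circumferential angle in degrees from the +x ray around
    the endocardial centroid, ``e_r``/``e_c``/``e_l`` unit direction fields
    ``(rows, cols, 2)`` (NaN outside the mask), ``layer`` the 0/1/2 =
    endo/mid/epi label and ``segment`` the 0..5 wall-segment label
    (-1 outside the mask / where not applicable).
    """

    grid: GridSpec
    mask: np.ndarray
    depth: np.ndarray
    view: str = "sax"
    theta: Optional[np.ndarray] = None
    e_r: Optional[np.ndarray] = None
    e_c: Optional[np.ndarray] = None
    e_l: Optional[np.ndarray] = None
    layer: Optional[np.ndarray] = None
    segment: Optional[np.ndarray] = None
    level: Optional[np.ndarray] = None  # LAX: 0/1/2 = basal/mid/apical thirds
    arc_position: Optional[np.ndarray] = None  # LAX: s in [0,1] along midline

    def direction(self, name: str) -> np.ndarray:
        """Unit-direction field for a strain component tag (Err/Ecc/Ell)."""
        table = {"Err": self.e_r, "Ecc": self.e_c, "Ell": self.e_l}
        if name not in table:
            raise ValueError(f"unknown strain direction {name!r}; expected Err, Ecc or Ell")
        vec = table[name]
        if vec is None:
            raise ValueError(f"geometry has no {name} direction field (view={self.view!r})")
        return vec


@dataclass
class DisplacementField:
    """Dense displacement (mm) on the reference grid for one target frame."""

    u: np.ndarray  # (rows, cols, 2), components (ux, uy) in mm
    grid: GridSpec
    frame_index: int
    converged: bool = True
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError("displacement must be (rows, cols, 2)")
        if self.u.shape[:2] != self.grid.shape:
            raise ValueError("displacement grid mismatch")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u[..., 0], self.u[..., 1])


def circle_contour(center: tuple[float, float], radius: float, n: int = 256) -> np.ndarray:
    """Closed polyline approximating a circle (mm); first point not repeated."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)])
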