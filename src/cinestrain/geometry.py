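"""Per-pixel myocardial geometry from end-diastolic contours.

Membership, transmural depth, local strain directions, the three-layer
split at 33.3% / 66.6% depth, the six-segment wall division, and the
basal/mid/apical slice-selection rule.
"""

from __future__ import annotations

import math

import numpy as np
import shapely

from cinestrain.core import ContourPair, GridSpec, PixelGeometry

#: Wall segments in clockwise anatomical order starting at the anterior wall.
SEGMENT_NAMES = ("Ant", "Antsep", "Sep", "Inf", "Post", "Lat")

#: Transmural layer labels: depth d < 1/3 -> endo, 1/3 <= d < 2/3 -> mid, else epi.
LAYER_NAMES = ("endo", "mid", "epi")

LEVEL_NAMES = ("basal", "mid", "apical")


def rasterize_myocardium(contours: ContourPair, grid: GridSpec) -> np.ndarray:
    """Boolean myocardial mask: pixel centers inside the epicardial contour
    and outside the endocardial contour.  Deterministic, center-sampled."""
    xs, ys = grid.pixel_centers()
    endo = contours.endo_polygon
    epi = contours.epi_polygon
    in_epi = shapely.contains_xy(epi, xs.ravel(), ys.ravel()).reshape(grid.shape)
    in_endo = shapely.contains_xy(endo, xs.ravel(), ys.ravel()).reshape(grid.shape)
    mask = in_epi & ~in_endo
    if not mask.any():
        raise ValueError("rasterization produced an empty myocardial mask")
    return mask


def compute_local_directions(
    contours: ContourPair, mask: np.ndarray, grid: GridSpec
) -> PixelGeometry:
    """Short-axis pixel geometry: transmural depth, angle, radial and
    circumferential unit directions.

    Depth is ``d = dist_endo / (dist_endo + dist_epi)`` from the exact
    distances of each pixel center to the two contour polylines (a dual
    signed-distance construction that is robust to non-circular contours).
    ``e_r`` points outward from the endocardial centroid; ``e_c`` is its
    +90 degree rotation (counter-clockwise with y up).
    """
    if not np.any(mask):
        raise ValueError("empty myocardial mask")
    xs, ys = grid.pixel_centers()
    mx, my = xs[mask], ys[mask]
    pts = shapely.points(mx, my)
    endo_ring = shapely.LinearRing(contours.endo)
    epi_ring = shapely.LinearRing(contours.epi)
    d_endo = shapely.distance(pts, endo_ring)
    d_epi = shapely.distance(pts, epi_ring)

    depth = np.full(grid.shape, np.nan)
    depth[mask] = d_endo / np.maximum(d_endo + d_epi, 1e-12)

    centroid = shapely.Polygon(contours.endo).centroid
    cx, cy = centroid.x, centroid.y
    dx, dy = xs - cx, ys - cy
    rr = np.maximum(np.hypot(dx, dy), 1e-12)
    e_r = np.stack([dx / rr, dy / rr], axis=-1)
    e_c = np.stack([-e_r[..., 1], e_r[..., 0]], axis=-1)
    outside = ~mask
    e_r[outside] = np.nan
    e_c[outside] = np.nan

    theta = np.full(grid.shape, np.nan)
    theta[mask] = np.degrees(np.arctan2(dy[mask], dx[mask])) % 360.0

    geo = PixelGeometry(
        grid=grid, mask=mask, depth=depth, view="sax", theta=theta, e_r=e_r, e_c=e_c
    )
    geo.layer = assign_layers(geo)
    return geo


def assign_layers(geometry: PixelGeometry) -> np.ndarray:
    """Three-layer labels from transmural depth.

    Half-open bands [0, 1/3), [1/3, 2/3), [2/3, 1]: a pixel exactly on the
    33.3% or 66.6% line belongs to the outer of the two adjacent layers.
    Returns int labels 0/1/2 = endo/mid/epi, -1 outside the mask.
    """
    d = geometry.depth
    layer = np.full(geometry.mask.shape, -1, dtype=int)
    m = geometry.mask
    layer[m & (d < 1.0 / 3.0)] = 0
    layer[m & (d >= 1.0 / 3.0) & (d < 2.0 / 3.0)] = 1
    layer[m & (d >= 2.0 / 3.0)] = 2
    return layer


def assign_segments(geometry: PixelGeometry, reference_angle_deg: float | None) -> np.ndarray:
    """Six equal 60-degree wall sectors.

    ``reference_angle_deg`` is the user-supplied anterior reference ray
    (degrees, same convention as ``PixelGeometry.theta``); sectors are
    labeled 0..5 = Ant, Antsep, Sep, Inf, Post, Lat advancing clockwise
    (decreasing theta) from that ray.  The anatomical anchor (normally the
    RV insertion) cannot be inferred from a single contour pair, hence the
    explicit argument.
    """
    if reference_angle_deg is None:
        raise ValueError(
            "segment assignment needs an anterior reference angle (degrees); "
            "supply the ray pointing at the anterior wall"
        )
    if geometry.theta is None:
        raise ValueError("segment assignment requires short-axis geometry with theta")
    seg = np.full(geometry.mask.shape, -1, dtype=int)
    m = geometry.mask
    rel = (reference_angle_deg - geometry.theta[m]) % 360.0  # clockwise offset
    seg[m] = np.floor(rel / 60.0).astype(int) % 6
    return seg


def select_levels(
    n_slices: int, first_non_outflow_index: int, apex_index: int
) -> tuple[int, int, int]:
    """Basal / mid / apical slice indices in an ordered base-to-apex stack.

    basal = the first slice excluding the outflow tract; mid = the middle
    slice of the stack (ties toward the apex); apical = the midpoint of the
    apex slice and the mid slice, rounded toward the apex.
    """
    if n_slices < 3:
        raise ValueError("need at least 3 slices to define basal/mid/apical levels")
    if not (0 <= first_non_outflow_index < n_slices):
        raise ValueError("first_non_outflow_index out of range")
    if not (0 <= apex_index < n_slices):
        raise ValueError("apex_index out of range")
    mid = n_slices // 2
    if apex_index <= mid:
        raise ValueError(
            f"apex slice ({apex_index}) must lie beyond the mid slice ({mid})"
        )
    apical = math.ceil((apex_index + mid) / 2.0)
    return first_non_outflow_index, mid, apical


def _polyline_arclength(poly: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(poly, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def lax_directions(
    midline: np.ndarray, thickness: float, grid: GridSpec
) -> PixelGeometry:
    """Long-axis pixel geometry from a wall midline and constant thickness.

    The mask is the set of pixels within ``thickness / 2`` of the midline
    (between its endpoints); ``e_l`` is the local midline tangent oriented
    base -> apex; depth is the transmural distance across the wall mapped
    to [0, 1]; ``level`` splits the midline into equal arc-length thirds
    (basal / mid / apical) and ``arc_position`` is the normalized midline
    coordinate s in [0, 1].
    """
    midline = np.asarray(midline, dtype=float)
    if midline.ndim != 2 or midline.shape[0] < 2:
        raise ValueError("midline must be an (N>=2, 2) polyline")
    if thickness <= 0:
        raise ValueError("wall thickness must be positive")

    xs, ys = grid.pixel_centers()
    line = shapely.LineString(midline)
    total = line.length
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = shapely.distance(pts, line).reshape(grid.shape)
    proj = shapely.line_locate_point(line, pts).reshape(grid.shape)
    half = thickness / 2.0
    interior = (proj > 1e-9) & (proj < total - 1e-9)
    mask = (dist <= half) & interior
    if not mask.any():
        raise ValueError("band mask is empty on this grid")

    depth = np.full(grid.shape, np.nan)
    # transverse signed side is irrelevant for strain; transmural depth runs
    # across the wall from one face (d=0) to the other (d=1)
    arc = _polyline_arclength(midline)
    # local tangent at the projected arclength
    tang_x = np.interp(proj, arc, np.gradient(midline[:, 0], arc, edge_order=1))
    tang_y = np.interp(proj, arc, np.gradient(midline[:, 1], arc, edge_order=1))
    norm = np.maximum(np.hypot(tang_x, tang_y), 1e-12)
    e_l = np.stack([tang_x / norm, tang_y / norm], axis=-1)
    e_l[~mask] = np.nan

    # signed transverse coordinate: cross product of (p - proj_point) with tangent
    proj_pts = shapely.line_interpolate_point(line, proj.ravel())
    px = shapely.get_x(proj_pts).reshape(grid.shape)
    py = shapely.get_y(proj_pts).reshape(grid.shape)
    signed = (xs - px) * (tang_y / norm) - (ys - py) * (tang_x / norm)
    depth[mask] = (signed[mask] + half) / thickness
    depth = np.clip(depth, 0.0, 1.0)

    s = np.full(grid.shape, np.nan)
    s[mask] = proj[mask] / total
    level = np.full(grid.shape, -1, dtype=int)
    level[mask] = np.minimum((s[mask] * 3.0).astype(int), 2)

    geo = PixelGeometry(
        grid=grid,
        mask=mask,
        depth=depth,
        view="lax",
        e_l=e_l,
        level=level,
        arc_position=s,
    )
    geo.layer = assign_layers(geo)
    return geo
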