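"""Pixel-wise strain maps, region strain-time curves, and peak systolic strain.

Strain measure: directional engineering strain.  With the deformation
gradient F = I + grad(u) (central differences in physical mm), the strain
along a unit direction e is ||F e|| - 1, reported in %.  This makes the
incompressible-annulus phantom exact (Ecc = r'/r - 1).  The directional
Green-Lagrange measure e'(F'F - I)e / 2 is available behind a flag.

Sign convention: radial strain is positive in systole (wall thickening),
circumferential and longitudinal strain negative (shortening).  "Peak
systolic" strain is the signed whole-cycle extremum of the region-mean
curve: maximum for Err, minimum for Ecc / Ell, earliest frame on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cinestrain.core import DisplacementField, PixelGeometry

_PEAK_SIGN = {"Err": +1.0, "Ecc": -1.0, "Ell": -1.0}


@dataclass
class StrainCurve:
    """Region-mean strain (%) per frame for one direction."""

    region: str
    direction: str
    values: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("strain curve must be a non-empty 1-D series")


@dataclass(frozen=True)
class PeakStrain:
    """Signed peak systolic strain (%) of one region curve."""

    value: float
    frame: int
    direction: str
    region: str


def deformation_gradient(field: DisplacementField) -> np.ndarray:
    """F = I + grad(u), (rows, cols, 2, 2), derivatives in physical mm.

    Central differences in the grid interior, one-sided at image borders
    (numpy.gradient); border pixels whose stencil leaves the mask are the
    caller's concern (region means are taken over interior wall pixels).
    """
    sx, sy = field.grid.spacing
    ux, uy = field.u[..., 0], field.u[..., 1]
    dux_dy, dux_dx = np.gradient(ux, sy, sx)
    duy_dy, duy_dx = np.gradient(uy, sy, sx)
    F = np.empty(field.grid.shape + (2, 2))
    F[..., 0, 0] = 1.0 + dux_dx
    F[..., 0, 1] = dux_dy
    F[..., 1, 0] = duy_dx
    F[..., 1, 1] = 1.0 + duy_dy
    return F


def directional_strain_field(
    field: DisplacementField,
    geometry: PixelGeometry,
    direction: str,
    measure: str = "engineering",
) -> np.ndarray:
    """Strain map (%) along the geometry's unit-direction field.

    NaN outside the myocardial mask.  ``direction`` is "Err", "Ecc" or
    "Ell"; ``measure`` is "engineering" (default) or "green".
    """
    if field.grid.shape != geometry.grid.shape:
        raise ValueError("displacement field and geometry grids differ")
    e = geometry.direction(direction)
    F = deformation_gradient(field)
    Fe = np.einsum("...ij,...j->...i", F, np.nan_to_num(e))
    stretch = np.hypot(Fe[..., 0], Fe[..., 1])
    if measure == "engineering":
        strain = stretch - 1.0
    elif measure == "green":
        strain = 0.5 * (stretch**2 - 1.0)
    else:
        raise ValueError(f"unknown strain measure {measure!r}")
    out = np.where(geometry.mask, strain * 100.0, np.nan)
    return out


def region_masks(geometry: PixelGeometry, regions: str = "layers") -> dict[str, np.ndarray]:
    """Named pixel regions for curve extraction.

    ``regions``: "layers" (endo/mid/epi), "segments" (six wall sectors,
    short-axis only), "levels" (long-axis basal/mid/apical thirds), or
    "global" (whole mask).
    """
    from cinestrain.geometry import LAYER_NAMES, LEVEL_NAMES, SEGMENT_NAMES

    m = geometry.mask
    if regions == "global":
        return {"global": m}
    if regions == "layers":
        if geometry.layer is None:
            raise ValueError("geometry has no layer labels")
        return {name: m & (geometry.layer == i) for i, name in enumerate(LAYER_NAMES)}
    if regions == "segments":
        if geometry.segment is None:
            raise ValueError("geometry has no segment labels; call assign_segments first")
        return {name: m & (geometry.segment == i) for i, name in enumerate(SEGMENT_NAMES)}
    if regions == "levels":
        if geometry.level is None:
            raise ValueError("geometry has no level labels (long-axis only)")
        return {name: m & (geometry.level == i) for i, name in enumerate(LEVEL_NAMES)}
    raise ValueError(f"unknown region spec {regions!r}")


def strain_curves(
    maps: np.ndarray | list[np.ndarray],
    geometry: PixelGeometry,
    direction: str,
    regions: str | dict[str, np.ndarray] = "layers",
    frame_times: np.ndarray | None = None,
) -> list[StrainCurve]:
    """Unweighted region-mean strain per frame.

    ``maps`` holds one strain map per frame (reference frame's map is all
    zeros on the mask by construction).  An empty region raises, naming it.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("maps must be (T, rows, cols)")
    masks = regions if isinstance(regions, dict) else region_masks(geometry, regions)
    curves = []
    for name, m in masks.items():
        if not np.any(m):
            raise ValueError(f"region {name!r} contains no pixels")
        vals = np.nanmean(maps[:, m], axis=1)
        curves.append(
            StrainCurve(region=name, direction=direction, values=vals, frame_times=frame_times)
        )
    return curves


def peak_systolic(curve: StrainCurve, direction: str | None = None) -> PeakStrain:
    """Signed whole-cycle extremum of a region-mean curve.

    Maximum for Err, minimum (most negative) for Ecc and Ell; ties resolve
    to the earliest frame (argmax/argmin convention).
    """
    direction = direction or curve.direction
    if direction not in _PEAK_SIGN:
        raise ValueError(f"unknown strain direction {direction!r}")
    v = curve.values
    idx = int(np.argmax(v)) if _PEAK_SIGN[direction] > 0 else int(np.argmin(v))
    return PeakStrain(value=float(v[idx]), frame=idx, direction=direction, region=curve.region)
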