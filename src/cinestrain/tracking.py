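"""Dense deformation tracking of cine frames.

The vendor algorithms this workflow emulates are unpublished, so tracking is
built on a documented, reproducible method: multi-resolution symmetric-forces
demons registration (SimpleITK) with Gaussian regularization of both the
update field (fluid-like) and the displacement field (diffusion-like).

Reference-to-frame fields are assembled by sequential frame-to-frame
registration composed with bilinear interpolation, followed by a short
direct reference-to-frame refinement initialized at the composed field
(removes accumulated composition bias), with optional drift correction
distributing the full-cycle closure residual linearly across frames.
All fields live on the reference grid (Lagrangian convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from cinestrain.core import CineSequence, ContourPair, DisplacementField, GridSpec


@dataclass(frozen=True)
class RegistrationParams:
    """Demons registration settings.

    ``shrink_factors`` / ``iterations`` define the coarse-to-fine pyramid;
    smoothing before shrinking uses ``sigma = shrink / 2`` pixels.  The two
    regularization widths are in mm.  ``refine_iterations`` full-resolution
    iterations re-register reference -> frame starting from the composed
    sequential field (0 disables).  ``max_rms`` is the demons RMS-change
    convergence threshold; a field whose final RMS change exceeds
    ``convergence_tolerance`` is flagged (never silently dropped).
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (60, 40, 30)
    update_field_sd: float = 2.0  # mm, fluid-like regularization
    displacement_field_sd: float = 1.0  # mm, diffusion-like regularization
    refine_iterations: int = 30
    drift_correction: bool = True
    max_rms: float = 0.0
    convergence_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if len(self.shrink_factors) != len(self.iterations):
            raise ValueError("shrink_factors and iterations must have equal length")
        if any(s < 1 for s in self.shrink_factors) or any(i < 1 for i in self.iterations):
            raise ValueError("shrink factors and iteration counts must be >= 1")


def _to_sitk(frame: np.ndarray, grid: GridSpec) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(frame, dtype=np.float32))
    img.SetSpacing((float(grid.spacing[0]), float(grid.spacing[1])))
    return img


def _field_to_sitk(u: np.ndarray, grid: GridSpec) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(u, dtype=np.float64), isVector=True)
    img.SetSpacing((float(grid.spacing[0]), float(grid.spacing[1])))
    return img


def _warp_mse(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray, grid: GridSpec) -> float:
    """Mean squared intensity difference between fixed and the moving image
    pulled back through x -> x + u(x)."""
    xs, ys = grid.pixel_centers()
    rr, cc = grid.to_index(xs + u[..., 0], ys + u[..., 1])
    warped = ndimage.map_coordinates(moving, [rr, cc], order=1, mode="nearest")
    return float(np.mean((warped - fixed) ** 2))


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    grid: GridSpec,
    params: RegistrationParams = RegistrationParams(),
    frame_index: int = 0,
    initial: np.ndarray | None = None,
) -> DisplacementField:
    """Non-rigid registration of one frame pair.

    Returns the displacement (mm) on the fixed grid mapping fixed positions
    to their corresponding moving-frame positions.  Deterministic given
    params.  ``metrics`` records the full-resolution warped MSE after each
    pyramid level (monotone refinement check) and the final demons RMS
    parameter change; non-convergence sets ``converged=False`` with a
    warning, never a silent failure.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.shape != grid.shape:
        raise ValueError("fixed and moving frames must share the registration grid")

    f_full = _to_sitk(fixed, grid)
    m_full = _to_sitk(moving, grid)

    filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    filt.SetSmoothUpdateField(params.update_field_sd > 0)
    if params.update_field_sd > 0:
        filt.SetUpdateFieldStandardDeviations(params.update_field_sd)
    filt.SetSmoothDisplacementField(params.displacement_field_sd > 0)
    if params.displacement_field_sd > 0:
        filt.SetStandardDeviations(params.displacement_field_sd)
    filt.SetMaximumRMSError(params.max_rms)

    fld: sitk.Image | None = None
    if initial is not None:
        fld = _field_to_sitk(initial, grid)

    level_mse: list[float] = []
    rms = np.inf
    for shrink, iters in zip(params.shrink_factors, params.iterations):
        if shrink > 1:
            sigma = shrink / 2.0 * min(grid.spacing)
            f = sitk.Shrink(sitk.SmoothingRecursiveGaussian(f_full, sigma), [shrink, shrink])
            m = sitk.Shrink(sitk.SmoothingRecursiveGaussian(m_full, sigma), [shrink, shrink])
        else:
            f, m = f_full, m_full
        if fld is None:
            fld = sitk.Image(f.GetSize(), sitk.sitkVectorFloat64, 2)
            fld.CopyInformation(f)
        else:
            fld = sitk.Cast(
                sitk.Resample(fld, f, sitk.Transform(), sitk.sitkLinear), sitk.sitkVectorFloat64
            )
        filt.SetNumberOfIterations(int(iters))
        fld = filt.Execute(f, m, fld)
        rms = float(filt.GetRMSChange())
        u_now = sitk.GetArrayFromImage(
            sitk.Resample(fld, f_full, sitk.Transform(), sitk.sitkLinear)
        )
        level_mse.append(_warp_mse(fixed, moving, u_now, grid))

    u = sitk.GetArrayFromImage(
        sitk.Resample(fld, f_full, sitk.Transform(), sitk.sitkLinear)
    )
    converged = rms <= params.convergence_tolerance
    if not converged:
        warnings.warn(
            f"demons registration did not converge (final RMS change {rms:.3g} "
            f"> {params.convergence_tolerance}); field returned with converged=False",
            stacklevel=2,
        )
    return DisplacementField(
        u=u,
        grid=grid,
        frame_index=frame_index,
        converged=converged,
        metrics={"level_mse": level_mse, "final_rms_change": rms},
    )


def interpolate_field(u: np.ndarray, grid: GridSpec, x: np.ndarray, y: np.ndarray):
    """Bilinear sample of a displacement field at physical points (mm)."""
    rr, cc = grid.to_index(x, y)
    ux = ndimage.map_coordinates(u[..., 0], [rr, cc], order=1, mode="nearest")
    uy = ndimage.map_coordinates(u[..., 1], [rr, cc], order=1, mode="nearest")
    return ux, uy


def _compose(u_ref_t: np.ndarray, u_pair: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Compose reference->t with t->t+1: u'(x) = u(x) + v(x + u(x))."""
    xs, ys = grid.pixel_centers()
    vx, vy = interpolate_field(u_pair, grid, xs + u_ref_t[..., 0], ys + u_ref_t[..., 1])
    return np.stack([u_ref_t[..., 0] + vx, u_ref_t[..., 1] + vy], axis=-1)


def track_to_reference(
    cine: CineSequence,
    reference: int = 0,
    params: RegistrationParams = RegistrationParams(),
) -> list[DisplacementField]:
    """Displacement fields from the reference frame to every frame.

    Sequential frame-to-frame registrations are composed outward from the
    reference (both directions for an interior reference frame); each
    composed field is then refined by a short direct reference-to-frame
    registration initialized at the composition.  With drift correction on,
    the closure field (last frame back to the reference, one extra
    registration) is distributed linearly across the cycle before
    refinement, enforcing near-zero displacement after a full cycle.
    field[reference] is identically zero.
    """
    T = cine.n_frames
    if T < 2:
        raise ValueError("tracking needs at least 2 frames")
    if not (0 <= reference < T):
        raise ValueError("reference frame index out of range")
    grid = cine.grid
    frames = cine.frames

    fields: list[np.ndarray | None] = [None] * T
    flags = [True] * T
    fields[reference] = np.zeros(grid.shape + (2,))

    def sweep(indices: list[int]) -> None:
        u = np.zeros(grid.shape + (2,))
        prev = reference
        for t in indices:
            pair = register_pair(frames[prev], frames[t], grid, params, frame_index=t)
            u = _compose(u, pair.u, grid)
            fields[t] = u
            flags[t] = flags[t] and pair.converged
            prev = t

    sweep(list(range(reference + 1, T)))
    sweep(list(range(reference - 1, -1, -1)))

    if params.drift_correction and reference == 0 and T > 2:
        closing = register_pair(frames[T - 1], frames[0], grid, params, frame_index=0)
        loop = _compose(fields[T - 1], closing.u, grid)  # full-cycle residual
        for t in range(1, T):
            fields[t] = fields[t] - (t / T) * loop

    if params.refine_iterations > 0:
        refine = RegistrationParams(
            shrink_factors=(1,),
            iterations=(params.refine_iterations,),
            update_field_sd=params.update_field_sd,
            displacement_field_sd=params.displacement_field_sd,
            refine_iterations=0,
            drift_correction=False,
            convergence_tolerance=params.convergence_tolerance,
        )
        for t in range(T):
            if t == reference:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence judged on the composite
                direct = register_pair(
                    frames[reference], frames[t], grid, refine, frame_index=t,
                    initial=fields[t],
                )
            fields[t] = direct.u

    return [
        DisplacementField(u=fields[t], grid=grid, frame_index=t, converged=flags[t])
        for t in range(T)
    ]


def propagate_contours(
    contours: ContourPair, fields: list[DisplacementField]
) -> list[ContourPair]:
    """Displace the reference contours through every tracked frame.

    Each vertex moves by the bilinearly interpolated field; a propagated
    polyline that self-intersects raises a warning (returned regardless).
    Vertices outside the field grid are an error.
    """
    import shapely

    out: list[ContourPair] = []
    for fld in fields:
        grid = fld.grid
        (rows, cols), (sx, sy) = grid.shape, grid.spacing
        new_polys = []
        for poly in (contours.endo, contours.epi):
            x, y = poly[:, 0], poly[:, 1]
            if (
                np.any(x < 0) or np.any(y < 0)
                or np.any(x > (cols - 1) * sx) or np.any(y > (rows - 1) * sy)
            ):
                raise ValueError(
                    f"contour vertex outside the displacement grid at frame {fld.frame_index}"
                )
            ux, uy = interpolate_field(fld.u, grid, x, y)
            new_polys.append(np.column_stack([x + ux, y + uy]))
        for p in new_polys:
            if not shapely.LinearRing(p).is_simple:
                warnings.warn(
                    f"propagated contour self-intersects at frame {fld.frame_index}",
                    stacklevel=2,
                )
        pair = ContourPair.__new__(ContourPair)
        pair.endo, pair.epi = new_polys
        pair.view = contours.view
        pair.slice_index = contours.slice_index
        pair.slice_thickness = contours.slice_thickness
        pair.slice_gap = contours.slice_gap
        out.append(pair)
    return out
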