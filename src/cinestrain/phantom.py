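"""Analytic deforming cine phantoms with closed-form ground-truth strain.

Two phantoms stand in for acquired bSSFP cine views:

* A short-axis annulus that contracts incompressibly.  A material circle at
  reference radius ``r`` moves to ``r'(r, t) = sqrt(r^2 - R_endo^2 +
  R_endo(t)^2)`` with ``R_endo(t) = R_endo (1 - a s(t))`` and ``s(t)`` a
  raised-cosine 0 -> 1 -> 0 systolic waveform.  This conserves the annular
  area between the endocardium and every material circle (2-D
  incompressibility), and yields closed-form engineering strains

  .. math:: E_{cc}(r,t) = r'/r - 1, \\qquad E_{rr}(r,t) = r/r' - 1,

  with an endo-to-epi circumferential gradient (|Ecc| strictly decreasing
  in r) arising purely from wall-thickening kinematics.

* A long-axis band whose material points slide along the midline so that the
  local longitudinal engineering strain equals a prescribed profile
  ``eps(s, t)``, linear in the normalized base-to-apex position ``s``.

Images are a fixed band-limited random texture warped by the analytic map
plus additive Gaussian noise, so registration is solvable but not trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cinestrain.core import CineSequence, ContourPair, GridSpec, circle_contour

#: Frame period (ms) matching a 42 ms cine temporal resolution.
DEFAULT_FRAME_TIME_MS = 42.0


def systolic_waveform(t: np.ndarray | float, peak_frame: int, n_frames: int) -> np.ndarray:
    """Raised-cosine contraction phase s(t): 0 at frame 0, 1 at ``peak_frame``,
    back to 0 at the last frame.  Smooth (zero slope) at both ends and at peak."""
    t = np.asarray(t, dtype=float)
    if not (1 <= peak_frame <= n_frames - 2):
        raise ValueError(f"peak_frame must lie in [1, {n_frames - 2}], got {peak_frame}")
    up = 0.5 * (1.0 - np.cos(np.pi * t / peak_frame))
    down = 0.5 * (1.0 - np.cos(np.pi * (n_frames - 1 - t) / (n_frames - 1 - peak_frame)))
    return np.where(t <= peak_frame, up, down)


@dataclass(frozen=True)
class SaxPhantomSpec:
    """Short-axis incompressible-annulus phantom parameters.

    ``contraction`` is the peak fractional reduction of the endocardial
    radius (0 < a < 1); 25 frames matches a routinely reconstructed cine.
    """

    R_endo: float = 25.0  # mm
    R_epi: float = 33.0  # mm
    contraction: float = 0.2  # peak endocardial radius reduction, unitless
    n_frames: int = 25
    peak_frame: int = 9
    image_size: int = 128  # pixels per side
    pixel_spacing: float = 1.0  # mm
    center: tuple[float, float] | None = None  # mm; default = image center
    texture_scale: float = 3.0  # mm, correlation length of the texture
    noise_sd: float = 0.05  # intensity units (texture has unit SD)
    seed: int = 0
    view: str = "sax-mid"

    def __post_init__(self) -> None:
        if not 0.0 < self.R_endo < self.R_epi:
            raise ValueError("need 0 < R_endo < R_epi")
        if not 0.0 <= self.contraction < 1.0:
            raise ValueError("contraction fraction must lie in [0, 1)")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if not (1 <= self.peak_frame <= self.n_frames - 2):
            raise ValueError("peak_frame must lie within the cycle interior")
        # deformed endocardial radius stays positive automatically for a < 1;
        # reject annuli whose deformed endo circle would collapse numerically
        if self.R_endo * (1.0 - self.contraction) <= 0.5 * self.pixel_spacing:
            raise ValueError(
                "degenerate annulus: deformed endocardial radius "
                f"{self.R_endo * (1 - self.contraction):.2f} mm collapses below pixel scale"
            )

    @property
    def center_mm(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.image_size - 1) / 2.0 * self.pixel_spacing
        return (c, c)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            (self.image_size, self.image_size), (self.pixel_spacing, self.pixel_spacing)
        )


class SaxStrainOracle:
    """Closed-form kinematics and strain of the incompressible annulus."""

    def __init__(self, spec: SaxPhantomSpec):
        self.spec = spec

    def phase(self, t: np.ndarray | float) -> np.ndarray:
        return systolic_waveform(t, self.spec.peak_frame, self.spec.n_frames)

    def endo_radius(self, t: np.ndarray | float) -> np.ndarray:
        return self.spec.R_endo * (1.0 - self.spec.contraction * self.phase(t))

    def deformed_radius(self, r: np.ndarray | float, t: np.ndarray | float) -> np.ndarray:
        """Radius at phase t of the material circle at reference radius r.

        Inside the cavity (r < R_endo) the map is a uniform radial scaling,
        continuous with the incompressible annulus map at r = R_endo.
        """
        r = np.asarray(r, dtype=float)
        Re_t = self.endo_radius(t)
        Re0 = self.spec.R_endo
        annulus = np.sqrt(np.maximum(r**2 - Re0**2 + Re_t**2, 0.0))
        cavity = r * Re_t / Re0
        return np.where(r >= Re0, annulus, cavity)

    def reference_radius(self, rho: np.ndarray | float, t: np.ndarray | float) -> np.ndarray:
        """Inverse map: reference radius of the point at radius rho at phase t."""
        rho = np.asarray(rho, dtype=float)
        Re_t = self.endo_radius(t)
        Re0 = self.spec.R_endo
        annulus = np.sqrt(np.maximum(rho**2 - Re_t**2 + Re0**2, 0.0))
        cavity = rho * Re0 / np.maximum(Re_t, 1e-12)
        return np.where(rho >= Re_t, annulus, cavity)

    def strain(self, r: np.ndarray | float, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """(Err, Ecc) in % at reference radius r, phase t (engineering strain).

        Valid inside the wall only; raises for points outside [R_endo, R_epi].
        """
        r = np.asarray(r, dtype=float)
        if np.any(r < self.spec.R_endo - 1e-9) or np.any(r > self.spec.R_epi + 1e-9):
            raise ValueError("strain oracle queried outside the phantom wall")
        rp = self.deformed_radius(r, t)
        ecc = (rp / r - 1.0) * 100.0
        err = (r / rp - 1.0) * 100.0
        return err, ecc

    def layer_mean_ecc(self, t: np.ndarray | float, depth_lo: float, depth_hi: float,
                       n: int = 2000) -> float:
        """Area-weighted mean Ecc (%) over the transmural band d in [lo, hi).

        Depth is linear in radius for concentric circles, so the band maps to
        radii [R_endo + lo*w, R_endo + hi*w] with w the wall thickness.
        """
        w = self.spec.R_epi - self.spec.R_endo
        r = np.linspace(self.spec.R_endo + depth_lo * w, self.spec.R_endo + depth_hi * w, n)
        _, ecc = self.strain(r, t)
        return float(np.average(ecc, weights=r))  # annular area element ~ r dr


def _smooth_texture(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    return (tex - tex.mean()) / tex.std()


def build_sax_phantom(
    spec: SaxPhantomSpec,
) -> tuple[CineSequence, ContourPair, SaxStrainOracle]:
    """Render the short-axis phantom.

    Returns the cine sequence (frame 0 = reference / end-diastole analog),
    the exact end-diastolic contours (circles), and the strain oracle.
    The texture is generated once on a 2x oversampled material grid and
    sampled at the analytically inverted map, so every frame shows the same
    material pattern in its deformed position.
    """
    oracle = SaxStrainOracle(spec)
    rng = np.random.default_rng(spec.seed)
    over = 2
    tex_spacing = spec.pixel_spacing / over
    tex = _smooth_texture(
        (spec.image_size * over, spec.image_size * over),
        spec.texture_scale / tex_spacing,
        rng,
    )

    xs, ys = spec.grid.pixel_centers()
    cx, cy = spec.center_mm
    dx, dy = xs - cx, ys - cy
    rho = np.hypot(dx, dy)

    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size))
    for t in range(spec.n_frames):
        r_ref = oracle.reference_radius(rho, t)
        scale = np.where(rho > 1e-9, r_ref / np.maximum(rho, 1e-9), 1.0)
        mat_x, mat_y = cx + dx * scale, cy + dy * scale
        img = ndimage.map_coordinates(
            tex, [mat_y / tex_spacing, mat_x / tex_spacing], order=1, mode="wrap"
        )
        frames[t] = img + spec.noise_sd * rng.standard_normal(img.shape)

    cine = CineSequence(
        frames=frames,
        grid=spec.grid,
        frame_times=np.arange(spec.n_frames) * DEFAULT_FRAME_TIME_MS,
        view=spec.view,
    )
    contours = ContourPair(
        endo=circle_contour((cx, cy), spec.R_endo),
        epi=circle_contour((cx, cy), spec.R_epi),
        view=spec.view,
    )
    return cine, contours, oracle


@dataclass(frozen=True)
class LaxPhantomSpec:
    """Long-axis band phantom: a vertical wall strip shortening toward the base.

    The midline runs from the basal anchor (held fixed) down to the apex;
    the local longitudinal engineering strain interpolates linearly in the
    normalized midline position s from ``eps_base`` (s=0) to ``eps_apex``
    (s=1), scaled by the systolic waveform.  Defaults mirror normative
    basal/apical longitudinal shortening.
    """

    length: float = 80.0  # mm, base-to-apex midline length
    thickness: float = 8.0  # mm, wall thickness
    eps_base: float = -0.24  # peak longitudinal strain at the base
    eps_apex: float = -0.132  # peak longitudinal strain at the apex
    n_frames: int = 25
    peak_frame: int = 9
    image_size: int = 128
    pixel_spacing: float = 1.0
    texture_scale: float = 3.0
    noise_sd: float = 0.05
    seed: int = 0
    view: str = "lax-4ch"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.thickness <= 0:
            raise ValueError("degenerate band geometry: length and thickness must be positive")
        if self.eps_base <= -1.0 or self.eps_apex <= -1.0:
            raise ValueError("strain <= -100% collapses the band")
        if self.n_frames < 3 or not (1 <= self.peak_frame <= self.n_frames - 2):
            raise ValueError("peak_frame must lie within the cycle interior")
        if self.length + 2 * self.pixel_spacing > self.image_size * self.pixel_spacing:
            raise ValueError("band does not fit in the image")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            (self.image_size, self.image_size), (self.pixel_spacing, self.pixel_spacing)
        )

    @property
    def base_point(self) -> tuple[float, float]:
        """Basal midline anchor (mm); band is vertical, centered in x."""
        cx = (self.image_size - 1) / 2.0 * self.pixel_spacing
        y0 = ((self.image_size - 1) * self.pixel_spacing - self.length) / 2.0
        return (cx, y0)

    @property
    def midline(self) -> np.ndarray:
        """Reference midline polyline, base -> apex."""
        cx, y0 = self.base_point
        s = np.linspace(0.0, 1.0, 64)
        return np.column_stack([np.full_like(s, cx), y0 + s * self.length])


@dataclass
class BandContour:
    """Long-axis wall reference geometry: midline polyline (mm, base first)
    plus constant wall thickness.  The wall occupies all points within
    ``thickness / 2`` of the midline."""

    midline: np.ndarray
    thickness: float
    view: str = "lax-4ch"

    def __post_init__(self) -> None:
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 2 or self.midline.shape[0] < 2:
            raise ValueError("midline must be an (N>=2, 2) polyline")
        if self.thickness <= 0:
            raise ValueError("wall thickness must be positive")


class LaxStrainOracle:
    """Closed-form longitudinal strain of the band phantom."""

    def __init__(self, spec: LaxPhantomSpec):
        self.spec = spec

    def phase(self, t: np.ndarray | float) -> np.ndarray:
        return systolic_waveform(t, self.spec.peak_frame, self.spec.n_frames)

    def strain(self, s: np.ndarray | float, t: np.ndarray | float) -> np.ndarray:
        """Ell in % at normalized midline position s (0=base, 1=apex), phase t."""
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-9) or np.any(s > 1.0 + 1e-9):
            raise ValueError("midline position s must lie in [0, 1]")
        eps = self.spec.eps_base + (self.spec.eps_apex - self.spec.eps_base) * s
        return eps * self.phase(t) * 100.0

    def deformed_arclength(self, s: np.ndarray | float, t: np.ndarray | float) -> np.ndarray:
        """Distance (mm) from the fixed basal anchor to material point s at phase t.

        Integral of the local stretch 1 + eps(s', t) along the midline.
        """
        s = np.asarray(s, dtype=float)
        w = self.phase(t)
        eb, ea = self.spec.eps_base, self.spec.eps_apex
        return self.spec.length * (s + w * (eb * s + 0.5 * (ea - eb) * s**2))


def build_lax_phantom(
    spec: LaxPhantomSpec,
) -> tuple[CineSequence, "BandContour", LaxStrainOracle]:
    """Render the long-axis band phantom.

    Material points move along the (vertical) midline so the local
    longitudinal engineering strain equals the oracle's profile; the
    transverse coordinate is unchanged.  Pixels beyond the band ends follow
    the end strain, keeping the warp globally smooth and invertible.
    Returns the cine, the reference wall contours (the band rectangle split
    into its two long edges), and the oracle.
    """
    oracle = LaxStrainOracle(spec)
    rng = np.random.default_rng(spec.seed)
    over = 2
    tex_spacing = spec.pixel_spacing / over
    tex = _smooth_texture(
        (spec.image_size * over, spec.image_size * over),
        spec.texture_scale / tex_spacing,
        rng,
    )

    xs, ys = spec.grid.pixel_centers()
    cx, y0 = spec.base_point
    L = spec.length

    # invert the monotone arclength map numerically on a fine 1-D table,
    # extended linearly beyond the band with the end strains
    s_fine = np.linspace(-0.5, 1.5, 4097)
    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size))
    for t in range(spec.n_frames):
        w = float(oracle.phase(t))
        eb, ea = spec.eps_base, spec.eps_apex
        s_clip = np.clip(s_fine, 0.0, 1.0)
        lam_in = oracle.deformed_arclength(s_clip, t)
        below = (s_fine < 0.0)
        above = (s_fine > 1.0)
        lam = lam_in.copy()
        lam[below] = L * s_fine[below] * (1.0 + w * eb)
        lam[above] = lam_in[above] + L * (s_fine[above] - 1.0) * (1.0 + w * ea)
        # deformed y of material s: y0 + lam; invert for each pixel row
        y_def = y0 + lam
        s_of_y = np.interp(ys[:, 0], y_def, s_fine)
        mat_y = (y0 + s_of_y * L)[:, None] * np.ones_like(xs)
        mat_x = xs
        img = ndimage.map_coordinates(
            tex, [mat_y / tex_spacing, mat_x / tex_spacing], order=1, mode="wrap"
        )
        frames[t] = img + spec.noise_sd * rng.standard_normal(img.shape)

    cine = CineSequence(
        frames=frames,
        grid=spec.grid,
        frame_times=np.arange(spec.n_frames) * DEFAULT_FRAME_TIME_MS,
        view=spec.view,
    )
    contours = BandContour(midline=spec.midline, thickness=spec.thickness, view=spec.view)
    return cine, contours, oracle
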