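"""Strain maps and curves: affine oracles, phantom fields, peak detection."""

import numpy as np
import pytest

from cinestrain import (
    ContourPair,
    GridSpec,
    directional_strain_field,
    peak_systolic,
    strain_curves,
)
from cinestrain.core import DisplacementField, circle_contour
from cinestrain.geometry import compute_local_directions, rasterize_myocardium
from cinestrain.strain import StrainCurve

GRID = GridSpec((96, 96), (1.0, 1.0))
CENTER = (47.5, 47.5)


@pytest.fixture(scope="module")
def annulus_geometry():
    contours = ContourPair(
        endo=circle_contour(CENTER, 25.0), epi=circle_contour(CENTER, 33.0)
    )
    mask = rasterize_myocardium(contours, GRID)
    return compute_local_directions(contours, mask, GRID)


def _analytic_field(oracle, spec, t):
    """Exact displacement of the annulus phantom on the reference grid."""
    xs, ys = spec.grid.pixel_centers()
    cx, cy = spec.center_mm
    r0 = np.maximum(np.hypot(xs - cx, ys - cy), 1e-9)
    scale = oracle.deformed_radius(r0, t) / r0
    u = np.stack([(xs - cx) * (scale - 1), (ys - cy) * (scale - 1)], axis=-1)
    return DisplacementField(u, spec.grid, t)


class TestDirectionalStrain:
    def test_zero_displacement_zero_strain(self, annulus_geometry):
        fld = DisplacementField(np.zeros(GRID.shape + (2,)), GRID, 0)
        m = directional_strain_field(fld, annulus_geometry, "Ecc")
        assert np.allclose(m[annulus_geometry.mask], 0.0)
        assert np.all(np.isnan(m[~annulus_geometry.mask]))

    def test_uniform_stretch_along_x(self, annulus_geometry):
        xs, _ = GRID.pixel_centers()
        u = np.zeros(GRID.shape + (2,))
        u[..., 0] = 0.1 * xs  # x' = 1.1 x
        fld = DisplacementField(u, GRID, 1)
        geo = annulus_geometry
        ex = np.zeros(GRID.shape + (2,))
        ex[..., 0] = 1.0
        geo_x = type(geo)(grid=geo.grid, mask=geo.mask, depth=geo.depth, e_r=ex, e_c=geo.e_c)
        m = directional_strain_field(fld, geo_x, "Err")
        inner = geo.mask.copy()
        inner[:1], inner[-1:], inner[:, :1], inner[:, -1:] = False, False, False, False
        assert np.allclose(m[inner], 10.0, atol=1e-6)

    def test_green_lagrange_flag(self, annulus_geometry):
        xs, _ = GRID.pixel_centers()
        u = np.zeros(GRID.shape + (2,))
        u[..., 0] = 0.1 * xs
        fld = DisplacementField(u, GRID, 1)
        ex = np.zeros(GRID.shape + (2,))
        ex[..., 0] = 1.0
        geo = annulus_geometry
        geo_x = type(geo)(grid=geo.grid, mask=geo.mask, depth=geo.depth, e_r=ex, e_c=geo.e_c)
        m = directional_strain_field(fld, geo_x, "Err", measure="green")
        inner = geo.mask.copy()
        inner[:1], inner[-1:], inner[:, :1], inner[:, -1:] = False, False, False, False
        assert np.allclose(m[inner], 10.5, atol=1e-6)  # (1.1^2 - 1)/2

    def test_phantom_field_matches_closed_form(self, sax_spec, sax_phantom, annulus_geometry):
        _, _, oracle = sax_phantom
        fld = _analytic_field(oracle, sax_spec, sax_spec.peak_frame)
        ecc = directional_strain_field(fld, annulus_geometry, "Ecc")
        err = directional_strain_field(fld, annulus_geometry, "Err")
        xs, ys = GRID.pixel_centers()
        r0 = np.hypot(xs - CENTER[0], ys - CENTER[1])
        ring = annulus_geometry.mask & (np.abs(r0 - 30.0) < 0.5)
        assert np.nanmean(ecc[ring]) == pytest.approx(-13.4, abs=1.0)
        assert np.nanmean(err[ring]) == pytest.approx(15.5, abs=2.0)

    def test_rotational_symmetry(self, sax_spec, sax_phantom, annulus_geometry):
        """Per-ring spread of Ecc under a rotationally symmetric field is tiny."""
        _, _, oracle = sax_phantom
        fld = _analytic_field(oracle, sax_spec, sax_spec.peak_frame)
        ecc = directional_strain_field(fld, annulus_geometry, "Ecc")
        xs, ys = GRID.pixel_centers()
        r0 = np.hypot(xs - CENTER[0], ys - CENTER[1])
        for rq in (26.0, 29.0, 32.0):
            ring = annulus_geometry.mask & (np.abs(r0 - rq) < 0.4)
            assert np.nanstd(ecc[ring]) < 1.0

    def test_sign_structure_through_systole(self, sax_spec, sax_phantom, annulus_geometry):
        """Contraction gives Ecc < 0 and Err > 0 at every systolic phase."""
        _, _, oracle = sax_phantom
        interior = annulus_geometry.mask & (annulus_geometry.depth > 0.1) \
            & (annulus_geometry.depth < 0.9)
        for t in range(1, sax_spec.peak_frame + 1):
            fld = _analytic_field(oracle, sax_spec, t)
            ecc = directional_strain_field(fld, annulus_geometry, "Ecc")
            err = directional_strain_field(fld, annulus_geometry, "Err")
            assert np.nanmax(ecc[interior]) < 0.0
            assert np.nanmin(err[interior]) > 0.0


class TestCurvesAndPeaks:
    def test_single_pixel_region(self, annulus_geometry):
        maps = np.zeros((3,) + GRID.shape)
        rr, cc = np.argwhere(annulus_geometry.mask)[0]
        maps[1, rr, cc] = -7.5
        maps[2, rr, cc] = -3.0
        region = np.zeros(GRID.shape, dtype=bool)
        region[rr, cc] = True
        curves = strain_curves(maps, annulus_geometry, "Ecc", {"pix": region})
        assert curves[0].values.tolist() == [0.0, -7.5, -3.0]

    def test_empty_region_error_names_region(self, annulus_geometry):
        maps = np.zeros((2,) + GRID.shape)
        with pytest.raises(ValueError, match="nothing"):
            strain_curves(maps, annulus_geometry, "Ecc", {"nothing": np.zeros(GRID.shape, bool)})

    @pytest.mark.parametrize(
        "values, direction, expected_value, expected_frame",
        [
            ([0, -5, -12, -18, -10], "Ecc", -18.0, 3),
            ([0, 10, 25, 22], "Err", 25.0, 2),
            ([0, -4, -9, -9, -2], "Ell", -9.0, 2),  # tie -> earliest frame
        ],
    )
    def test_peak_systolic_extrema(self, values, direction, expected_value, expected_frame):
        curve = StrainCurve("global", direction, np.asarray(values, float))
        peak = peak_systolic(curve)
        assert peak.value == expected_value
        assert peak.frame == expected_frame

    def test_layer_ordering_from_analytic_field(
        self, sax_spec, sax_phantom, annulus_geometry
    ):
        """Endocardial circumferential shortening exceeds mid, exceeds epi."""
        _, _, oracle = sax_phantom
        maps = np.stack([
            directional_strain_field(
                _analytic_field(oracle, sax_spec, t), annulus_geometry, "Ecc"
            )
            for t in range(sax_spec.n_frames)
        ])
        curves = {c.region: c for c in strain_curves(maps, annulus_geometry, "Ecc", "layers")}
        peaks = {k: peak_systolic(c).value for k, c in curves.items()}
        assert peaks["endo"] < peaks["mid"] < peaks["epi"] < 0
        for k, (lo, hi) in {"endo": (0, 1 / 3), "mid": (1 / 3, 2 / 3), "epi": (2 / 3, 1)}.items():
            truth = oracle.layer_mean_ecc(sax_spec.peak_frame, lo, hi)
            assert peaks[k] == pytest.approx(truth, abs=1.5)
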