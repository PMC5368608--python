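"""Contour-derived geometry: mask, depth, directions, layers, segments, levels."""

import numpy as np
import pytest

from cinestrain import ContourPair, GridSpec
from cinestrain.core import circle_contour
from cinestrain.geometry import (
    LAYER_NAMES,
    SEGMENT_NAMES,
    assign_layers,
    assign_segments,
    compute_local_directions,
    lax_directions,
    rasterize_myocardium,
    select_levels,
)

GRID = GridSpec((96, 96), (1.0, 1.0))
CENTER = (47.5, 47.5)


@pytest.fixture(scope="module")
def annulus():
    contours = ContourPair(
        endo=circle_contour(CENTER, 25.0), epi=circle_contour(CENTER, 33.0)
    )
    mask = rasterize_myocardium(contours, GRID)
    geo = compute_local_directions(contours, mask, GRID)
    return contours, mask, geo


class TestRasterize:
    def test_annulus_pixel_count_matches_area(self, annulus):
        _, mask, _ = annulus
        area = np.pi * (33.0**2 - 25.0**2)  # 1458 mm^2 at 1 mm spacing
        assert mask.sum() == pytest.approx(area, rel=0.01)

    def test_no_pixel_inside_endocardium(self, annulus):
        contours, mask, _ = annulus
        import shapely

        xs, ys = GRID.pixel_centers()
        inside_endo = shapely.contains_xy(
            contours.endo_polygon, xs[mask], ys[mask]
        )
        assert not inside_endo.any()

    def test_degenerate_contours_rejected(self):
        ring = circle_contour(CENTER, 25.0)
        with pytest.raises(ValueError, match="inside"):
            ContourPair(endo=ring, epi=ring)


class TestDepthAndDirections:
    def test_depth_linear_in_radius(self, annulus):
        _, _, geo = annulus
        xs, ys = GRID.pixel_centers()
        r = np.hypot(xs - CENTER[0], ys - CENTER[1])
        ring = geo.mask & (np.abs(r - 29.0) < 0.5)
        # d = (r - 25) / 8, exact for concentric circles
        assert np.nanmean(geo.depth[ring]) == pytest.approx(0.5, abs=0.03)
        assert np.nanmax(np.abs(geo.depth[geo.mask] - (r[geo.mask] - 25.0) / 8.0)) < 0.02

    def test_depth_boundary_values(self, annulus):
        _, _, geo = annulus
        xs, ys = GRID.pixel_centers()
        r = np.hypot(xs - CENTER[0], ys - CENTER[1])
        near_endo = geo.mask & (r < 25.5)
        near_epi = geo.mask & (r > 32.5)
        assert np.nanmax(geo.depth[near_endo]) < 0.1  # within half a pixel of d=0
        assert np.nanmin(geo.depth[near_epi]) > 0.9

    def test_directions_east_of_center(self, annulus):
        _, _, geo = annulus
        row, col = 47, 47 + 29  # pixel center (76.0, 47.0): nearly due east
        row = int(round(CENTER[1]))  # y = 47.5 has no exact pixel; use closest
        e_r = geo.e_r[row, col]
        e_c = geo.e_c[row, col]
        assert e_r == pytest.approx([1.0, 0.0], abs=0.03)
        assert e_c == pytest.approx([0.0, 1.0], abs=0.03)
        # orthonormality everywhere on the mask
        dots = np.einsum("...i,...i->...", geo.e_r[geo.mask], geo.e_c[geo.mask])
        assert np.allclose(dots, 0, atol=1e-12)
        assert np.allclose(np.hypot(*geo.e_r[geo.mask].T), 1.0)


class TestLayers:
    def test_threshold_rule_with_tie_break(self):
        from cinestrain.core import PixelGeometry

        depth = np.array([[0.2, 0.5, 0.9], [1.0 / 3.0, 2.0 / 3.0, np.nan]])
        mask = np.array([[True] * 3, [True, True, False]])
        geo = PixelGeometry(grid=GridSpec((2, 3)), mask=mask, depth=depth)
        layer = assign_layers(geo)
        # exact 33.3% / 66.6% boundaries belong to the outer layer
        assert layer.tolist() == [[0, 1, 2], [1, 2, -1]]

    def test_layers_partition_mask(self, annulus):
        _, _, geo = annulus
        assert (geo.layer[geo.mask] >= 0).all()
        assert np.bincount(geo.layer[geo.mask], minlength=3).sum() == geo.mask.sum()

    def test_layer_areas_match_analytic_split_radii(self):
        # depth thirds at r = 25 + 8/3 = 27.67 and 25 + 16/3 = 30.33 mm;
        # 0.5 mm sampling keeps ring-band lattice aliasing below 1%
        grid = GridSpec((192, 192), (0.5, 0.5))
        center = (47.75, 47.75)
        contours = ContourPair(
            endo=circle_contour(center, 25.0), epi=circle_contour(center, 33.0)
        )
        geo = compute_local_directions(
            contours, rasterize_myocardium(contours, grid), grid
        )
        areas = np.bincount(geo.layer[geo.mask], minlength=3) * 0.25
        expected = np.pi * np.diff(np.array([25.0, 27.667, 30.333, 33.0]) ** 2)
        assert areas == pytest.approx(expected, rel=0.02)


class TestSegments:
    def test_partition_and_sixth_share(self, annulus):
        _, _, geo = annulus
        seg = assign_segments(geo, reference_angle_deg=90.0)
        labels = seg[geo.mask]
        assert set(np.unique(labels)) == set(range(6))
        counts = np.bincount(labels, minlength=6)
        assert counts == pytest.approx(np.full(6, geo.mask.sum() / 6), rel=0.02)

    def test_rotating_reference_permutes_cyclically(self, annulus):
        _, _, geo = annulus
        a = assign_segments(geo, 90.0)[geo.mask]
        b = assign_segments(geo, 150.0)[geo.mask]
        assert np.array_equal((a + 1) % 6, b % 6)

    def test_missing_reference_angle_is_an_error(self, annulus):
        _, _, geo = annulus
        with pytest.raises(ValueError, match="reference angle"):
            assign_segments(geo, None)

    def test_six_named_segments(self):
        assert SEGMENT_NAMES == ("Ant", "Antsep", "Sep", "Inf", "Post", "Lat")


class TestLevelSelection:
    @pytest.mark.parametrize(
        "n, outflow, apex, expected",
        [
            (9, 0, 8, (0, 4, 6)),
            (3, 0, 2, (0, 1, 2)),
            (8, 1, 7, (1, 4, 6)),  # even stack: mid ties toward apex
            (9, 2, 7, (2, 4, 6)),  # apical midpoint 5.5 rounds toward apex
        ],
    )
    def test_rule(self, n, outflow, apex, expected):
        assert select_levels(n, outflow, apex) == expected

    def test_apex_not_beyond_mid_is_an_error(self):
        with pytest.raises(ValueError, match="apex"):
            select_levels(9, 0, 4)


class TestLaxGeometry:
    def test_vertical_band(self):
        midline = np.column_stack([np.full(33, 47.5), np.linspace(13.0, 83.0, 33)])
        geo = lax_directions(midline, thickness=8.0, grid=GRID)
        # tangent points base -> apex (+y)
        el = geo.e_l[geo.mask]
        assert np.allclose(el[:, 0], 0.0, atol=1e-9)
        assert np.allclose(el[:, 1], 1.0, atol=1e-9)
        # mask is ~ 8 mm x 70 mm
        assert geo.mask.sum() == pytest.approx(8 * 70, rel=0.05)
        # levels split the arc into thirds
        counts = np.bincount(geo.level[geo.mask], minlength=3)
        assert counts == pytest.approx(np.full(3, geo.mask.sum() / 3), rel=0.06)
        # depth spans the wall thickness
        assert np.nanmin(geo.depth[geo.mask]) < 0.1
        assert np.nanmax(geo.depth[geo.mask]) > 0.9

    def test_empty_band_rejected(self):
        midline = np.array([[500.0, 500.0], [600.0, 600.0]])  # off-grid
        with pytest.raises(ValueError):
            lax_directions(midline, 8.0, GRID)
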