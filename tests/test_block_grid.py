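"""Grid construction: 4-px division counts, band curves, tiling quality."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import respitune as rt
from respitune.block_grid import (
    SIDE_CHAINS,
    build_band_curves,
    lung_polygon,
    points_at_fractions,
    polyline_arclength,
    subdivide_bands,
    _side_polylines,
)
from respitune.lung_geometry import GeometryError


def rect_contour(width=24.0, height=40.0, x0=10.0, y0=10.0):
    """Rectangle-like left-lung contour: straight sides, 12 control points."""
    pts = np.zeros((12, 2))
    # anchors P1 (top-left), P3 (top-right), P5 (bottom-right), P7 (bottom-left)
    pts[0] = (x0, y0)
    pts[2] = (x0 + width, y0)
    pts[4] = (x0 + width, y0 + height)
    pts[6] = (x0, y0 + height)
    pts[1] = (x0 + width / 2, y0)  # P2 apex control (midline top)
    pts[3] = (x0 + width, y0 + height / 2)  # P4
    pts[5] = (x0 + width / 2, y0 + height)  # P6 base control (midline bottom)
    # medial chain P7 -> P9 -> P11 -> P1 straight up the left edge
    pts[8] = (x0, y0 + 2 * height / 3)  # P9
    pts[10] = (x0, y0 + height / 3)  # P11
    pts[7] = (x0, y0 + 5 * height / 6)  # P8
    pts[9] = (x0, y0 + height / 2)  # P10
    pts[11] = (x0, y0 + height / 6)  # P12
    return pts


class TestGridSpec:
    def test_forty_px_side_gives_ten_divisions(self, toy_left_contour):
        spec = rt.compute_grid_spec(toy_left_contour, "left")
        assert spec.M == 10

    def test_division_segments_are_4px_arcs(self, toy_left_contour):
        """Dividing the 40 px side into M pieces leaves 4 px per segment."""
        spec = rt.compute_grid_spec(toy_left_contour, "left")
        a, b = _side_polylines(toy_left_contour, "left")
        shorter = min((a, b), key=polyline_arclength)
        fr = np.linspace(0, 1, spec.M + 1)
        split = points_at_fractions(shorter, fr)
        seg_lengths = np.linalg.norm(np.diff(split, axis=0), axis=1)
        np.testing.assert_allclose(seg_lengths, 4.0, atol=0.05)

    def test_minimum_one_division(self):
        tiny = rect_contour(width=3.0, height=3.5)
        spec = rt.compute_grid_spec(tiny, "left")
        assert spec.M == 1
        assert all(n >= 1 for n in spec.n_m)

    def test_degenerate_contour_rejected(self):
        pts = np.zeros((12, 2))
        with pytest.raises(GeometryError, match="degenerate|zero"):
            rt.compute_grid_spec(pts, "left")

    def test_spec_fixed_from_expiration_reused_for_larger_frames(self, tiny_analysis):
        """M and N_m never change even when other frames' contours are larger."""
        res = tiny_analysis
        assert res.grid.polys.shape[1] == sum(
            res.specs[s].n_cells for s in ("left", "right")
        )
        # every frame has the same cell count and ids by construction
        assert len(res.grid.ids) == res.grid.n_cells


class TestBandCurves:
    def test_curve0_and_curveM_hit_apex_and_base_anchors(self, toy_left_contour):
        curves = build_band_curves(toy_left_contour, "left", m=10)
        np.testing.assert_allclose(curves[0, 0], toy_left_contour[0])  # P1
        np.testing.assert_allclose(curves[0, -1], toy_left_contour[2])  # P3
        np.testing.assert_allclose(curves[-1, 0], toy_left_contour[6])  # P7
        np.testing.assert_allclose(curves[-1, -1], toy_left_contour[4])  # P5

    def test_even_spacing_on_rectangle(self):
        """Straight sides + midline supplement give evenly spaced straight bands."""
        height = 40.0
        m = 10
        curves = build_band_curves(rect_contour(height=height), "left", m=m)
        ys = curves[:, :, 1]
        # each band curve is horizontal ...
        assert np.all(np.ptp(ys, axis=1) < 1e-9)
        # ... and spaced height / M apart
        np.testing.assert_allclose(np.diff(ys[:, 0]), height / m, atol=0.5)

    def test_right_lung_curves_hit_its_anchors(self, tiny_phantom):
        pts = tiny_phantom.annotation.right.ep
        curves = build_band_curves(pts, "right", m=8)
        np.testing.assert_allclose(curves[0, 0], pts[0], atol=1e-9)  # P1
        np.testing.assert_allclose(curves[0, -1], pts[2], atol=1e-9)  # P3
        np.testing.assert_allclose(curves[-1, 0], pts[8], atol=1e-9)  # P9
        np.testing.assert_allclose(curves[-1, -1], pts[6], atol=1e-9)  # P7


class TestSubdivision:
    def test_uniform_band_gives_congruent_cells(self):
        contour = rect_contour(width=24.0, height=40.0)
        spec = rt.compute_grid_spec(contour, "left")
        curves = build_band_curves(contour, "left", spec.M)
        cells = subdivide_bands(curves, spec)
        areas = [Polygon(c).area for c in cells]
        np.testing.assert_allclose(areas, np.mean(areas), rtol=0.05)
        np.testing.assert_allclose(np.mean(areas), 4.0 * 4.0, rtol=0.1)

    def test_single_division_band_equals_band_region(self):
        contour = rect_contour(width=3.0, height=40.0)
        spec = rt.compute_grid_spec(contour, "left")
        assert set(spec.n_m) == {1}
        curves = build_band_curves(contour, "left", spec.M)
        cells = subdivide_bands(curves, spec)
        assert len(cells) == spec.M

    def test_band_area_conserved_within_1_percent(self, tiny_phantom):
        pts = tiny_phantom.annotation.left.ep
        spec = rt.compute_grid_spec(pts, "left")
        curves = build_band_curves(pts, "left", spec.M)
        cells = subdivide_bands(curves, spec)
        i = 0
        for m in range(1, spec.M + 1):
            nm = spec.n_m[m - 1]
            band = Polygon(
                np.concatenate([curves[m - 1], curves[m][::-1]])
            )
            cell_area = sum(Polygon(c).area for c in cells[i : i + nm])
            assert abs(cell_area - band.area) / band.area < 0.01
            i += nm

    def test_cells_tile_lung_within_1_percent(self, tiny_phantom):
        """Cells are interior-disjoint and their union covers the lung field."""
        from shapely.ops import unary_union

        pts = tiny_phantom.annotation.left.ep
        spec = rt.compute_grid_spec(pts, "left")
        curves = build_band_curves(pts, "left", spec.M)
        cells = [Polygon(c) for c in subdivide_bands(curves, spec)]
        total = sum(c.area for c in cells)
        union = unary_union(cells)
        lung = lung_polygon(pts, "left")
        assert abs(total - union.area) / union.area < 0.01  # disjoint interiors
        assert abs(union.area - lung.area) / lung.area < 0.01  # covers lung


class TestFrameConsistency:
    def test_centroid_motion_bounded_by_contour_motion(self, tiny_analysis):
        res = tiny_analysis
        grid = res.grid
        for t in (0, grid.n_frames // 2):
            d_cells = np.linalg.norm(
                grid.centroids(t + 1) - grid.centroids(t), axis=1
            ).max()
            d_contour = max(
                np.linalg.norm(
                    res.contours.at(t + 1, s) - res.contours.at(t, s), axis=1
                ).max()
                for s in ("left", "right")
            )
            assert d_cells <= d_contour + 1e-6
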