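"""Geometric chain: contour, tips, arcs, centile widths.

Oracles are analytic shapes (rectangle, constant-width half annulus,
regular polygon) rasterized at known spacing.
"""

import numpy as np
import pytest

from cc_centile import (
    CCError, CCWarning, ClosedContour, MidsagittalMask,
    extract_contour, extract_width_profile, find_endpoints,
    fit_centile_widths, render_mask, segment_areas, shape_summary,
    split_arcs,
)


class TestExtractContour:
    def test_rectangle_area_perimeter(self, rect_mask):
        c = extract_contour(rect_mask)
        # half-pixel boundary: corners are cut by marching squares
        assert c.area == pytest.approx(800.0, rel=0.01)
        assert c.perimeter == pytest.approx(180.0, rel=0.01)
        assert c.signed_area > 0  # counter-clockwise

    def test_largest_component_wins_with_warning(self):
        grid = np.zeros((40, 60), dtype=bool)
        grid[5:25, 5:55] = True        # 1000 px blob
        grid[30:35, 30:31] = True      # 5 px blob
        with pytest.warns(CCWarning, match="components"):
            c = extract_contour(MidsagittalMask(grid, (1.0, 1.0)))
        assert c.area == pytest.approx(20 * 50, rel=0.01)

    def test_holes_filled_with_warning(self):
        grid = np.zeros((30, 30), dtype=bool)
        grid[5:25, 5:25] = True
        grid[14:16, 14:16] = False
        with pytest.warns(CCWarning, match="holes"):
            c = extract_contour(MidsagittalMask(grid, (1.0, 1.0)))
        assert c.area == pytest.approx(400, rel=0.01)

    def test_empty_mask_errors(self):
        with pytest.raises(CCError) as exc:
            extract_contour(MidsagittalMask(np.zeros((5, 5), bool), (1, 1)))
        assert exc.value.code == "empty-mask"

    def test_border_touching_errors(self):
        grid = np.ones((10, 10), dtype=bool)
        with pytest.raises(CCError) as exc:
            extract_contour(MidsagittalMask(grid, (1, 1)))
        assert exc.value.code == "mask-truncated"


class TestFindEndpoints:
    def test_rectangle_tips_at_short_side_midpoints(self, rect_mask):
        c = extract_contour(rect_mask)
        ia, ip = find_endpoints(c, mask=rect_mask)
        ant, post = c.points[ia], c.points[ip]
        assert ant[0] == pytest.approx(4.5, abs=1.0)
        assert post[0] == pytest.approx(84.5, abs=1.0)
        # vertical midpoint of the bar (rows 5..15 -> y 4.5..14.5)
        assert ant[1] == pytest.approx(9.5, abs=1.0)
        assert post[1] == pytest.approx(9.5, abs=1.0)

    def test_annulus_tips_near_mid_radius(self, annulus_mask):
        c = extract_contour(annulus_mask)
        ia, ip = find_endpoints(c, mask=annulus_mask)
        # centre of the annulus in mask mm coordinates
        cx, cy = 55.0, 5.0
        for idx in (ia, ip):
            x, y = c.points[idx]
            assert abs(y - cy) < 1.5          # on a flat end
            assert np.hypot(x - cx, y - cy) == pytest.approx(45.0, abs=3.0)

    def test_disk_has_no_axis(self, disk_mask):
        c = extract_contour(disk_mask)
        with pytest.raises(CCError) as exc:
            find_endpoints(c, mask=disk_mask)
        assert exc.value.code == "no-elongation"

    def test_hint_overrides_skeleton(self, rect_mask):
        c = extract_contour(rect_mask)
        ia, ip = find_endpoints(c, hint=((4.5, 9.5), (84.5, 9.5)))
        assert c.points[ia][0] < c.points[ip][0]


class TestSplitArcs:
    def test_rectangle_arc_lengths(self, rect_mask):
        c = extract_contour(rect_mask)
        arcs = split_arcs(c, find_endpoints(c, mask=rect_mask))
        for arc in (arcs.dorsal, arcs.ventral):
            length = np.hypot(*np.diff(arc, axis=0).T).sum()
            # one long side plus two half short sides = 90 mm
            assert length == pytest.approx(90.0, rel=0.02)
        assert arcs.dorsal[:, 1].mean() > arcs.ventral[:, 1].mean()

    def test_orientation_invariance(self, rect_mask):
        c = extract_contour(rect_mask)
        ends = find_endpoints(c, mask=rect_mask)
        a1 = split_arcs(c, ends)
        n = len(c.points)
        rev = ClosedContour(c.points[::-1])
        a2 = split_arcs(rev, (n - 1 - ends[0], n - 1 - ends[1]))
        assert np.allclose(a1.dorsal, a2.dorsal)
        assert np.allclose(a1.ventral, a2.ventral)

    def test_adjacent_cut_errors(self, rect_mask):
        c = extract_contour(rect_mask)
        with pytest.raises(CCError) as exc:
            split_arcs(c, (3, 4))
        assert exc.value.code == "degenerate-cut"


class TestFitCentileWidths:
    def test_rectangle_oracle(self, rect_mask):
        prof, cl = extract_width_profile(rect_mask)
        assert prof.n_segments == 100
        assert prof.widths.shape == (99,)
        assert np.allclose(prof.widths[4:95], 10.0, rtol=0.02)
        assert prof.centreline_length == pytest.approx(80.0, rel=0.02)
        assert prof.area == pytest.approx(800.0, rel=0.01)
        assert prof.perimeter == pytest.approx(180.0, rel=0.01)
        assert prof.converged and prof.iterations <= 5

    def test_annulus_oracle(self, annulus_mask):
        prof, cl = extract_width_profile(annulus_mask)
        assert np.allclose(prof.widths[4:95], 10.0, rtol=0.02)
        assert prof.centreline_length == pytest.approx(np.pi * 45, rel=0.02)
        assert prof.area == pytest.approx(np.pi * 450, rel=0.01)

    def test_displacement_monotone_after_three_iterations(
            self, rect_mask, annulus_mask):
        for mask in (rect_mask, annulus_mask):
            prof, _ = extract_width_profile(mask)
            h = prof.displacement_history
            assert all(h[i + 1] <= h[i] + 1e-12 for i in range(2, len(h) - 1))

    def test_segment_area_conservation(self, rect_mask, annulus_mask):
        for mask in (rect_mask, annulus_mask):
            prof, cl = extract_width_profile(mask)
            areas = segment_areas(prof, cl)
            assert len(areas) == 100
            assert areas.sum() == pytest.approx(prof.area, rel=0.015)

    def test_mirror_reverses_widths_exactly(self, annulus_mask):
        prof, _ = extract_width_profile(annulus_mask)
        mirrored = MidsagittalMask(annulus_mask.grid[:, ::-1].copy(),
                                   annulus_mask.spacing)
        prof_m, _ = extract_width_profile(mirrored)
        assert np.array_equal(prof_m.widths, prof.widths[::-1])

    def test_rotation_90_leaves_widths_unchanged(self, rect_mask):
        prof, _ = extract_width_profile(rect_mask)
        rot = MidsagittalMask(np.rot90(rect_mask.grid).copy(), (1.0, 1.0))
        prof_r, _ = extract_width_profile(rot)
        assert np.allclose(np.sort(prof_r.widths[4:95]),
                           np.sort(prof.widths[4:95]), rtol=0.02)


class TestShapeSummary:
    def test_unit_square(self):
        sq = ClosedContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        area, perim = shape_summary(sq)
        assert area == 1.0 and perim == 4.0

    def test_regular_1000gon_approximates_circle(self):
        t = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        poly = ClosedContour(np.column_stack([np.cos(t), np.sin(t)]))
        area, perim = shape_summary(poly)
        assert area == pytest.approx(np.pi, abs=1e-4)
        assert perim == pytest.approx(2 * np.pi, abs=1e-4)


class TestRenderRoundTrip:
    def test_constant_profile_on_arch(self):
        mask = render_mask(np.full(99, 10.0), spacing=0.25)
        prof, _ = extract_width_profile(mask)
        assert np.abs(prof.widths[4:95] - 10.0).max() < 0.5

    def test_straight_sweep_is_a_rectangle(self):
        mask = render_mask(np.full(99, 10.0), spacing=0.25,
                           arch_radius_mm=np.inf, arch_length_mm=80.0)
        prof, _ = extract_width_profile(mask)
        assert prof.area == pytest.approx(800.0, rel=0.02)
        assert np.allclose(prof.widths[4:95], 10.0, rtol=0.03)

    def test_sweep_fold_error(self):
        with pytest.raises(CCError) as exc:
            render_mask(np.full(99, 70.0), arch_radius_mm=30.0)
        assert exc.value.code == "sweep-fold"
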