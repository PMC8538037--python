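"""Shape-descriptor correctness against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.special import ellipe
from skimage import draw

from vicmorph import morphometry as mm
from vicmorph import synth
from vicmorph.morphometry import CellMask


class TestAreaPerimeter:
    def test_square_area_exact(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        a, _ = mm.measure_area_perimeter(CellMask(m, pixel_size=1.0))
        assert a == 100.0

    def test_pixel_size_scaling(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        a1, p1 = mm.measure_area_perimeter(CellMask(m, pixel_size=1.0))
        a2, p2 = mm.measure_area_perimeter(CellMask(m, pixel_size=0.5))
        assert a2 == pytest.approx(a1 / 4) and p2 == pytest.approx(p1 / 2)

    @pytest.mark.parametrize("radius", [25, 50, 100])
    def test_disc_perimeter_within_1pct(self, radius):
        m = np.zeros((2 * radius + 21,) * 2, bool)
        rr, cc = draw.disk((radius + 10, radius + 10), radius)
        m[rr, cc] = True
        _, p = mm.measure_area_perimeter(CellMask(m, pixel_size=1.0))
        assert p == pytest.approx(2 * np.pi * radius, rel=0.01)

    def test_ellipse_perimeter_vs_elliptic_integral(self, ellipse_mask):
        # exact circumference of a 2:1 ellipse via the complete elliptic integral
        a, b = 100.0, 50.0
        p_true = 4 * a * ellipe(1 - (b / a) ** 2)
        _, p = mm.measure_area_perimeter(ellipse_mask)
        assert p == pytest.approx(p_true, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            CellMask(np.zeros((10, 10), bool), pixel_size=1.0)


class TestDegreeOfCircularity:
    def test_circle_identity(self):
        r = 7.0
        assert mm.degree_of_circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_rasterized_disc_near_one(self, disc_mask):
        a, p = mm.measure_area_perimeter(disc_mask)
        assert mm.degree_of_circularity(a, p) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse_doc(self):
        # numeric-perimeter oracle: A = 2*pi, P from the elliptic integral
        a, b = 2.0, 1.0
        P = 4 * a * ellipe(1 - (b / a) ** 2)
        doc = mm.degree_of_circularity(np.pi * a * b, P)
        assert doc == pytest.approx(0.917, abs=0.001)

    def test_isoperimetric_violation_raises(self):
        with pytest.raises(ValueError, match="isoperimetric"):
            mm.degree_of_circularity(100.0, 10.0)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            mm.degree_of_circularity(0.0, 10.0)


class TestElongation:
    def test_circle_is_zero(self, disc_mask):
        assert mm.elongation(disc_mask) == pytest.approx(0.0, abs=0.02)

    def test_axis_aligned_2to1_rectangle_exact(self, rect_mask):
        assert mm.elongation(rect_mask) == 0.5

    def test_rotated_rectangle(self):
        from scipy.ndimage import rotate

        m = np.zeros((60, 110), bool)
        m[5:55, 5:105] = True
        mr = rotate(m.astype(float), 30, order=1) > 0.5
        assert mm.elongation(CellMask(mr, 1.0)) == pytest.approx(0.5, abs=0.01)

    def test_agrees_with_rotating_angle_scan(self):
        """Brute-force oracle: minimum-area bounding box over a fine
        orientation grid matches the rotating-calipers rectangle."""
        rng = np.random.default_rng(11)
        for trial in range(12):
            sp = synth.ShapeParams("Fib", 600, 120, (0.2, 0.8), (0, 3), seed=0)
            cell, _ = synth.gen_cell_mask(sp, rng_seed=int(rng.integers(2**31)))
            contour = mm._contour(cell.mask)
            best = np.inf
            for ang in np.linspace(0, np.pi / 2, 721):
                c, s = np.cos(ang), np.sin(ang)
                rot = contour @ np.array([[c, -s], [s, c]])
                ext = rot.max(axis=0) - rot.min(axis=0)
                if ext[0] * ext[1] < best:
                    best = ext[0] * ext[1]
                    elong_bf = 1.0 - ext.min() / ext.max()
            assert mm.elongation(cell) == pytest.approx(elong_bf, abs=0.01)


class TestAxisRatio:
    def test_circle_is_one(self, disc_mask):
        assert mm.axis_ratio(disc_mask) == pytest.approx(1.0, abs=0.03)

    def test_reciprocal_identity_on_random_shapes(self):
        """axis_ratio x (1 - elongation) = 1 for every mask (same rectangle)."""
        rng = np.random.default_rng(5)
        for cls in ("SMc", "Fib", "myFib"):
            sp = synth.default_shape_params(cls)
            for _ in range(5):
                cell, _ = synth.gen_cell_mask(sp, rng_seed=int(rng.integers(2**31)))
                x = mm.elongation(cell)
                assert mm.axis_ratio(cell) * (1.0 - x) == pytest.approx(1.0, abs=1e-9)

    def test_cutoff_algebra(self):
        # x = 0.667 corresponds to the spindle axis-ratio cutoff of 3
        assert 1.0 / (1.0 - 0.667) == pytest.approx(3.0, abs=0.01)
        # x = 0.5 lies in the intermediate 1.5-3.0 axis-ratio band
        assert 1.5 < 1.0 / (1.0 - 0.5) < 3.0


class TestCountCusps:
    def test_disc_has_none(self, disc_mask):
        assert mm.count_cusps(disc_mask) == 0

    def test_smoothed_triangle_has_three(self):
        sp = synth.ShapeParams("myFib", 600, 1.0, (0.0, 0.05), (3, 3))
        cell, _ = synth.gen_cell_mask(sp, rng_seed=1, elongation=0.02)
        assert mm.count_cusps(cell) == 3

    def test_tiny_contour_warns_and_returns_zero(self):
        m = np.zeros((8, 8), bool)
        m[3:5, 3:5] = True
        with pytest.warns(UserWarning, match="unreliable"):
            assert mm.count_cusps(CellMask(m, 1.0)) == 0

    def test_star_polygon_recovery_95pct(self):
        """Generator ground truth as oracle: k-tip stars, k = 1..8."""
        ok = tot = 0
        for k in range(1, 9):
            sp = synth.ShapeParams("myFib", 800, 100, (0.05, 0.3), (k, k))
            for s in range(10):
                cell, truth = synth.gen_cell_mask(sp, rng_seed=1000 * k + s)
                ok += mm.count_cusps(cell) == truth["n_cusps"]
                tot += 1
        assert ok / tot >= 0.95


class TestInvariances:
    @pytest.mark.parametrize("rot", [1, 2, 3])
    def test_90deg_rotation_exact(self, rot):
        sp = synth.default_shape_params("Fib")
        cell, _ = synth.gen_cell_mask(sp, rng_seed=42)
        rotated = CellMask(np.rot90(cell.mask, rot), cell.pixel_size)
        for f in (mm.elongation, mm.axis_ratio):
            assert f(rotated) == pytest.approx(f(cell), abs=1e-6)
        a0, p0 = mm.measure_area_perimeter(cell)
        a1, p1 = mm.measure_area_perimeter(rotated)
        assert (a1, p1) == (a0, p0)

    def test_arbitrary_rotation_within_2pct(self):
        """Rasterizing the same ellipse at different orientations moves DOC
        and elongation by under 2%."""
        ref = None
        for ang in (0.0, 0.3, 1.1):
            m = np.zeros((260, 260), bool)
            rr, cc = draw.ellipse(130, 130, 40, 90, shape=m.shape, rotation=ang)
            m[rr, cc] = True
            cell = CellMask(m, 1.0)
            a, p = mm.measure_area_perimeter(cell)
            vals = (mm.degree_of_circularity(a, p), mm.elongation(cell))
            if ref is None:
                ref = vals
            else:
                assert vals[0] == pytest.approx(ref[0], rel=0.02)
                assert vals[1] == pytest.approx(ref[1], abs=0.02)

    def test_scale_invariance_of_dimensionless_features(self):
        """Rasterizing the same physical shape at twice the resolution
        leaves the dimensionless descriptors unchanged within tolerance."""
        sp_lo = synth.default_shape_params("myFib", pixel_size=0.65)
        sp_hi = synth.default_shape_params("myFib", pixel_size=0.325)
        lo, t_lo = synth.gen_cell_mask(sp_lo, rng_seed=3)
        hi, t_hi = synth.gen_cell_mask(sp_hi, rng_seed=3)
        assert t_lo["elongation"] == t_hi["elongation"]  # identical polygon
        a0, p0 = mm.measure_area_perimeter(lo)
        a1, p1 = mm.measure_area_perimeter(hi)
        assert a1 == pytest.approx(a0, rel=0.01)
        assert mm.degree_of_circularity(a1, p1) == pytest.approx(
            mm.degree_of_circularity(a0, p0), rel=0.015
        )
        assert mm.elongation(hi) == pytest.approx(mm.elongation(lo), abs=0.01)
        assert mm.count_cusps(hi) == mm.count_cusps(lo)

    def test_disc_doc_is_population_maximum(self):
        rng = np.random.default_rng(9)
        docs = []
        for cls in ("SMc", "Fib", "myFib"):
            sp = synth.default_shape_params(cls)
            for _ in range(4):
                cell, _ = synth.gen_cell_mask(sp, rng_seed=int(rng.integers(2**31)))
                a, p = mm.measure_area_perimeter(cell)
                docs.append(mm.degree_of_circularity(a, p))
        assert max(docs) <= 1.0

    def test_resolution_convergence_on_disc(self):
        """Perimeter error vs the analytic circumference shrinks with radius."""
        errs = []
        for radius in (20, 40, 80):
            m = np.zeros((2 * radius + 11,) * 2, bool)
            rr, cc = draw.disk((radius + 5, radius + 5), radius)
            m[rr, cc] = True
            _, p = mm.measure_area_perimeter(CellMask(m, 1.0))
            errs.append(abs(p / (2 * np.pi * radius) - 1))
        assert errs[2] < errs[0]
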