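"""Generator contracts: determinism, ground-truth round-trips, Poisson
statistics, forward-model correctness."""

import numpy as np
import pytest
from scipy import stats as sps

from vicmorph import afm, morphometry as mm, synth


class TestShapeParamsValidation:
    def test_bad_elongation_range(self):
        with pytest.raises(ValueError):
            synth.ShapeParams("SMc", 200, 50, (0.9, 0.5), (1, 2))

    def test_bad_area(self):
        with pytest.raises(ValueError):
            synth.ShapeParams("SMc", -5, 50, (0.1, 0.5), (1, 2))

    def test_bad_class(self):
        with pytest.raises(ValueError):
            synth.ShapeParams("fibroblast", 200, 50, (0.1, 0.5), (1, 2))


class TestGenCellMask:
    def test_deterministic(self):
        sp = synth.default_shape_params("Fib")
        c1, t1 = synth.gen_cell_mask(sp, rng_seed=5)
        c2, t2 = synth.gen_cell_mask(sp, rng_seed=5)
        assert np.array_equal(c1.mask, c2.mask) and t1 == t2

    def test_single_connected_component(self):
        for cls in ("SMc", "Fib", "myFib"):
            sp = synth.default_shape_params(cls)
            for s in range(5):
                cell, _ = synth.gen_cell_mask(sp, rng_seed=s)
                from skimage.measure import label

                assert label(cell.mask, connectivity=2).max() == 1

    def test_degenerate_area_raises(self):
        sp = synth.default_shape_params("SMc")
        with pytest.raises(ValueError, match="degenerate"):
            synth.gen_cell_mask(sp, rng_seed=0, area=10.0)

    def test_smc_elongation_within_range(self):
        """Generator self-consistency: measured elongation of a rendered
        spindle lies in the requested band up to raster tolerance."""
        sp = synth.ShapeParams("SMc", 230, 102, (0.85, 0.95), (2, 2))
        for s in range(8):
            cell, truth = synth.gen_cell_mask(sp, rng_seed=s)
            x = mm.elongation(cell)
            assert 0.85 - 0.03 <= x <= 0.95 + 0.03
            assert x == pytest.approx(truth["elongation"], abs=0.03)

    def test_myfib_area_distribution_mean(self):
        """Sample mean of generated areas matches the configured mean
        (998 um^2 myofibroblast population) within sampling error."""
        sp = synth.default_shape_params("myFib")
        areas = [synth.gen_cell_mask(sp, rng_seed=s)[1]["area_um2"] for s in range(200)]
        sem = np.std(areas) / np.sqrt(len(areas))
        assert np.mean(areas) == pytest.approx(998.0, abs=3 * sem + 5)

    def test_triangle_has_three_tips(self):
        sp = synth.ShapeParams("myFib", 600, 1.0, (0.0, 0.05), (3, 3))
        cell, truth = synth.gen_cell_mask(sp, rng_seed=2, elongation=0.02)
        assert truth["n_cusps"] == 3
        assert mm.count_cusps(cell) == 3


class TestGenNucleiField:
    def test_zero_density_empty(self):
        fp = synth.FieldParams(density=0.0, field_area=0.1, n_fields=2, seed=1)
        for f in synth.gen_nuclei_field(fp):
            assert f["realized_count"] == 0

    def test_deterministic(self):
        fp = synth.FieldParams(density=300.0, field_area=0.1, n_fields=2, seed=7)
        a = synth.gen_nuclei_field(fp)
        b = synth.gen_nuclei_field(fp)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa["centroids_um"], fb["centroids_um"])

    def test_hard_core_separation(self):
        from scipy.spatial.distance import pdist

        fp = synth.FieldParams(density=700.0, field_area=0.15, n_fields=1, seed=3)
        pts = synth.gen_nuclei_field(fp)[0]["centroids_um"]
        assert pdist(pts).min() >= synth.MIN_NUCLEUS_SEP_UM

    def test_poisson_mean_and_dispersion(self):
        """Counts over many fields match mean ~ variance ~ density x area
        (chi-square dispersion test at 1% level)."""
        fp = synth.FieldParams(density=500.0, field_area=0.05, n_fields=80, seed=11)
        counts = np.array([f["realized_count"] for f in synth.gen_nuclei_field(fp)])
        expected = 500.0 * 0.05
        assert counts.mean() == pytest.approx(expected, rel=0.10)
        # index-of-dispersion statistic ~ chi2(n-1) under Poisson
        stat = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = sps.chi2.ppf([0.005, 0.995], len(counts) - 1)
        assert lo < stat < hi

    def test_realized_density_matches_nominal(self):
        fp = synth.FieldParams(density=773.0, field_area=0.15, n_fields=25, seed=5)
        fields = synth.gen_nuclei_field(fp)
        dens = [f["realized_count"] / f["field_area_mm2"] for f in fields]
        sem = np.std(dens) / np.sqrt(len(dens))
        assert np.mean(dens) == pytest.approx(773.0, abs=3 * sem)


class TestGenMarkerField:
    def test_fraction_zero_is_pure_background(self):
        sp = synth.default_shape_params("Fib")
        cell, _ = synth.gen_cell_mask(sp, rng_seed=1)
        f = synth.gen_marker_field(cell, 0.0, background_level=0.3, noise_sd=0.0, rng_seed=0)
        inside = f["marker"][cell.mask]
        assert not f["truth_painted"].any()
        assert np.allclose(inside, 0.3)

    def test_fraction_above_one_rejected(self):
        sp = synth.default_shape_params("Fib")
        cell, _ = synth.gen_cell_mask(sp, rng_seed=1)
        with pytest.raises(ValueError):
            synth.gen_marker_field(cell, 1.2)

    @pytest.mark.parametrize("mode", ["punctae", "filament", "coloc"])
    @pytest.mark.parametrize("frac", [0.05, 0.21])
    def test_painted_count_exact(self, mode, frac):
        sp = synth.default_shape_params("myFib")
        cell, _ = synth.gen_cell_mask(sp, rng_seed=4)
        f = synth.gen_marker_field(cell, frac, background_level=0.0, noise_sd=0.0,
                                   rng_seed=9, mode=mode)
        assert f["truth_painted"].sum() == round(frac * cell.mask.sum())

    def test_deterministic(self):
        sp = synth.default_shape_params("myFib")
        cell, _ = synth.gen_cell_mask(sp, rng_seed=4)
        f1 = synth.gen_marker_field(cell, 0.07, rng_seed=3)
        f2 = synth.gen_marker_field(cell, 0.07, rng_seed=3)
        assert np.array_equal(f1["marker"], f2["marker"])


class TestGenForceCurve:
    def test_precontact_force_zero_noiseless(self):
        p = synth.CurveParams(E_true=5.5, noise_sd=0.0, seed=0)
        c = synth.gen_force_curve(p)
        pre = c.z < p.contact_offset
        assert np.allclose(c.d[pre], 0.0)

    def test_trigger_at_max_indentation(self):
        p = synth.CurveParams(E_true=5.5, noise_sd=0.0)
        c = synth.gen_force_curve(p)
        delta = (c.z - p.contact_offset) - c.d
        assert delta.max() == pytest.approx(250.0, abs=0.5)

    def test_closed_form_at_full_indentation(self):
        """Single-point oracle: F at 250 nm from the closed form."""
        E, R, nu = 5.5, 4.0, 0.5
        f_oracle = (4.0 / 3.0) * (E / (1 - nu**2)) * np.sqrt(R) * (250.0 / 1000.0) ** 1.5
        p = synth.CurveParams(E_true=E, bead_radius=R, poisson_ratio=nu, noise_sd=0.0)
        c = synth.gen_force_curve(p)
        F = c.k * c.d
        assert F.max() == pytest.approx(f_oracle, rel=1e-3)

    def test_refit_recovers_exactly(self):
        p = synth.CurveParams(E_true=5.5, noise_sd=0.0, seed=0)
        c = afm.ForceCurve.from_synthetic(synth.gen_force_curve(p))
        delta, F = afm.to_force_indentation(c, p.contact_offset)
        fit = afm.hertz_fit(delta, F, R_um=p.bead_radius, nu=p.poisson_ratio)
        assert fit.E_kPa == pytest.approx(5.5, rel=1e-6)


class TestGenHeightProfile:
    def test_zero_target_constant(self):
        pr = synth.gen_height_profile("flat", 0.0, rng_seed=1)
        assert np.all(pr["h_nm"] == 0.0)

    def test_rms_rescaled_exactly(self):
        for kind, target in (("flat", 20.8), ("fibrous", 423.0)):
            pr = synth.gen_height_profile(kind, target, rng_seed=2)
            assert afm.line_rms_roughness(pr["x_um"], pr["h_nm"]) == pytest.approx(target, rel=0.02)

    def test_deterministic(self):
        a = synth.gen_height_profile("fibrous", 522.0, rng_seed=8)
        b = synth.gen_height_profile("fibrous", 522.0, rng_seed=8)
        assert np.array_equal(a["h_nm"], b["h_nm"])


class TestAnalyticHelpers:
    def test_circle_doc_one(self):
        assert synth.ellipse_doc(1.0) == pytest.approx(1.0)

    def test_doc_aspect_inversion_roundtrip(self):
        for doc in (0.45, 0.6, 0.85):
            assert synth.ellipse_doc(synth.aspect_for_doc(doc)) == pytest.approx(doc, abs=1e-9)


class TestFileInterfaces:
    def test_field_tiff_roundtrip(self, tmp_path):
        import tifffile

        img = np.random.default_rng(0).random((32, 32))
        path = tmp_path / "field.tiff"
        synth.write_field_tiff(path, {"dapi": img, "actin": img, "marker": img},
                               pixel_size=0.65, truth={"n": 3})
        stack = tifffile.imread(path)
        assert stack.shape == (3, 32, 32)
        assert (tmp_path / "field.tiff.json").exists()

    def test_force_curve_csv_roundtrip(self, tmp_path):
        p = synth.CurveParams(E_true=4.2, noise_sd=0.0)
        c = synth.gen_force_curve(p)
        path = tmp_path / "curve.csv"
        synth.write_force_curve_csv(path, c)
        back = afm.read_force_curve_csv(path)
        assert np.allclose(back.z, c.z) and np.allclose(back.d, c.d)
        assert back.k == c.k and back.R == c.R
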