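import dataclasses

import numpy as np
import pytest
import shapely
from scipy import integrate, stats

from infiltra import synthetic
from infiltra.synthetic import (
    ExponentialLaw,
    FlatLaw,
    SyntheticSpec,
    generate_node_stack,
    generate_section,
    law_from_dict,
    simulate_band_counts,
)


class TestSpecValidation:
    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            ExponentialLaw(amplitude_per_mm2=100.0, decay_per_um=-0.01)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            FlatLaw(density_per_mm2=-1.0)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="capsule_fraction"):
            SyntheticSpec(collagen_capsule_fraction=1.2)

    def test_law_from_dict(self):
        law = law_from_dict({"kind": "exponential", "amplitude_per_mm2": 10, "decay_per_um": 0.01})
        assert isinstance(law, ExponentialLaw)
        with pytest.raises(ValueError):
            law_from_dict({"kind": "nope"})

    def test_tumor_too_large_rejected(self):
        spec = SyntheticSpec(image_shape_px=(64, 64), pixel_size_um=1.0, tumor_radius_um=100.0)
        with pytest.raises(ValueError, match="fit"):
            generate_section(spec)


class TestDeterminism:
    def test_section_bit_identical(self, small_exp_spec):
        s1, t1, r1 = generate_section(small_exp_spec)
        s2, t2, r2 = generate_section(dataclasses.replace(small_exp_spec))
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        assert t1.true_cells.equals(t2.true_cells)
        np.testing.assert_array_equal(r1.vertices, r2.vertices)

    def test_node_stack_bit_identical(self):
        spec = SyntheticSpec(
            image_shape_px=(64, 64), pixel_size_um=2.0, n_slices=5, z_step_um=4.0,
            node_radius_um=50.0, n_node_cells=5, seed=9,
        )
        a, ta = generate_node_stack(spec)
        b, tb = generate_node_stack(dataclasses.replace(spec))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert ta.true_cells.equals(tb.true_cells)


class TestSectionGroundTruth:
    def test_zero_density_gives_no_cells(self):
        spec = SyntheticSpec(
            image_shape_px=(128, 128), pixel_size_um=2.0, tumor_radius_um=100.0,
            law=FlatLaw(density_per_mm2=0.0), seed=1,
        )
        _, truth, _ = generate_section(spec)
        assert len(truth.true_cells) == 0

    def test_cells_inside_tumor(self, small_exp_spec):
        _, truth, roi = generate_section(small_exp_spec)
        poly = roi.polygon
        px = small_exp_spec.pixel_size_um
        for row in truth.true_cells.itertuples():
            assert shapely.contains_xy(poly, row.x_um / px, row.y_um / px)
        # and inside the rasterized mask (allowing the border ring)
        for row in truth.true_cells.itertuples():
            r, c = int(round(row.y_um / px)), int(round(row.x_um / px))
            assert truth.tumor_mask[
                max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2
            ].any()

    def test_capsule_mask_subset_and_span(self, small_exp_spec):
        from scipy.ndimage import distance_transform_edt

        _, truth, _ = generate_section(small_exp_spec)
        assert not (truth.capsule_mask & ~truth.tumor_mask).any()
        d_um = distance_transform_edt(truth.tumor_mask) * small_exp_spec.pixel_size_um
        inside = truth.tumor_mask
        np.testing.assert_array_equal(
            truth.capsule_mask, inside & (d_um < small_exp_spec.capsule_width_um)
        )

    def test_flat_law_poisson_expectation(self):
        # tumor of area ~1 mm² (radius 564 µm) at 4 µm/px, rho = 100 / mm²
        spec = SyntheticSpec(
            image_shape_px=(300, 300), pixel_size_um=4.0, tumor_radius_um=564.0,
            law=FlatLaw(density_per_mm2=100.0), background_sd=0.0,
        )
        counts = []
        for seed in range(200):
            _, truth, roi = generate_section(dataclasses.replace(spec, seed=seed))
            counts.append(len(truth.true_cells))
        area_mm2 = roi.area_px2 * (4.0 / 1000.0) ** 2
        expected = 100.0 * area_mm2
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_exponential_band_expectation(self):
        """Pooled band counts match the law integrated over disk annuli (χ² + 3 SE)."""
        A, lam, R = 1500.0, 0.01, 220.0
        spec = SyntheticSpec(
            image_shape_px=(256, 256), pixel_size_um=2.0, tumor_radius_um=R,
            law=ExponentialLaw(A, lam), background_sd=0.0,
        )
        edges = np.arange(0.0, 250.0, 50.0)
        pooled = np.zeros(len(edges) - 1)
        n_seeds = 60
        for seed in range(n_seeds):
            _, truth, _ = generate_section(dataclasses.replace(spec, seed=seed))
            d = truth.true_cells["true_distance_um"].to_numpy()
            pooled += np.histogram(d, bins=edges)[0]

        def rate(d):  # cells per µm of depth: density × annulus circumference
            return (A / 1e6) * np.exp(-lam * d) * 2 * np.pi * (R - d)

        expected = np.array(
            [integrate.quad(rate, lo, hi)[0] for lo, hi in zip(edges[:-1], edges[1:])]
        ) * n_seeds
        assert np.all(np.abs(pooled - expected) < 3 * np.sqrt(expected))
        chi2 = float(((pooled - expected) ** 2 / expected).sum())
        p = stats.chi2.sf(chi2, df=len(expected))
        assert p > 0.01

    def test_truncation_is_logged_not_hidden(self):
        spec = SyntheticSpec(
            image_shape_px=(64, 64), pixel_size_um=2.0, tumor_radius_um=40.0,
            law=FlatLaw(density_per_mm2=0.0), background_mean=0.5, background_sd=2.0,
        )
        stack, truth, _ = generate_section(spec)
        assert truth.n_truncated_pixels > 0
        assert np.all(stack.pixels >= 0)

    def test_ground_truth_csv(self, tmp_path, small_exp_spec):
        _, truth, _ = generate_section(small_exp_spec)
        path = tmp_path / "truth.csv"
        synthetic.write_ground_truth(truth, path)
        header = path.read_text().splitlines()[0]
        assert header == "x_um,y_um,area_um2,true_distance_um"


class TestNodeStack:
    def test_cylinder_volume_exact_in_pixel_units(self):
        spec = SyntheticSpec(
            image_shape_px=(128, 128), pixel_size_um=2.0, n_slices=8, z_step_um=3.0,
            node_shape="cylinder", node_radius_um=80.0, seed=2,
        )
        _, truth = generate_node_stack(spec)
        areas = truth.tumor_mask.sum(axis=(1, 2)) * spec.pixel_size_um**2
        # every slice identical: volume is S·n·Δz exactly
        assert len(set(areas.tolist())) == 1
        assert areas.sum() * spec.z_step_um == pytest.approx(areas[0] * 8 * 3.0)

    def test_hemisphere_close_to_analytic(self):
        R = 100.0
        spec = SyntheticSpec(
            image_shape_px=(128, 128), pixel_size_um=2.0, n_slices=50, z_step_um=R / 50,
            node_shape="hemisphere", node_radius_um=R, seed=3,
        )
        _, truth = generate_node_stack(spec)
        areas = truth.tumor_mask.sum(axis=(1, 2)) * spec.pixel_size_um**2
        vol = areas.sum() * spec.z_step_um
        assert vol == pytest.approx((2 / 3) * np.pi * R**3, rel=0.05)
        assert truth.analytic_volume_um3 == pytest.approx((2 / 3) * np.pi * R**3)

    def test_zero_cells(self):
        spec = SyntheticSpec(
            image_shape_px=(64, 64), pixel_size_um=2.0, n_slices=4, z_step_um=2.0,
            node_radius_um=40.0, n_node_cells=0, seed=4,
        )
        _, truth = generate_node_stack(spec)
        assert len(truth.true_cells) == 0

    def test_planted_cells_inside_tissue(self):
        spec = SyntheticSpec(
            image_shape_px=(96, 96), pixel_size_um=2.0, n_slices=6, z_step_um=4.0,
            node_radius_um=60.0, n_node_cells=12, seed=5,
        )
        _, truth = generate_node_stack(spec)
        assert len(truth.true_cells) == 12
        for row in truth.true_cells.itertuples():
            z = int(round(row.z_um / spec.z_step_um))
            y = int(round(row.y_um / spec.pixel_size_um))
            x = int(round(row.x_um / spec.pixel_size_um))
            assert truth.tumor_mask[z, y, x]


class TestSimulateBandCounts:
    def test_flat_mean(self, rng):
        edges = np.arange(0, 300, 50.0)
        counts = simulate_band_counts(FlatLaw(600.0), edges, 0.1, 2000, rng)
        assert counts.shape == (2000, 5)
        np.testing.assert_allclose(counts.mean(axis=0), 60.0, rtol=0.05)

    def test_exponential_band_means_are_exact_integrals(self, rng):
        edges = np.arange(0, 300, 50.0)
        lam, A = 0.01, 1000.0
        counts = simulate_band_counts(ExponentialLaw(A, lam), edges, 1.0, 5000, rng)
        lo, hi = edges[:-1], edges[1:]
        expected = A * (np.exp(-lam * lo) - np.exp(-lam * hi)) / (lam * 50.0)
        np.testing.assert_allclose(counts.mean(axis=0), expected, rtol=0.05)
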