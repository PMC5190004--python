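import numpy as np
import pytest

from infiltra import geometry
from infiltra.detection import CellRecord, detect_cells, DetectionParams
from infiltra.geometry import BandPartition, DistanceMap, cavalieri_volume
from infiltra.profiles import (
    BinnedCells,
    bin_cells,
    build_density_profile,
    homing_density,
)
from infiltra.synthetic import (
    FlatLaw,
    SyntheticSpec,
    generate_node_stack,
    generate_section,
    simulate_band_counts,
)


def _record(x_um, y_um):
    return CellRecord(
        x_um=x_um, y_um=y_um, z_um=None, area_um2=10.0, volume_um3=None,
        mean_intensity=1.0, component_id=0,
    )


def flat_dmap(value, shape=(10, 10), px=1.0):
    return DistanceMap(values_um=np.full(shape, float(value)), pixel_size_um=px)


def uniform_bands(w, n, px=1.0, count_per_band=10):
    return BandPartition(
        edges_um=w * np.arange(n + 1, dtype=float),
        pixel_counts=np.full(n, count_per_band),
        pixel_size_um=px,
    )


class TestBinCells:
    def test_no_cells(self):
        binned = bin_cells([], flat_dmap(5.0), uniform_bands(10.0, 3))
        assert binned.counts.tolist() == [0, 0, 0]
        assert binned.unassigned == 0

    def test_band_edge_goes_deeper(self):
        # distance exactly at a band edge belongs to the deeper band (half-open)
        binned = bin_cells([_record(2.0, 2.0)], flat_dmap(10.0), uniform_bands(10.0, 3))
        assert binned.counts.tolist() == [0, 1, 0]

    def test_outside_tumor_unassigned(self):
        dmap = DistanceMap(values_um=np.full((10, 10), np.nan), pixel_size_um=1.0)
        binned = bin_cells([_record(2.0, 2.0)], dmap, uniform_bands(10.0, 3))
        assert binned.unassigned == 1

    def test_beyond_max_depth_unassigned(self):
        binned = bin_cells([_record(2.0, 2.0)], flat_dmap(35.0), uniform_bands(10.0, 3))
        assert binned.unassigned == 1
        assert binned.total == 1

    def test_centroid_outside_image_errors(self):
        with pytest.raises(ValueError, match="outside the image"):
            bin_cells([_record(500.0, 2.0)], flat_dmap(5.0), uniform_bands(10.0, 3))

    def test_count_conservation_random(self, rng):
        dmap = DistanceMap(
            values_um=rng.uniform(0, 60, size=(40, 40)), pixel_size_um=1.0
        )
        cells = [
            _record(float(rng.uniform(0, 39)), float(rng.uniform(0, 39)))
            for _ in range(200)
        ]
        binned = bin_cells(cells, dmap, uniform_bands(10.0, 4))
        assert binned.counts.sum() + binned.unassigned == 200

    def test_matches_ground_truth_histogram(self, small_exp_spec):
        """Pixel-distance binning agrees with the exact-distance histogram."""
        stack, truth, roi = generate_section(small_exp_spec)
        mask, _ = geometry.extract_tumor_border(
            roi, image_shape=stack.pixels.shape[1:3]
        )
        dmap = geometry.compute_distance_map(mask, stack.pixel_size_um)
        bands = geometry.partition_bands(dmap, 50.0, 200.0)
        cells = [
            _record(r.x_um, r.y_um) for r in truth.true_cells.itertuples()
        ]
        binned = bin_cells(cells, dmap, bands)
        true_d = truth.true_cells["true_distance_um"].to_numpy()
        w = 50.0
        true_band = np.where(true_d < 200.0, np.floor(true_d / w), -1).astype(int)
        # per-cell agreement, exempting cells within the pixel-discretization
        # slack (1.5 px pitch: centroid rounding + polygon-vs-grid offset) of an edge
        slack = 1.5 * stack.pixel_size_um
        n = len(cells)
        measured_band = []
        for cell in cells:
            col = int(round(cell.x_um / dmap.pixel_size_um))
            row = int(round(cell.y_um / dmap.pixel_size_um))
            idx = bands.band_index(dmap.values_um[row, col])
            measured_band.append(-1 if idx is None else idx)
        exact_agree = np.asarray(measured_band) == true_band
        edge_dist = np.minimum(true_d % w, w - (true_d % w))
        ambiguous = edge_dist <= slack
        ok = exact_agree | ambiguous
        assert ok.mean() >= 0.99
        # and gross counts stay close
        hist = np.histogram(true_d, bins=bands.edges_um)[0]
        assert np.abs(binned.counts - hist).sum() <= max(2, 0.05 * n)


class TestDensityProfile:
    def _binned(self, counts, sample_id, group="g", areas_px=1000):
        bands = uniform_bands(50.0, len(counts), px=1.0, count_per_band=areas_px)
        return BinnedCells(
            counts=np.asarray(counts), unassigned=0, bands=bands,
            sample_id=sample_id, group_label=group,
        )

    def test_density_is_exact_quotient(self):
        binned = self._binned([10, 20], "s1")
        dens = binned.densities_per_mm2()
        assert dens[0] == pytest.approx(10 / 1000 * 1e6)

    def test_single_sample_sem_absent(self):
        prof = build_density_profile([self._binned([5, 5], "s1")])
        assert prof.group_summary["sem"].isna().all()
        assert prof.group_summary["n"].tolist() == [1, 1]

    def test_two_point_sem(self):
        # densities 10 and 20 cells/mm² in one band -> mean 15, SEM 5
        area_px = 1_000_000  # 1 mm² at 1 µm/px
        a = self._binned([10], "s1", areas_px=area_px)
        b = self._binned([20], "s2", areas_px=area_px)
        prof = build_density_profile([a, b])
        row = prof.group_summary.iloc[0]
        assert row["mean_density_per_mm2"] == pytest.approx(15.0)
        assert row["sem"] == pytest.approx(5.0)

    def test_mismatched_edges_rejected(self):
        a = self._binned([1, 2], "s1")
        b = BinnedCells(
            counts=np.array([1, 2]), unassigned=0,
            bands=uniform_bands(25.0, 2), sample_id="s2", group_label="g",
        )
        with pytest.raises(ValueError, match="band edges"):
            build_density_profile([a, b])

    def test_zero_area_band_absent_not_zero(self):
        bands = BandPartition(
            edges_um=np.array([0.0, 50.0, 100.0]),
            pixel_counts=np.array([100, 0]),
            pixel_size_um=1.0,
        )
        binned = BinnedCells(
            counts=np.array([3, 0]), unassigned=0, bands=bands,
            sample_id="s1", group_label="g",
        )
        dens = binned.densities_per_mm2()
        assert np.isnan(dens[1])
        prof = build_density_profile([binned])
        assert prof.group_summary.iloc[1]["n"] == 0

    def test_scale_invariance(self):
        base = self._binned([3, 7, 11], "s1")
        scaled = self._binned([30, 70, 110], "s2")
        d1 = base.densities_per_mm2()
        d2 = scaled.densities_per_mm2()
        np.testing.assert_allclose(d2, 10 * d1)

    def test_ci_coverage_on_flat_law(self, rng):
        """t-based 95% CI covers the true flat density in ≈95% of repetitions."""
        rho, area_mm2, n_samples = 600.0, 0.1, 8
        edges = np.array([0.0, 50.0, 100.0])
        area_px = int(area_mm2 * 1e6)  # at 1 µm/px
        covered = 0
        reps = 300
        for _ in range(reps):
            counts = simulate_band_counts(FlatLaw(rho), edges, area_mm2, n_samples, rng)
            samples = [
                BinnedCells(
                    counts=counts[i], unassigned=0,
                    bands=uniform_bands(50.0, 2, count_per_band=area_px),
                    sample_id=f"s{i}", group_label="g",
                )
                for i in range(n_samples)
            ]
            prof = build_density_profile(samples)
            row = prof.group_summary.iloc[0]
            covered += int(row["ci_lo"] <= rho <= row["ci_hi"])
        assert 0.90 <= covered / reps <= 0.99


class TestHomingDensity:
    def test_cells_per_um2(self):
        hd = homing_density(50, reference_area_um2=1e6)
        assert hd.density == pytest.approx(5e-5)
        assert hd.unit == "cells_per_um2"

    def test_zero_cells(self):
        assert homing_density(0, reference_area_um2=100.0).density == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            homing_density(5, reference_area_um2=0.0)

    def test_requires_exactly_one_reference(self):
        with pytest.raises(ValueError):
            homing_density(5)
        with pytest.raises(ValueError):
            homing_density(5, reference_area_um2=1.0, volume=1.0)

    def test_node_stack_density_matches_analytic(self):
        spec = SyntheticSpec(
            image_shape_px=(128, 128), pixel_size_um=2.0, n_slices=25, z_step_um=4.0,
            node_shape="hemisphere", node_radius_um=100.0, n_node_cells=40,
            background_mean=5.0, background_sd=1.0, seed=21,
        )
        stack, truth = generate_node_stack(spec)
        ch = stack.channel_index("cell_signal")
        areas = [
            float((stack.pixels[z, :, :, ch] >= 40.0).sum()) * 4.0
            for z in range(stack.n_slices)
        ]
        vol = cavalieri_volume(areas, 4.0)
        hd = homing_density(len(truth.true_cells), volume=vol)
        analytic = 40 / (truth.analytic_volume_um3 / 1e9)
        assert hd.unit == "cells_per_mm3"
        assert hd.density == pytest.approx(analytic, rel=0.05)
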