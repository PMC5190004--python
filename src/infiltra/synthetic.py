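"""Synthetic calibrated sections and z-stacks with known ground truth.

Cell placement is an inhomogeneous Poisson process realized by thinning a
homogeneous process, so the expected density at inward border distance ``d``
is exactly the requested law. Ground-truth distances are exact Euclidean
point-to-polygon distances, independent of the pixel distance maps computed
by the analysis code under test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon as ShapelyPolygon
from skimage.draw import disk as draw_disk, polygon2mask

from infiltra.io_formats import ImageStack, RegionOfInterest

logger = logging.getLogger(__name__)

SATURATED = 255.0


@dataclass
class ExponentialLaw:
    """Expected density A·exp(−λ·d) cells/mm² at inward distance d (µm)."""

    amplitude_per_mm2: float
    decay_per_um: float

    kind: Literal["exponential"] = "exponential"

    def __post_init__(self) -> None:
        if self.amplitude_per_mm2 < 0 or self.decay_per_um < 0:
            raise ValueError("amplitude and decay rate must be non-negative")

    def density_at(self, d_um):
        """Expected density (cells/mm²) at inward distance ``d_um``."""
        return self.amplitude_per_mm2 * np.exp(-self.decay_per_um * np.asarray(d_um))


@dataclass
class FlatLaw:
    """Constant expected density cells/mm², independent of border distance."""

    density_per_mm2: float

    kind: Literal["flat"] = "flat"

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError("density must be non-negative")

    def density_at(self, d_um):
        """Expected density (cells/mm²), constant in ``d_um``."""
        return np.full_like(np.asarray(d_um, dtype=float), self.density_per_mm2)


PlacementLaw = ExponentialLaw | FlatLaw


def law_from_dict(doc: dict) -> PlacementLaw:
    """Build a placement law from a config mapping (``kind`` selects the class)."""
    doc = dict(doc)
    kind = doc.pop("kind")
    if kind == "exponential":
        return ExponentialLaw(**doc)
    if kind == "flat":
        return FlatLaw(**doc)
    raise ValueError(f"unknown placement law kind {kind!r}")


@dataclass
class SyntheticSpec:
    """Parameters for one synthetic section or node stack.

    Identical spec + seed gives bit-identical output.
    """

    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    tumor_radius_um: float = 450.0
    tumor_center_px: tuple[float, float] | None = None  # (x, y); default image center
    tumor_polygon_px: np.ndarray | None = None  # explicit (x, y) polygon overrides circle
    capsule_width_um: float = 250.0
    law: PlacementLaw = field(default_factory=lambda: FlatLaw(density_per_mm2=100.0))
    cell_radius_um: float = 3.0
    cell_radius_jitter_um: float = 0.0
    cell_peak_intensity: float = 200.0
    background_mean: float = 10.0
    background_sd: float = 2.0
    collagen_capsule_fraction: float = 0.6
    collagen_interior_fraction: float = 0.1
    # node-stack parameters
    n_slices: int = 1
    z_step_um: float = 2.0
    node_shape: Literal["cylinder", "hemisphere"] = "hemisphere"
    node_radius_um: float = 200.0
    n_node_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.capsule_width_um < 0:
            raise ValueError("capsule_width_um must be non-negative")
        for name in ("collagen_capsule_fraction", "collagen_interior_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    def tumor_polygon(self) -> ShapelyPolygon:
        """Tumor outline in pixel coordinates."""
        if self.tumor_polygon_px is not None:
            return ShapelyPolygon(np.asarray(self.tumor_polygon_px, dtype=float))
        h, w = self.image_shape_px
        cx, cy = self.tumor_center_px if self.tumor_center_px else (w / 2.0, h / 2.0)
        radius_px = self.tumor_radius_um / self.pixel_size_um
        return Point(cx, cy).buffer(radius_px, quad_segs=90)


@dataclass
class GroundTruth:
    """Known truth for a synthetic image."""

    true_cells: pd.DataFrame  # columns: x_um, y_um, area_um2, true_distance_um
    tumor_mask: np.ndarray
    capsule_mask: np.ndarray
    law: PlacementLaw | None = None
    analytic_volume_um3: float | None = None
    n_truncated_pixels: int = 0


def _sample_points_in_polygon(
    poly: ShapelyPolygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside ``poly`` (pixel coords), by bounding-box rejection."""
    import shapely

    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, 2 * (n - len(out)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _place_cells(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Thinned Poisson placement; returns cells with exact border distances (µm)."""
    poly = spec.tumor_polygon()
    area_um2 = poly.area * spec.pixel_size_um**2
    peak_per_um2 = float(spec.law.density_at(0.0)) / 1e6
    n_cand = rng.poisson(peak_per_um2 * area_um2)
    rows = []
    if n_cand > 0:
        import shapely

        pts = _sample_points_in_polygon(poly, n_cand, rng)
        boundary = poly.exterior
        d_um = (
            shapely.distance(boundary, shapely.points(pts)) * spec.pixel_size_um
        )
        accept_p = np.asarray(spec.law.density_at(d_um), dtype=float) / (
            peak_per_um2 * 1e6
        )
        u = rng.uniform(size=n_cand)
        radii = spec.cell_radius_um + (
            rng.uniform(-1, 1, n_cand) * spec.cell_radius_jitter_um
        )
        radii = np.clip(radii, 0.5, None)
        for (x, y), d, r, keep in zip(pts, d_um, radii, u < accept_p):
            if keep:
                rows.append(
                    {
                        "x_um": x * spec.pixel_size_um,
                        "y_um": y * spec.pixel_size_um,
                        "area_um2": math.pi * r**2,
                        "radius_um": r,
                        "true_distance_um": d,
                    }
                )
    columns = ["x_um", "y_um", "area_um2", "radius_um", "true_distance_um"]
    return pd.DataFrame(rows, columns=columns)


def _truncated_background(
    shape: tuple[int, ...], mean: float, sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    noise = rng.normal(mean, sd, size=shape) if sd > 0 else np.full(shape, mean)
    n_neg = int((noise < 0).sum())
    if n_neg:
        logger.info("truncated %d negative background pixels at 0", n_neg)
        noise = np.maximum(noise, 0.0)
    return noise, n_neg


def generate_section(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[ImageStack, GroundTruth, RegionOfInterest]:
    """Render one 2D section: cell channel, collagen channel, tumor ROI.

    Channel 0 is ``cell_signal`` (disks at the stated peak intensity on
    truncated-Gaussian background), channel 1 is ``collagen_shg`` (saturated
    pixels at ``collagen_capsule_fraction`` inside the capsule annulus and
    ``collagen_interior_fraction`` elsewhere inside the tumor).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h, w = spec.image_shape_px
    poly = spec.tumor_polygon()
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError("tumor does not fit inside the image frame")

    cells = _place_cells(spec, rng)

    cell_plane = np.zeros((h, w), dtype=np.float64)
    for row in cells.itertuples(index=False):
        rr, cc = draw_disk(
            (row.y_um / spec.pixel_size_um, row.x_um / spec.pixel_size_um),
            max(row.radius_um / spec.pixel_size_um, 0.6),
            shape=(h, w),
        )
        cell_plane[rr, cc] = np.maximum(cell_plane[rr, cc], spec.cell_peak_intensity)
    background, n_trunc = _truncated_background(
        (h, w), spec.background_mean, spec.background_sd, rng
    )
    cell_plane = cell_plane + background

    verts_xy = np.asarray(poly.exterior.coords)[:-1]
    tumor_mask = polygon2mask((h, w), verts_xy[:, ::-1])
    dist_um = ndimage.distance_transform_edt(tumor_mask) * spec.pixel_size_um
    capsule_mask = tumor_mask & (dist_um < spec.capsule_width_um)

    collagen_plane = np.zeros((h, w), dtype=np.float64)
    u = rng.uniform(size=(h, w))
    interior_mask = tumor_mask & ~capsule_mask
    collagen_plane[capsule_mask & (u < spec.collagen_capsule_fraction)] = SATURATED
    collagen_plane[interior_mask & (u < spec.collagen_interior_fraction)] = SATURATED

    pixels = np.stack([cell_plane, collagen_plane], axis=-1)[np.newaxis, ...]
    stack = ImageStack(
        pixels=pixels.astype(np.float32),
        pixel_size_um=spec.pixel_size_um,
        z_step_um=None,
        channel_roles={0: "cell_signal", 1: "collagen_shg"},
        source_id=f"synthetic-section-seed{spec.seed}",
    )
    truth = GroundTruth(
        true_cells=cells,
        tumor_mask=tumor_mask,
        capsule_mask=capsule_mask,
        law=spec.law,
        n_truncated_pixels=n_trunc,
    )
    roi = RegionOfInterest(
        vertices=verts_xy, label="tumor_mask", source_id=stack.source_id
    )
    return stack, truth, roi


def _node_slice_radius_um(spec: SyntheticSpec, z_um: float) -> float:
    if spec.node_shape == "cylinder":
        return spec.node_radius_um
    if spec.node_shape == "hemisphere":
        if z_um >= spec.node_radius_um:
            return 0.0
        return math.sqrt(spec.node_radius_um**2 - z_um**2)
    raise ValueError(f"unknown node_shape {spec.node_shape!r}")


def node_analytic_volume_um3(spec: SyntheticSpec) -> float:
    """Closed-form volume of the continuous node solid."""
    r = spec.node_radius_um
    if spec.node_shape == "cylinder":
        return math.pi * r**2 * (spec.n_slices * spec.z_step_um)
    if spec.node_shape == "hemisphere":
        return (2.0 / 3.0) * math.pi * r**3
    raise ValueError(f"unknown node_shape {spec.node_shape!r}")


def generate_node_stack(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render a z-stack of a filled solid of known volume with planted point cells.

    Tissue pixels carry a uniform mid intensity; planted cells are saturated
    single-voxel-seeded spots separated by at least 3 voxels so they remain
    distinct connected components.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h, w = spec.image_shape_px
    tissue_intensity = 50.0
    cx, cy = (w / 2.0, h / 2.0)
    planes = np.zeros((spec.n_slices, h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    tissue_masks = []
    for i in range(spec.n_slices):
        z_um = i * spec.z_step_um
        r_px = _node_slice_radius_um(spec, z_um) / spec.pixel_size_um
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        tissue_masks.append(mask)
        planes[i][mask] = tissue_intensity
    tissue = np.stack(tissue_masks)

    cell_rows = []
    if spec.n_node_cells > 0:
        occupied: list[tuple[int, int, int]] = []
        zs, ys, xs = np.nonzero(tissue)
        if len(zs) == 0:
            raise ValueError("node tissue is empty; cannot place cells")
        attempts = 0
        while len(cell_rows) < spec.n_node_cells:
            attempts += 1
            if attempts > 10000 * spec.n_node_cells:
                raise RuntimeError("unable to place requested node cells")
            j = rng.integers(len(zs))
            z, y, x = int(zs[j]), int(ys[j]), int(xs[j])
            if any(
                max(abs(z - oz), abs(y - oy), abs(x - ox)) < 3
                for oz, oy, ox in occupied
            ):
                continue
            occupied.append((z, y, x))
            planes[z, y, x] = SATURATED
            cell_rows.append(
                {
                    "x_um": x * spec.pixel_size_um,
                    "y_um": y * spec.pixel_size_um,
                    "z_um": z * spec.z_step_um,
                    "area_um2": spec.pixel_size_um**2,
                    "true_distance_um": np.nan,
                }
            )
    cells = pd.DataFrame(
        cell_rows, columns=["x_um", "y_um", "z_um", "area_um2", "true_distance_um"]
    )

    background, n_trunc = _truncated_background(
        planes.shape, spec.background_mean, spec.background_sd, rng
    )
    pixels = (planes + background)[..., np.newaxis]
    stack = ImageStack(
        pixels=pixels.astype(np.float32),
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um if spec.n_slices > 1 else None,
        channel_roles={0: "cell_signal"},
        source_id=f"synthetic-node-seed{spec.seed}",
    )
    truth = GroundTruth(
        true_cells=cells,
        tumor_mask=tissue,
        capsule_mask=np.zeros_like(tissue),
        law=None,
        analytic_volume_um3=node_analytic_volume_um3(spec),
        n_truncated_pixels=n_trunc,
    )
    return stack, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the true-cell table (x_um, y_um, area_um2, true_distance_um) as CSV."""
    cols = ["x_um", "y_um", "area_um2", "true_distance_um"]
    truth.true_cells[cols].to_csv(path, index=False, float_format="%.6f")


def simulate_band_counts(
    law: PlacementLaw,
    band_edges_um: np.ndarray,
    area_per_band_mm2: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pre-binned Poisson counts (shape ``(n_samples, n_bands)``) under ``law``.

    The expected count in a band is the law integrated over the band (exact
    for both supported laws) times the band area. Used for fast calibration
    studies that bypass image rendering.
    """
    edges = np.asarray(band_edges_um, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    if isinstance(law, ExponentialLaw) and law.decay_per_um > 0:
        lam = law.decay_per_um
        mean_density = (
            law.amplitude_per_mm2
            * (np.exp(-lam * lo) - np.exp(-lam * hi))
            / (lam * (hi - lo))
        )
    else:
        mean_density = law.density_at((lo + hi) / 2.0)
    expected = mean_density * area_per_band_mm2
    return rng.poisson(expected, size=(n_samples, len(lo)))
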