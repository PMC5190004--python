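"""Tumor border extraction, inward distance maps, concentric bands, Cavalieri volumes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon2mask

from infiltra.io_formats import RegionOfInterest

logger = logging.getLogger(__name__)

#: Sentinel for pixels outside the tumor in a distance map.
OUTSIDE = np.nan


@dataclass
class DistanceMap:
    """Per-pixel inward Euclidean distance (µm) from the outer tumor border.

    ``values_um`` carries NaN for pixels outside the tumor. Distances are
    center-to-center: the distance of an inside pixel to the nearest outside
    pixel, so pixels on the border row carry one pixel pitch.
    """

    values_um: np.ndarray
    pixel_size_um: float

    @property
    def inside(self) -> np.ndarray:
        return ~np.isnan(self.values_um)

    @property
    def max_depth_um(self) -> float:
        return float(np.nanmax(self.values_um))


@dataclass
class BandPartition:
    """Uniform half-open distance bands ``[d_i, d_{i+1})`` with pixel areas."""

    edges_um: np.ndarray
    pixel_counts: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.edges_um = np.asarray(self.edges_um, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=np.int64)
        if len(self.edges_um) != len(self.pixel_counts) + 1:
            raise ValueError("edges must have one more entry than bands")

    @property
    def n_bands(self) -> int:
        return len(self.pixel_counts)

    @property
    def band_width_um(self) -> float:
        return float(self.edges_um[1] - self.edges_um[0])

    @property
    def midpoints_um(self) -> np.ndarray:
        return (self.edges_um[:-1] + self.edges_um[1:]) / 2.0

    @property
    def areas_um2(self) -> np.ndarray:
        return self.pixel_counts * self.pixel_size_um**2

    def band_index(self, distance_um: float) -> int | None:
        """Index of the half-open band containing ``distance_um``; None if out of range."""
        if np.isnan(distance_um) or distance_um < self.edges_um[0]:
            return None
        idx = int(np.floor((distance_um - self.edges_um[0]) / self.band_width_um))
        if idx >= self.n_bands:
            return None
        return idx


@dataclass
class VolumeEstimate:
    """Serial-section volume: each slice area multiplied by the z step."""

    slice_areas_um2: np.ndarray
    z_step_um: float
    volume_um3: float = field(init=False)

    def __post_init__(self) -> None:
        self.slice_areas_um2 = np.asarray(self.slice_areas_um2, dtype=float)
        if self.slice_areas_um2.size < 1:
            raise ValueError("at least one slice area is required")
        if np.any(self.slice_areas_um2 < 0):
            raise ValueError("slice areas must be non-negative")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        self.volume_um3 = float(self.slice_areas_um2.sum() * self.z_step_um)

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 / 1e9


def extract_tumor_border(
    roi_or_mask: RegionOfInterest | np.ndarray,
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the tumor region and return ``(mask, border_contour)``.

    For an ROI input, ``image_shape`` (``(height, width)``) is required. For a
    binary-mask input the largest connected component is kept (warning if more
    than one) and internal holes are filled: the margin is the external contour.
    The returned contour is an ``(n, 2)`` array of ``(x, y)`` points.
    """
    if isinstance(roi_or_mask, RegionOfInterest):
        if image_shape is None:
            raise ValueError("image_shape is required to rasterize an ROI")
        # polygon2mask expects (row, col) points
        mask = polygon2mask(image_shape, roi_or_mask.vertices[:, ::-1])
    else:
        mask = np.asarray(roi_or_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask")

    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.warning(
            "mask has %d components; keeping the dominant one (%d px of %d)",
            n_comp,
            int(sizes.max()),
            int(mask.sum()),
        )
        mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)

    contours = measure.find_contours(mask.astype(float), 0.5)
    contour_rc = max(contours, key=len)
    border_xy = contour_rc[:, ::-1]
    return mask, border_xy


def compute_distance_map(mask: np.ndarray, pixel_size_um: float) -> DistanceMap:
    """Exact Euclidean distance transform of ``mask``, scaled to µm.

    Each in-tumor pixel carries its distance to the nearest outside pixel.
    An all-true mask is rejected: the border must be in frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not mask.any():
        raise ValueError("empty mask")
    if mask.all():
        raise ValueError("mask covers the whole frame; the border must be in frame")
    dist_px = ndimage.distance_transform_edt(mask)
    values = np.where(mask, dist_px * pixel_size_um, OUTSIDE)
    return DistanceMap(values_um=values, pixel_size_um=float(pixel_size_um))


def partition_bands(
    dmap: DistanceMap, band_width_um: float, max_depth_um: float
) -> BandPartition:
    """Partition in-tumor pixels into uniform half-open distance bands.

    ``max_depth_um`` must be an integer multiple of ``band_width_um``. Trailing
    bands deeper than the tumor may have zero area (logged).
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")
    if max_depth_um < band_width_um:
        raise ValueError("max_depth_um must be at least one band width")
    n_bands = int(round(max_depth_um / band_width_um))
    if abs(n_bands * band_width_um - max_depth_um) > 1e-9 * band_width_um:
        raise ValueError("max_depth_um must be a multiple of band_width_um")

    d = dmap.values_um[dmap.inside]
    covered = d[d < max_depth_um]
    idx = np.floor(covered / band_width_um).astype(np.int64)
    counts = np.bincount(idx, minlength=n_bands)
    edges = band_width_um * np.arange(n_bands + 1, dtype=float)
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.info("%d of %d bands have zero area", n_empty, n_bands)
    return BandPartition(
        edges_um=edges, pixel_counts=counts, pixel_size_um=dmap.pixel_size_um
    )


def cavalieri_volume(slice_areas_um2, z_step_um: float) -> VolumeEstimate:
    """Volume as the sum of serial slice areas times the slice spacing."""
    return VolumeEstimate(slice_areas_um2=slice_areas_um2, z_step_um=float(z_step_um))
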