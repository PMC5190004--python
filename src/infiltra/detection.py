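"""Thresholded connected-component cell detection in 2D sections and 3D stacks.

Detection is deliberately simple: intensity threshold, connected components
under a stated connectivity, and a physical size filter. Touching cells merge
into one component — a documented limitation exercised by the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from infiltra.io_formats import ImageStack

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Threshold and size-filter settings.

    ``threshold`` is the absolute intensity τ: pixels with intensity ≥ τ are
    foreground. Area bounds are inclusive and in µm² (volume bounds in µm³
    for stacks). ``connectivity`` is 4 or 8 in 2D, 6 or 26 in 3D.
    """

    threshold: float
    min_area_um2: float = 0.0
    max_area_um2: float = 200.0
    min_volume_um3: float = 0.0
    max_volume_um3: float = math.inf
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be below max_area_um2")
        if not self.min_volume_um3 < self.max_volume_um3:
            raise ValueError("min_volume_um3 must be below max_volume_um3")
        if self.connectivity not in (4, 8, 6, 26):
            raise ValueError("connectivity must be one of 4, 8 (2D) or 6, 26 (3D)")

    def skimage_connectivity(self, ndim: int) -> int:
        table = {(2, 4): 1, (2, 8): 2, (3, 6): 1, (3, 26): 3}
        try:
            return table[(ndim, self.connectivity)]
        except KeyError:
            raise ValueError(
                f"connectivity {self.connectivity} is not valid for {ndim}D"
            ) from None


@dataclass
class CellRecord:
    """One detected cell (2D section) or spot (3D stack)."""

    x_um: float
    y_um: float
    z_um: float | None
    area_um2: float | None
    volume_um3: float | None
    mean_intensity: float
    component_id: int
    sample_id: str = ""


def estimate_background_threshold(
    control_images: Sequence[ImageStack], k: float
) -> float:
    """τ = pooled mean + k·SD of all control cell-channel pixels."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if not control_images:
        raise ValueError("at least one control image is required")
    pools = []
    for stack in control_images:
        ch = stack.channel_index("cell_signal")
        pools.append(np.asarray(stack.pixels[..., ch], dtype=float).ravel())
    pooled = np.concatenate(pools)
    if pooled.size == 0:
        raise ValueError("empty pixel pool")
    return float(pooled.mean() + k * pooled.std())


def detect_cells(
    stack: ImageStack,
    params: DetectionParams,
    z: int = 0,
    sample_id: str = "",
) -> list[CellRecord]:
    """Detect cells in one slice of the cell-signal channel.

    Connected components of pixels ≥ τ become candidates; components outside
    the inclusive area bounds are discarded (each drop logged). Centroids are
    intensity-weighted and reported in µm relative to the image origin.
    """
    if stack.pixel_size_um is None or stack.pixel_size_um <= 0:
        raise ValueError("calibration (pixel_size_um) is required: the area filter is in µm²")
    plane = np.asarray(stack.plane("cell_signal", z=z), dtype=float)
    px2 = stack.pixel_size_um**2

    fg = plane >= params.threshold
    labels = measure.label(fg, connectivity=params.skimage_connectivity(2))
    records: list[CellRecord] = []
    n_dropped = 0
    for prop in measure.regionprops(labels, intensity_image=plane):
        area_um2 = prop.area * px2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            n_dropped += 1
            continue
        cy, cx = prop.centroid_weighted
        records.append(
            CellRecord(
                x_um=cx * stack.pixel_size_um,
                y_um=cy * stack.pixel_size_um,
                z_um=None,
                area_um2=area_um2,
                volume_um3=None,
                mean_intensity=float(prop.intensity_mean),
                component_id=int(prop.label),
                sample_id=sample_id,
            )
        )
    if n_dropped:
        logger.info(
            "detect_cells[%s]: dropped %d component(s) outside area bounds [%g, %g] µm²",
            sample_id or "?",
            n_dropped,
            params.min_area_um2,
            params.max_area_um2,
        )
    return records


def count_spots_3d(
    stack: ImageStack,
    params: DetectionParams,
    sample_id: str = "",
) -> tuple[int, list[CellRecord]]:
    """Count 3D spots as thresholded connected components with a volume filter.

    Single-slice stacks fall back to :func:`detect_cells` (logged notice).
    """
    if stack.n_slices == 1:
        logger.info("count_spots_3d: single-slice stack; falling back to detect_cells")
        conn2d = params.connectivity if params.connectivity in (4, 8) else 8
        params2d = DetectionParams(
            threshold=params.threshold,
            min_area_um2=params.min_area_um2,
            max_area_um2=params.max_area_um2,
            connectivity=conn2d,
        )
        records = detect_cells(stack, params2d, sample_id=sample_id)
        return len(records), records

    ch = stack.channel_index("cell_signal")
    volume = np.asarray(stack.pixels[..., ch], dtype=float)
    voxel_um3 = stack.pixel_size_um**2 * stack.z_step_um

    conn3d = params.connectivity if params.connectivity in (6, 26) else 26
    params3d = DetectionParams(
        threshold=params.threshold,
        min_volume_um3=params.min_volume_um3,
        max_volume_um3=params.max_volume_um3,
        connectivity=conn3d,
    )
    fg = volume >= params.threshold
    labels = measure.label(fg, connectivity=params3d.skimage_connectivity(3))
    records: list[CellRecord] = []
    n_dropped = 0
    for prop in measure.regionprops(labels, intensity_image=volume):
        vol_um3 = prop.area * voxel_um3
        if not (params3d.min_volume_um3 <= vol_um3 <= params3d.max_volume_um3):
            n_dropped += 1
            continue
        cz, cy, cx = prop.centroid_weighted
        records.append(
            CellRecord(
                x_um=cx * stack.pixel_size_um,
                y_um=cy * stack.pixel_size_um,
                z_um=cz * stack.z_step_um,
                area_um2=None,
                volume_um3=vol_um3,
                mean_intensity=float(prop.intensity_mean),
                component_id=int(prop.label),
                sample_id=sample_id,
            )
        )
    if n_dropped:
        logger.info(
            "count_spots_3d[%s]: dropped %d component(s) outside volume bounds",
            sample_id or "?",
            n_dropped,
        )
    return len(records), records


def records_to_frame(records: Sequence[CellRecord]):
    """Tabulate records for CSV export."""
    import pandas as pd

    cols = [
        "sample_id",
        "component_id",
        "x_um",
        "y_um",
        "z_um",
        "area_um2",
        "volume_um3",
        "mean_intensity",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in records], columns=cols
    )
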