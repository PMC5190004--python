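"""Banded density profiles and homing-density summaries.

The aggregation unit is the sample (animal/section): per-band densities are
computed per sample and group statistics (mean, SEM, t-based 95% CI) are taken
across samples, never across pixels. The canonical density unit is cells/mm².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from infiltra.detection import CellRecord
from infiltra.geometry import BandPartition, DistanceMap, VolumeEstimate

logger = logging.getLogger(__name__)

UM2_PER_MM2 = 1e6


@dataclass
class BinnedCells:
    """Per-band cell counts for one sample, plus the unassigned bucket."""

    counts: np.ndarray
    unassigned: int
    bands: BandPartition
    sample_id: str = ""
    group_label: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unassigned

    def densities_per_mm2(self) -> np.ndarray:
        """count/area densities; bands with zero area yield NaN (absent), never 0/0."""
        areas = self.bands.areas_um2
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(areas > 0, self.counts / areas * UM2_PER_MM2, np.nan)
        return dens


@dataclass
class DensityProfile:
    """Per-sample densities and group-level aggregates per band."""

    per_sample: pd.DataFrame
    # columns: group,sample_id,band_lo_um,band_hi_um,band_mid_um,count,area_um2,density_per_mm2
    group_summary: pd.DataFrame
    # columns: group,band_lo_um,band_hi_um,band_mid_um,n,mean_density_per_mm2,sem,ci_lo,ci_hi
    band_edges_um: np.ndarray

    def group_points(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(band midpoints, mean densities) for ``group``, NaN bands dropped."""
        sub = self.group_summary[self.group_summary["group"] == group]
        d = sub["band_mid_um"].to_numpy(dtype=float)
        y = sub["mean_density_per_mm2"].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        return d[keep], y[keep]

    def sample_points(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Pooled per-sample (midpoint, density) points for ``group``."""
        sub = self.per_sample[self.per_sample["group"] == group]
        d = sub["band_mid_um"].to_numpy(dtype=float)
        y = sub["density_per_mm2"].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        return d[keep], y[keep]


@dataclass
class HomingDensity:
    """Cell count normalized by a reference section area or tissue volume."""

    sample_id: str
    count: int
    reference: float
    unit: str  # "cells_per_um2" or "cells_per_mm3"

    @property
    def density(self) -> float:
        return self.count / self.reference


def bin_cells(
    cells: Sequence[CellRecord],
    dmap: DistanceMap,
    bands: BandPartition,
    sample_id: str = "",
    group_label: str = "",
) -> BinnedCells:
    """Assign each cell to the band containing the distance-map value at its centroid.

    Cells outside the tumor or deeper than the last band edge go to the
    ``unassigned`` bucket (counted, never silently dropped). A centroid outside
    the image frame is an error.
    """
    h, w = dmap.values_um.shape
    px = dmap.pixel_size_um
    counts = np.zeros(bands.n_bands, dtype=np.int64)
    unassigned = 0
    for cell in cells:
        col = int(round(cell.x_um / px))
        row = int(round(cell.y_um / px))
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(
                f"cell centroid ({cell.x_um:.1f}, {cell.y_um:.1f}) µm is outside the image"
            )
        idx = bands.band_index(dmap.values_um[row, col])
        if idx is None:
            unassigned += 1
        else:
            counts[idx] += 1
    if unassigned:
        logger.info(
            "bin_cells[%s]: %d cell(s) unassigned (outside tumor or beyond max depth)",
            sample_id or "?",
            unassigned,
        )
    return BinnedCells(
        counts=counts,
        unassigned=unassigned,
        bands=bands,
        sample_id=sample_id,
        group_label=group_label,
    )


def build_density_profile(samples: Sequence[BinnedCells]) -> DensityProfile:
    """Aggregate per-sample band densities into group mean ± SEM and 95% CI.

    All samples must share band edges. SEM and CI are across samples with
    n−1 degrees of freedom and are reported absent (NaN) when fewer than two
    samples contribute to a band.
    """
    if not samples:
        raise ValueError("at least one binned sample is required")
    edges = samples[0].bands.edges_um
    for s in samples[1:]:
        if not np.array_equal(s.bands.edges_um, edges):
            raise ValueError("all samples must share identical band edges")

    rows = []
    for s in samples:
        dens = s.densities_per_mm2()
        mids = s.bands.midpoints_um
        for i in range(s.bands.n_bands):
            rows.append(
                {
                    "group": s.group_label,
                    "sample_id": s.sample_id,
                    "band_lo_um": edges[i],
                    "band_hi_um": edges[i + 1],
                    "band_mid_um": mids[i],
                    "count": int(s.counts[i]),
                    "area_um2": float(s.bands.areas_um2[i]),
                    "density_per_mm2": float(dens[i]),
                }
            )
    per_sample = pd.DataFrame(rows)

    summary_rows = []
    for (group, lo), sub in per_sample.groupby(["group", "band_lo_um"], sort=True):
        vals = sub["density_per_mm2"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        if n >= 2:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            tcrit = float(sps.t.ppf(0.975, n - 1))
            ci_lo, ci_hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            sem = ci_lo = ci_hi = np.nan
        summary_rows.append(
            {
                "group": group,
                "band_lo_um": lo,
                "band_hi_um": float(sub["band_hi_um"].iloc[0]),
                "band_mid_um": float(sub["band_mid_um"].iloc[0]),
                "n": n,
                "mean_density_per_mm2": mean,
                "sem": sem,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
            }
        )
    group_summary = pd.DataFrame(summary_rows).sort_values(
        ["group", "band_lo_um"], ignore_index=True
    )
    return DensityProfile(
        per_sample=per_sample, group_summary=group_summary, band_edges_um=edges
    )


def homing_density(
    count: int,
    reference_area_um2: float | None = None,
    volume: VolumeEstimate | float | None = None,
    sample_id: str = "",
) -> HomingDensity:
    """Cells per µm² of section area, or cells per mm³ of tissue volume."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if (reference_area_um2 is None) == (volume is None):
        raise ValueError("provide exactly one of reference_area_um2 or volume")
    if reference_area_um2 is not None:
        if reference_area_um2 <= 0:
            raise ValueError("reference area must be positive")
        return HomingDensity(
            sample_id=sample_id,
            count=int(count),
            reference=float(reference_area_um2),
            unit="cells_per_um2",
        )
    vol_mm3 = volume.volume_mm3 if isinstance(volume, VolumeEstimate) else float(volume)
    if vol_mm3 <= 0:
        raise ValueError("reference volume must be positive")
    return HomingDensity(
        sample_id=sample_id, count=int(count), reference=vol_mm3, unit="cells_per_mm3"
    )
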