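"""Image, ROI and sample-table I/O plus the interchange schemas shared by all stages.

Conventions (fixed across the package):

- array axis order is ``(z, y, x, channel)``;
- coordinates are 0-based, a pixel index refers to the pixel *center*;
- ROI vertices are ``(x, y)`` pairs in pixel units;
- in-plane pixels are isotropic (a single ``pixel_size_um``); anisotropic
  input is rejected, never resampled.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger(__name__)

CHANNEL_ROLES = frozenset({"cell_signal", "collagen_shg", "trichrome_rgb", "other"})
ROI_LABELS = frozenset({"tumor_mask", "capsule", "exclusion"})

#: JSON key under which calibration metadata is embedded in the TIFF description.
_META_KEY = "infiltra_meta"


class CalibrationError(ValueError):
    """Raised when required physical calibration is absent or invalid."""


class RoiValidationError(ValueError):
    """Raised when an ROI polygon violates the schema invariants."""


@dataclass
class ImageStack:
    """Calibrated multi-channel pixel data, 2D section or 3D stack.

    Parameters
    ----------
    pixels
        Non-negative intensity array indexed ``(z, y, x, channel)``.
    pixel_size_um
        In-plane size of one pixel in micrometers (isotropic).
    z_step_um
        Spacing between consecutive slices in micrometers; ``None`` for
        single sections.
    channel_roles
        Mapping channel index -> role, one of :data:`CHANNEL_ROLES`.
    source_id
        Free-text provenance.
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None
    channel_roles: Mapping[int, str] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be (z, y, x, channel); got ndim={self.pixels.ndim}"
            )
        if not np.issubdtype(self.pixels.dtype, np.floating) and not np.issubdtype(
            self.pixels.dtype, np.unsignedinteger
        ):
            raise ValueError(f"unsupported pixel dtype {self.pixels.dtype}")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if not (self.pixel_size_um is not None and self.pixel_size_um > 0):
            raise CalibrationError("pixel_size_um must be a positive number")
        if self.n_slices > 1:
            if self.z_step_um is None or self.z_step_um <= 0:
                raise CalibrationError(
                    "z_step_um must be positive for stacks with more than one slice"
                )
        self.channel_roles = {int(k): str(v) for k, v in dict(self.channel_roles).items()}
        n_ch = self.pixels.shape[3]
        if set(self.channel_roles) != set(range(n_ch)):
            raise ValueError(
                f"channel_roles must cover every channel 0..{n_ch - 1} exactly once"
            )
        for role in self.channel_roles.values():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        for unique_role in ("cell_signal", "collagen_shg"):
            if sum(r == unique_role for r in self.channel_roles.values()) > 1:
                raise ValueError(f"at most one {unique_role} channel is allowed")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel_index(self, role: str) -> int:
        """Return the index of the unique channel with ``role``."""
        matches = [i for i, r in self.channel_roles.items() if r == role]
        if not matches:
            raise KeyError(f"no channel with role {role!r}")
        if len(matches) > 1:
            raise KeyError(f"role {role!r} is not unique")
        return matches[0]

    def channel_indices(self, role: str) -> list[int]:
        return sorted(i for i, r in self.channel_roles.items() if r == role)

    def plane(self, role: str, z: int = 0) -> np.ndarray:
        """Return the 2D ``(y, x)`` plane for ``role`` at slice ``z``."""
        return self.pixels[z, :, :, self.channel_index(role)]

    def z_positions_um(self) -> np.ndarray:
        """Physical z position of each slice (slice 0 at 0 µm)."""
        step = self.z_step_um if self.z_step_um is not None else 0.0
        return np.arange(self.n_slices, dtype=float) * step


@dataclass
class RegionOfInterest:
    """A simple closed polygon in pixel coordinates, ``(x, y)`` vertex order."""

    vertices: np.ndarray
    label: str = "tumor_mask"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise RoiValidationError("vertices must be an (n, 2) array of (x, y)")
        if self.vertices.shape[0] < 3:
            raise RoiValidationError("polygon needs at least 3 vertices")
        if self.label not in ROI_LABELS:
            raise RoiValidationError(f"unknown ROI label {self.label!r}")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise RoiValidationError("polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise RoiValidationError("polygon area must be > 0")

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area_px2(self) -> float:
        return float(self.polygon.area)


@dataclass
class SampleTable:
    """Rows of ``(sample_id, group_label, image_path, roi_path)``."""

    rows: list[dict]

    def __post_init__(self) -> None:
        ids = [r["sample_id"] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_id values must be unique")
        groups = {r["group_label"] for r in self.rows}
        if not groups or any(not g for g in groups):
            raise ValueError("at least one non-empty group label is required")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r["group_label"] not in seen:
                seen.append(r["group_label"])
        return seen


# ---------------------------------------------------------------------------
# TIFF image I/O


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write ``stack`` as a TIFF with calibration embedded in the description tag."""
    meta = {
        # top-level "shape" keeps tifffile's shaped-description reader happy
        "shape": list(stack.pixels.shape),
        _META_KEY: {
            "shape": list(stack.pixels.shape),
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
            "source_id": stack.source_id,
        }
    }
    tifffile.imwrite(Path(path), stack.pixels, description=json.dumps(meta))


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_image_stack(
    path: str | Path,
    calibration: Mapping | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Calibration precedence: explicit ``calibration`` argument, then a sidecar
    ``<path>.json``, then metadata embedded in the file. Overrides are logged.
    Single-plane files yield a one-slice stack.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    embedded: dict = {}
    try:
        parsed = json.loads(desc)
        embedded = parsed.get(_META_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        embedded = {}

    meta = dict(embedded)
    for override in (_read_sidecar(path), dict(calibration or {})):
        for key, val in override.items():
            if key in meta and meta[key] != val:
                logger.warning(
                    "calibration override for %s: %s %r -> %r", path.name, key, meta[key], val
                )
            meta[key] = val

    if "shape" in meta:
        arr = arr.reshape(meta["shape"])
    else:
        # normalize squeezed layouts to (z, y, x, c)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :, np.newaxis]
        elif arr.ndim == 3:
            # ambiguous without metadata; treat leading axis as z
            arr = arr[:, :, :, np.newaxis]

    if "pixel_size_um" not in meta or meta["pixel_size_um"] is None:
        raise CalibrationError(
            f"missing calibration field 'pixel_size_um' for {path} "
            "(supply via sidecar JSON or the calibration argument)"
        )
    roles = meta.get("channel_roles")
    if roles is None:
        roles = {i: "other" for i in range(arr.shape[3])}
    else:
        roles = {int(k): v for k, v in roles.items()}
    return ImageStack(
        pixels=arr,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=None if meta.get("z_step_um") is None else float(meta["z_step_um"]),
        channel_roles=roles,
        source_id=str(meta.get("source_id", path.name)),
    )


# ---------------------------------------------------------------------------
# ROI JSON I/O


def write_roi(roi: RegionOfInterest, path: str | Path) -> None:
    doc = {
        "label": roi.label,
        "vertices": [[float(x), float(y)] for x, y in roi.vertices],
        "source_id": roi.source_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_roi(path: str | Path) -> RegionOfInterest:
    """Read and validate an ROI JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    return RegionOfInterest(
        vertices=np.asarray(doc["vertices"], dtype=float),
        label=doc.get("label", "tumor_mask"),
        source_id=doc.get("source_id", str(path)),
    )


# ---------------------------------------------------------------------------
# Sample table


def read_sample_table(path: str | Path, check_paths: bool = True) -> SampleTable:
    """Read a ``sample_id,group_label,image_path,roi_path`` CSV."""
    path = Path(path)
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "group_label", "image_path", "roi_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"sample table must have columns {sorted(required)}")
        for row in reader:
            rows.append({k: row[k] for k in required})
    table = SampleTable(rows)
    if check_paths:
        base = path.parent
        for row in table.rows:
            for key in ("image_path", "roi_path"):
                p = Path(row[key])
                if not p.is_absolute():
                    p = base / p
                if not p.is_file():
                    raise FileNotFoundError(f"{key} {p} for sample {row['sample_id']}")
                row[key] = str(p)
    return table


# ---------------------------------------------------------------------------
# Projection


def max_intensity_projection(
    stack: ImageStack, z_range_um: Sequence[float] | None = None
) -> ImageStack:
    """Per-channel maximum-intensity projection over a physical z interval.

    ``z_range_um`` is inclusive ``(lo, hi)``; ``None`` projects the whole stack.
    The result is a one-slice stack with ``z_step_um`` dropped.
    """
    positions = stack.z_positions_um()
    if z_range_um is None:
        keep = np.ones(stack.n_slices, dtype=bool)
    else:
        lo, hi = float(z_range_um[0]), float(z_range_um[1])
        keep = (positions >= lo) & (positions <= hi)
    if not keep.any():
        raise ValueError(f"z range {z_range_um} selects no slices")
    projected = stack.pixels[keep].max(axis=0, keepdims=True)
    return replace(stack, pixels=projected, z_step_um=None)
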