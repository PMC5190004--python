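"""End-to-end orchestration of the infiltration-gradient and fibrosis arcs.

A single config drives every stage; all randomness flows from one seed
through named per-sample substreams, and every output bundle embeds a
provenance block (config hash, seed, package/library versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import infiltra
from infiltra import geometry, profiles, regression, synthetic
from infiltra.detection import DetectionParams, detect_cells, records_to_frame
from infiltra.fibrosis import binarize_shg, collagen_density
from infiltra.io_formats import read_image_stack, read_roi, read_sample_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class DataError(RuntimeError):
    """A stage failed on a concrete sample (exit code 3)."""


_TOP_KEYS = {
    "seed",
    "output_dir",
    "band_width_um",
    "max_depth_um",
    "capsule_depth_um",
    "detection",
    "fit",
    "fibrosis",
    "synthetic",
    "samples",
    "log_level",
}
_DETECTION_KEYS = {
    "threshold",
    "min_area_um2",
    "max_area_um2",
    "min_volume_um3",
    "max_volume_um3",
    "connectivity",
}
_FIT_KEYS = {"mode", "weighting"}
_FIBROSIS_KEYS = {"shg_threshold", "perimeter_error_px", "hue_range", "saturation_min"}
_SYNTH_KEYS = {
    "groups",
    "image_shape_px",
    "pixel_size_um",
    "tumor_radius_um",
    "capsule_width_um",
    "cell_radius_um",
    "cell_radius_jitter_um",
    "cell_peak_intensity",
    "background_mean",
    "background_sd",
    "collagen_capsule_fraction",
    "collagen_interior_fraction",
}
_GROUP_KEYS = {"label", "n_sections", "law", "collagen_capsule_fraction"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration. Unknown keys are rejected."""

    raw: dict
    seed: int = 0
    output_dir: Path = Path("infiltra_out")
    band_width_um: float = 50.0
    max_depth_um: float = 400.0
    capsule_depth_um: float = 250.0
    detection: dict = field(default_factory=dict)
    fit: dict = field(default_factory=lambda: {"mode": "group_means", "weighting": "none"})
    fibrosis: dict = field(default_factory=dict)
    synthetic: dict | None = None
    samples: str | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in (
            ("detection", _DETECTION_KEYS),
            ("fit", _FIT_KEYS),
            ("fibrosis", _FIBROSIS_KEYS),
            ("synthetic", _SYNTH_KEYS),
        ):
            sub = doc.get(section)
            if sub is not None:
                bad = set(sub) - allowed
                if bad:
                    raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
        synth = doc.get("synthetic")
        if synth is not None:
            for grp in synth.get("groups", []):
                bad = set(grp) - _GROUP_KEYS
                if bad:
                    raise ConfigError(f"unknown keys in synthetic group: {sorted(bad)}")
        if synth is None and doc.get("samples") is None:
            raise ConfigError("config needs either 'synthetic' or 'samples'")
        fit = {"mode": "group_means", "weighting": "none"}
        fit.update(doc.get("fit") or {})
        if fit["mode"] not in ("group_means", "per_sample"):
            raise ConfigError(f"unknown fit mode {fit['mode']!r}")
        cfg = cls(
            raw=doc,
            seed=int(doc.get("seed", 0)),
            output_dir=Path(doc.get("output_dir", "infiltra_out")),
            band_width_um=float(doc.get("band_width_um", 50.0)),
            max_depth_um=float(doc.get("max_depth_um", 400.0)),
            capsule_depth_um=float(doc.get("capsule_depth_um", 250.0)),
            detection=dict(doc.get("detection") or {}),
            fit=fit,
            fibrosis=dict(doc.get("fibrosis") or {}),
            synthetic=synth,
            samples=doc.get("samples"),
        )
        return cfg

    def detection_params(self) -> DetectionParams:
        if "threshold" not in self.detection:
            raise ConfigError("detection.threshold is required (no default exists)")
        return DetectionParams(**self.detection)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        import scipy
        import skimage

        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "config": self.raw,
            "versions": {
                "infiltra": infiltra.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-image": skimage.__version__,
                "pandas": pd.__version__,
            },
        }


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return PipelineConfig.from_dict(doc)


def default_synthetic_config(seed: int = 0, output_dir: str = "infiltra_out") -> dict:
    """Shipped default: two 8-section cohorts, decaying vs flat infiltration."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "band_width_um": 50.0,
        "max_depth_um": 400.0,
        "capsule_depth_um": 250.0,
        "detection": {"threshold": 60.0, "max_area_um2": 200.0, "connectivity": 8},
        "fit": {"mode": "group_means", "weighting": "none"},
        "fibrosis": {"shg_threshold": 128.0, "perimeter_error_px": 2},
        "synthetic": {
            "image_shape_px": [512, 512],
            "pixel_size_um": 2.0,
            "tumor_radius_um": 450.0,
            "capsule_width_um": 250.0,
            "cell_radius_um": 3.0,
            "cell_peak_intensity": 200.0,
            "background_mean": 10.0,
            "background_sd": 3.0,
            "collagen_capsule_fraction": 0.6,
            "collagen_interior_fraction": 0.1,
            "groups": [
                {
                    "label": "capsuled",
                    "n_sections": 8,
                    "law": {
                        "kind": "exponential",
                        "amplitude_per_mm2": 2000.0,
                        "decay_per_um": 0.01,
                    },
                },
                {
                    "label": "open",
                    "n_sections": 8,
                    "law": {"kind": "flat", "density_per_mm2": 600.0},
                },
            ],
        },
    }


def _synthetic_spec_for(
    cfg: PipelineConfig, group: dict, section_idx: int, substream_seed: int
) -> synthetic.SyntheticSpec:
    synth = cfg.synthetic or {}
    kwargs: dict[str, Any] = {
        k: synth[k]
        for k in _SYNTH_KEYS - {"groups", "image_shape_px"}
        if k in synth
    }
    if "collagen_capsule_fraction" in group:
        kwargs["collagen_capsule_fraction"] = group["collagen_capsule_fraction"]
    if "image_shape_px" in synth:
        kwargs["image_shape_px"] = tuple(synth["image_shape_px"])
    return synthetic.SyntheticSpec(
        law=synthetic.law_from_dict(group["law"]), seed=substream_seed, **kwargs
    )


def _substream_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


@dataclass
class SampleInput:
    """One resolved sample: image + tumor ROI (+ ground truth when synthetic)."""

    sample_id: str
    group_label: str
    stack: Any
    roi: Any
    truth: synthetic.GroundTruth | None = None


def _resolve_samples(cfg: PipelineConfig) -> list[SampleInput]:
    samples: list[SampleInput] = []
    if cfg.synthetic is not None:
        groups = cfg.synthetic.get("groups", [])
        if not groups:
            raise ConfigError("synthetic config needs at least one group")
        total = sum(int(g["n_sections"]) for g in groups)
        seeds = _substream_seeds(cfg.seed, total)
        i = 0
        for grp in groups:
            for k in range(int(grp["n_sections"])):
                spec = _synthetic_spec_for(cfg, grp, k, seeds[i])
                stack, truth, roi = synthetic.generate_section(spec)
                samples.append(
                    SampleInput(
                        sample_id=f"{grp['label']}-{k:02d}",
                        group_label=grp["label"],
                        stack=stack,
                        roi=roi,
                        truth=truth,
                    )
                )
                i += 1
    else:
        table = read_sample_table(cfg.samples)
        for row in table.rows:
            samples.append(
                SampleInput(
                    sample_id=row["sample_id"],
                    group_label=row["group_label"],
                    stack=read_image_stack(row["image_path"]),
                    roi=read_roi(row["roi_path"]),
                )
            )
    return samples


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_infiltration(cfg: PipelineConfig) -> dict:
    """Detect, bin, profile, fit and compare; write the full report bundle."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.detection_params()
    samples = _resolve_samples(cfg)

    binned = []
    all_records = []
    for sample in samples:
        try:
            records = detect_cells(
                sample.stack, params, sample_id=sample.sample_id
            )
            mask, _border = geometry.extract_tumor_border(
                sample.roi, image_shape=sample.stack.pixels.shape[1:3]
            )
            dmap = geometry.compute_distance_map(mask, sample.stack.pixel_size_um)
            bands = geometry.partition_bands(
                dmap, cfg.band_width_um, cfg.max_depth_um
            )
            binned.append(
                profiles.bin_cells(
                    records,
                    dmap,
                    bands,
                    sample_id=sample.sample_id,
                    group_label=sample.group_label,
                )
            )
            all_records.extend(records)
        except (ValueError, RuntimeError) as exc:
            raise DataError(
                f"infiltration stage failed for sample {sample.sample_id}: {exc}"
            ) from exc

    profile = profiles.build_density_profile(binned)
    _write_csv(records_to_frame(all_records), out / "cells.csv")
    _write_csv(profile.per_sample, out / "profile_per_sample.csv")
    _write_csv(profile.group_summary, out / "profile_group_summary.csv")

    groups = list(dict.fromkeys(s.group_label for s in samples))
    fits: dict[str, dict] = {}
    for group in groups:
        if cfg.fit["mode"] == "group_means":
            d, y = profile.group_points(group)
        else:
            d, y = profile.sample_points(group)
        entry: dict[str, Any] = {"mode": cfg.fit["mode"]}
        try:
            entry["exponential"] = regression.fit_exponential_decay(d, y).to_dict()
        except regression.FitError as exc:
            entry["exponential"] = {"error": str(exc)}
        try:
            entry["linear"] = regression.fit_linear(d, y).to_dict()
        except regression.FitError as exc:
            entry["linear"] = {"error": str(exc)}
        fits[group] = entry

    comparison: dict[str, Any]
    if len(groups) == 2:
        pts = {}
        try:
            for group in groups:
                if cfg.fit["mode"] == "group_means":
                    d, y = profile.group_points(group)
                else:
                    d, y = profile.sample_points(group)
                dd, yy, _ = regression.log_transform_profile(
                    d, y, profile.band_edges_um, cfg.capsule_depth_um
                )
                pts[group] = (dd, yy)
            comp = regression.compare_slopes(
                *pts[groups[0]],
                *pts[groups[1]],
                fit_range_um=(0.0, cfg.capsule_depth_um),
            )
            comparison = comp.to_dict()
            comparison["groups"] = groups
        except regression.FitError as exc:
            comparison = {"error": str(exc), "groups": groups}
    else:
        comparison = {"error": "insufficient groups for slope comparison", "groups": groups}

    report = {
        "provenance": cfg.provenance(),
        "n_samples": len(samples),
        "groups": groups,
        "fits": fits,
        "slope_comparison": comparison,
        "unassigned_cells": {b.sample_id: b.unassigned for b in binned},
    }
    with open(out / "infiltration_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)

    _plot_profile(profile, groups, out / "profile.png")
    return report


def _plot_profile(profile: profiles.DensityProfile, groups, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 4))
    for group in groups:
        sub = profile.group_summary[profile.group_summary["group"] == group]
        d = sub["band_mid_um"]
        y = sub["mean_density_per_mm2"]
        ax0.errorbar(d, y, yerr=sub["sem"], marker="o", capsize=3, label=group)
        pos = y > 0
        ax1.plot(d[pos], np.log(y[pos]), marker="o", label=group)
    ax0.set_xlabel("distance from outer tumor border (µm)")
    ax0.set_ylabel("cell density (cells/mm²)")
    ax1.set_xlabel("distance from outer tumor border (µm)")
    ax1.set_ylabel("ln density")
    ax0.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_fibrosis(cfg: PipelineConfig) -> dict:
    """SHG-based collagen density per sample (capsule ROI), with group summary."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if "shg_threshold" not in cfg.fibrosis:
        raise ConfigError("fibrosis.shg_threshold is required (no default exists)")
    tau = float(cfg.fibrosis["shg_threshold"])
    err_px = int(cfg.fibrosis.get("perimeter_error_px", 2))

    samples = _resolve_samples(cfg)
    rows = []
    for sample in samples:
        try:
            binary = binarize_shg(sample.stack, tau)
            # restrict to the capsule annulus of the tumor ROI
            mask, _ = geometry.extract_tumor_border(
                sample.roi, image_shape=sample.stack.pixels.shape[1:3]
            )
            dmap = geometry.compute_distance_map(mask, sample.stack.pixel_size_um)
            capsule = mask & (dmap.values_um < cfg.capsule_depth_um)
            meas = collagen_density(
                binary,
                sample.roi,
                perimeter_error_px=err_px,
                threshold=tau,
                sample_id=sample.sample_id,
            )
            # capsule-restricted point estimate (the ROI here is the whole tumor)
            n_cap = int(capsule.sum())
            frac_cap = float(binary[capsule].sum() / n_cap) if n_cap else np.nan
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group_label,
                    "region": "capsule",
                    "threshold": tau,
                    "fraction": frac_cap,
                    "percent": 100.0 * frac_cap,
                    "bound_lo": meas.bound_lo,
                    "bound_hi": meas.bound_hi,
                    "pixels_total": n_cap,
                    "pixels_positive": int(binary[capsule].sum()),
                }
            )
        except (ValueError, RuntimeError) as exc:
            raise DataError(
                f"fibrosis stage failed for sample {sample.sample_id}: {exc}"
            ) from exc

    table = pd.DataFrame(rows)
    _write_csv(table, out / "collagen_per_sample.csv")
    summary = (
        table.groupby("group")["fraction"]
        .agg(["count", "mean", "std", "min", "max"])
        .reset_index()
    )
    _write_csv(summary, out / "collagen_group_summary.csv")
    report = {
        "provenance": cfg.provenance(),
        "n_samples": len(samples),
        "summary": summary.to_dict(orient="records"),
    }
    with open(out / "fibrosis_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def run_volume(
    cfg: PipelineConfig,
    n_slices: int = 20,
    node_shape: str = "hemisphere",
    node_radius_um: float = 200.0,
    z_step_um: float = 4.0,
    n_cells: int = 30,
    tissue_threshold: float = 40.0,
) -> dict:
    """Cavalieri volume + homing density (cells/mm³) on a synthetic node stack."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticSpec(
        image_shape_px=(256, 256),
        pixel_size_um=2.0,
        n_slices=n_slices,
        z_step_um=z_step_um,
        node_shape=node_shape,  # type: ignore[arg-type]
        node_radius_um=node_radius_um,
        n_node_cells=n_cells,
        background_mean=5.0,
        background_sd=1.0,
        seed=cfg.seed,
    )
    stack, truth = synthetic.generate_node_stack(spec)
    ch = stack.channel_index("cell_signal")
    areas = [
        float((stack.pixels[z, :, :, ch] >= tissue_threshold).sum())
        * stack.pixel_size_um**2
        for z in range(stack.n_slices)
    ]
    vol = geometry.cavalieri_volume(areas, stack.z_step_um or z_step_um)
    dens = profiles.homing_density(
        len(truth.true_cells), volume=vol, sample_id="node-stack"
    )
    report = {
        "provenance": cfg.provenance(),
        "volume_um3": vol.volume_um3,
        "volume_mm3": vol.volume_mm3,
        "analytic_volume_um3": truth.analytic_volume_um3,
        "n_cells": dens.count,
        "density_cells_per_mm3": dens.density,
    }
    with open(out / "volume_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
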