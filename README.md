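# infiltra

Spatial analysis of labeled-cell infiltration into tumors and of peritumoral
fibrosis in calibrated microscopy sections, with a fully synthetic
ground-truth data generator for end-to-end validation.

The pipeline covers two analysis arcs:

1. **Infiltration gradient** — detect labeled cells in 2D sections
   (intensity threshold + connected components with a 200 µm² upper size
   filter), compute each cell's inward Euclidean distance from the outer
   tumor border, bin cells into uniform concentric distance bands, build
   per-sample and group-level density profiles (cells/mm², mean ± SEM,
   95% CI), fit exponential-decay and linear models, and compare
   log-linear slopes between two groups over the capsule range
   (default 0–250 µm) via a pooled interaction regression.
2. **Fibrosis** — binarize the collagen (SHG) channel at a fixed threshold,
   measure the collagen-positive pixel fraction over hand-drawn ROIs with
   ±2 px perimeter-error bounds, classify trichrome-stained collagen by a
   hue/saturation rule, and estimate tissue volumes from serial sections by
   the sum-of-areas × z-step rule. An iterative Grubbs screen flags outliers
   in scalar readouts.

Because no imaging data is publicly deposited for the motivating study, the
`synthetic` module generates calibrated sections and z-stacks with known
ground truth: a convex tumor with a fibrotic capsule annulus, cells placed
by an inhomogeneous Poisson process whose radial density follows an
exponential-decay or flat law, truncated-Gaussian background, and
ellipsoidal node stacks with analytic volumes.

## CLI

```bash
infiltra synth --seed 1 --out config.yaml      # write the default two-group synthetic config
infiltra run-infiltration config.yaml          # full gradient arc -> CSVs + JSON + PNG
infiltra run-fibrosis config.yaml              # capsule collagen fractions per sample
infiltra volume config.yaml                    # Cavalieri volume + cells/mm³ on a node stack
infiltra detect config.yaml image.tif          # single-image detection
infiltra profile config.yaml image.tif roi.json  # detection + banded densities for one section
infiltra fit out/profile_group_summary.csv --group capsuled
infiltra compare out/profile_group_summary.csv --range-um 250
infiltra fibrosis config.yaml image.tif roi.json
infiltra grubbs 1 1 1 1 1 1 1 100
```

Exit codes: `0` success, `2` config error, `3` data error. Every output
bundle embeds a provenance block (config hash, seed, library versions).

### Inputs

- **Images**: TIFF/OME-TIFF, axis order `(z, y, x, channel)`, 8/16-bit
  unsigned or 32-bit float. Physical calibration (`pixel_size_um`, and
  `z_step_um` for stacks) is required — via embedded metadata, a sidecar
  `<image>.json`, or an explicit override (logged). In-plane pixels must be
  isotropic.
- **ROIs**: JSON `{"label": ..., "vertices": [[x, y], ...], "source_id": ...}`,
  simple polygons in pixel coordinates, labels `tumor_mask` / `capsule` /
  `exclusion`.
- **Sample tables**: CSV with header `sample_id,group_label,image_path,roi_path`.

## Package layout

| module | responsibility |
| --- | --- |
| `infiltra.io_formats` | calibrated `ImageStack`, ROI polygons, sample tables, MIP |
| `infiltra.synthetic` | ground-truth sections, node stacks, pre-binned count simulator |
| `infiltra.detection` | background-derived thresholds, 2D cell detection, 3D spot counts |
| `infiltra.geometry` | border extraction, exact distance maps, concentric bands, Cavalieri volumes |
| `infiltra.profiles` | cell binning, density profiles, homing densities |
| `infiltra.regression` | exponential/linear fits, log-slope comparison, Grubbs screen |
| `infiltra.fibrosis` | SHG binarization, ROI collagen density ± perimeter bounds, trichrome fraction |
| `infiltra.pipeline` / `infiltra.cli` | config validation, orchestration, provenance, CLI |

## Conventions

- 0-based pixel coordinates; a pixel index refers to the pixel center;
  `(x, y)` order in ROI files, `(z, y, x, channel)` in arrays.
- Distance bands are half-open `[lo, hi)`: a cell at exactly 250 µm falls
  outside the 0–250 µm capsule set.
- Densities are canonically cells/mm²; conversions to cells/µm² and
  cells/mm³ are exact and labeled.
- Group statistics aggregate across samples (animals/sections), never
  across pixels; SEM requires n ≥ 2 and is otherwise reported absent.
- Zero-density bands are excluded from the ln transform (no pseudo-count),
  with a logged count.
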