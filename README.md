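# dosemass

Dose–volume / dose–mass histogram analysis of paired deep-inspiration
breath-hold (DIBH) vs free-breathing (FB) radiotherapy datasets, with
deformable-registration-based lung-expansion metrics and a synthetic thorax
phantom generator for end-to-end validation.

## What it does

- **I/O** (`dosemass.io_formats`): voxel volumes (MetaImage `.mha`, DICOM CT
  series), dose grids (MetaImage, DICOM RT Dose with grid scaling), structure
  sets (JSON contours, DICOM RT Structure Set), HU→mass-density tables (CSV),
  and contour→mask rasterization (voxel-center, even-odd rule). The DICOM
  adapter is self-contained (Explicit VR Little Endian, axis-aligned).
- **Dosimetry** (`dosemass.dosimetry`): cumulative DVH/DMH computation and
  scalar metrics — volume- and mass-weighted Dmean, Vx/Mx as relative (%) and
  absolute (cm³/g) values, computed by exact voxel recount with the “≥ dose”
  convention. Trilinear dose-grid resampling onto the CT grid.
- **Registration & expansion** (`dosemass.registration`): the three-step
  workflow — lung/non-lung tissue split, multi-stage free-form cubic B-spline
  registration minimizing mean squared error (with a global affine
  pre-stage), and displacement-field merging with a boundary cross-fade.
  Derived metrics: mean left/anterior/caudal expansion, 3-D expansion, and
  the breathing-pattern index ((caudal − anterior)/anterior × 100%).
- **Synthetic phantoms** (`dosemass.phantom`): paired FB/DIBH thorax phantoms
  with known analytic ground-truth deformation, mass-conserving lung density
  change (volume ×1.8, density ×1/1.8 by default), a heart that leaves the
  tangential field in DIBH, chest-wall-anchored two-tangent dose fields
  normalized to a 50 Gy median PTV dose, and configurable “adverse anatomy”
  cases whose irradiated lung mass increases in DIBH.
- **Cohort statistics** (`dosemass.stats`): paired deltas (DIBH − FB, plus
  relative %), Wilcoxon signed-rank test (exact for n ≤ 25), OLS regression
  of ΔDMH on ΔDVH with the zero-crossing threshold, Spearman correlation
  tables with significance stars, and Table-style cohort summaries.
- **Pipeline & CLI** (`dosemass.pipeline`, `dosemass` command): one config
  drives phantom/cohort generation or file loading, per-patient analysis,
  aggregation and CSV/JSON reporting.

## CLI

```bash
# generate a synthetic cohort in research formats (.mha + JSON + CSV)
dosemass phantom --n 5 --seed 1 --out data/

# analyze one exported pair (add --no-registration to skip expansion analysis)
dosemass analyze-patient --data data/synthetic_000 --out patient.json

# full cohort analysis (synthetic mode by default; see RunConfig for files mode)
dosemass analyze-cohort --n 31 --seed 1 --no-registration --out results_dir

# re-print a previous run's summary table
dosemass report --results results_dir
```

Exit codes: 0 success, 1 partial per-patient failure, 2 fatal.

## Conventions

Axis-aligned LPS patient frame (+x left, +y posterior, +z superior);
“anterior” = −y, “caudal” = −z. Arrays are indexed `[ix, iy, iz]`.
Deformation fields map FB positions to DIBH positions; mask warping is the
pull-back (carries DIBH-frame masks onto the FB grid). Deltas are always
DIBH − FB; relative deltas are % of the FB value.
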