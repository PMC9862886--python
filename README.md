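# fhnquant

3D quantification of femoral head necrosis (FHN) from segmentation label
maps, with a synthetic-phantom validation harness and the accompanying
statistical comparison framework.

Given a 3D label volume (0 = background, 1 = unaffected femoral bone,
2 = necrotic bone) the package computes six parameters per hip:

1. volume of necrosis (cm³)
2. volume of unaffected bone (cm³)
3. percent of necrotic bone volume (%)
4. surface of necrotic bone (cm²)
5. femoral head surface (cm²)
6. percent of necrotic femoral head surface (%)

plus the **modified Kerboul angle** (sum of the necrotic arc angles in the
midcoronal and midsagittal planes, measured at the fitted head center).

Surface measurement follows a neck-cut-plane procedure: the label map is
converted to a triangulated contour, a plane is fitted to the flat region
where the segmentation ends in the femoral neck (seeded consensus / RANSAC
style fit), and everything within 3 mm of that plane is removed before
areas are measured.

Because no patient data are available, validation uses voxelized hip
phantoms — a spherical head with a flat neck cut and a spherical-sector
lesion — for which every quantity has a closed form:

| quantity | closed form |
|---|---|
| necrotic volume | (2/3)·π·R³·(1 − cos θ) |
| necrotic cap surface | 2·π·R²·(1 − cos θ) |
| trimmed head surface | 2·π·R·(R + d − margin) |
| modified Kerboul angle | 4·θ |

A perturbation model emulates manual-vs-automatic segmentation
disagreement at calibrated Dice levels (defaults 0.75 necrotic / 0.91
unaffected), and a cohort generator produces early/advanced ARCO groups
for Mann–Whitney comparisons.

## Layout

| module | role |
|---|---|
| `fhnquant.mask_io` | NIfTI label-volume I/O, validation, metadata, manifests |
| `fhnquant.phantom_sim` | phantoms with analytic truth, Dice-calibrated perturbation, cohorts |
| `fhnquant.quant3d` | volumetry, surface mesh, neck-cut plane fit, 3 mm trim, six parameters |
| `fhnquant.kerboul` | head sphere fit and modified Kerboul angle |
| `fhnquant.stats_report` | Dice, paired t/CI/Pearson, Mann–Whitney, report tables |
| `fhnquant.pipeline` + `fhnquant.cli` | TOML-configured simulate → quantify → report pipeline and CLI |

## CLI

```bash
# generate a synthetic cohort (NIfTI volumes + truth JSON + manifest CSV)
fhnquant simulate --out sim/ --n-early 6 --n-advanced 24 --seed 1

# six-parameter quantification (CSV + provenance JSON, optional PLY meshes)
fhnquant quantify sim/case-001_manual3d.nii --out metrics.csv --margin-mm 3

# modified Kerboul angles
fhnquant kerboul sim/case-001_manual3d.nii --out kerboul.json

# paired comparison of two metrics CSVs (aligned by case_id)
fhnquant compare --metrics-a a.csv --metrics-b b.csv --out paired.csv

# early-vs-advanced group stats + Kerboul correlations
fhnquant cohort-stats --metrics run/metrics.csv --out stats/

# full pipeline from a TOML config
fhnquant run --config run.toml
```

Example `run.toml`:

```toml
workdir = "run1"
trim_margin_mm = 3.0

[cohort]
n_early = 6
n_advanced = 24
grid_3d = "iso3d"    # 0.8 mm isotropic
grid_2d = "aniso2d"  # 160 x 30 x 160 at 0.44 x 2.4 x 0.44 mm

[noise]
target_dice_necrotic = 0.75
target_dice_unaffected = 0.91

[seeds]
cohort = 1
noise = 2
plane = 20230112
```

The pipeline writes per-case NIfTI volumes, a tidy `metrics.csv`, report
tables (summary, paired comparisons, group comparison, Kerboul
correlations), a checksummed artifact manifest and a run log. Re-running
the same config is byte-identical; deleting a downstream artifact
regenerates it without re-simulating upstream ones.

## Conventions

* World coordinates in mm, voxel-center convention, axes L→R / P→A / I→S
  (superior = +axis2); NIfTI inputs are reoriented to this convention.
* Labels are strictly {0, 1, 2}; other codings are rejected, not remapped.
* Volumes are processed at native spacing — no resampling.
* All statistical tests are two-sided at α = 0.05; IQR uses
  linear-interpolation quantiles; Dice of two empty masks is 1; no
  multiple-testing correction is applied.
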