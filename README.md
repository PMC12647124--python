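# mucomap

Quantitative 3-D analysis of airway mucus plugging in micro-CT-style
volumes: airway lumen and mucus segmentation, three cross-section
extraction methods, mucus area/contact ratio metrics, ordinal mucus
scoring over an 11-generation murine airway nomenclature, and the
accompanying nonparametric statistics — all exercisable on synthetic
airway-tree phantoms with exact voxel-counted ground truth.

## Modules

| module | purpose |
| --- | --- |
| `mucomap.phantom` | synthetic branching airway trees, programmable plug/crescent/annulus mucus deposits, exact per-station ground-truth ratios, synthetic ratio cohorts and ordinal score tables |
| `mucomap.volume_io` | TIFF-stack and NRRD volume I/O (axis order z,y,x; explicit isotropic voxel size in µm), score-CSV validation, green→red RGB ratio maps |
| `mucomap.segmentation` | marked-watershed airway segmentation with skeleton-based branch labelling; band-binarisation + morphology mucus segmentation; unconnected-component exclusion |
| `mucomap.cross_section` | slice (z-planes), skeleton (planes orthogonal to a 3-D thinning centerline) and geodesic (chamfer distance level-set bins) cross-sections |
| `mucomap.metrics` | mucus area ratio, mucus contact ratio, per-branch profiles, per-sample summaries and the area/contact correlation |
| `mucomap.scoring` | nomenclature catalog (5 lobes × generations 1–11), 0/1/2 auto-scoring from area ratios, per-animal mean-score aggregation |
| `mucomap.stats` | Mann-Whitney U (exact enumeration / tie-corrected normal approximation), Bonferroni-Dunn adjustment, Kruskal-Wallis, Dunn's post-hoc, Pearson, simple linear regression |
| `mucomap.pipeline` / `mucomap.cli` | end-to-end orchestration with YAML config, manifest-first execution and deterministic seeded runs |

## CLI

```bash
# build a phantom bundle (intensity TIFF, label/mucus NRRD, ground-truth CSV)
mucomap phantom --spec tree.yaml --shape 128,128,128 --voxel-um 1.0 \
    --noise-sd 0.05 --seed 1 --out bundle/

# segment an existing volume
mucomap segment --volume bundle/intensity.tif --voxel-um 1.0 \
    --seed 12,64,64 --bg-seed 2,2,2 --out seg/

# cross-sections and ratios
mucomap crosssec --labels seg/labels.nrrd --mucus seg/mucus.nrrd \
    --method all --out records.csv
mucomap metrics summarize --records records.csv --sample-id s0 --out summary.csv

# ordinal scoring
mucomap score aggregate --scores scores.csv --by generation --out agg.csv
mucomap score study --scores scores.csv --out study/

# full pipeline from a YAML config (see mucomap.pipeline.PipelineConfig)
mucomap run-all --config config.yaml --seed 1
```

A tree spec is a YAML file with a `branches` list (`branch_id`, `parent_id`,
`origin` [z,y,x voxels], `direction`, `length` and `radius` in µm,
`generation` 1–11, `lobe` in {RUL, RML, RLL, RCL, LL}) and an optional
`deposits` list (`kind`: plug | crescent | annulus, `axial_span`,
`fill_fraction` or `thickness`, `angular_coverage`).

## Conventions

- Axis order is (z, y, x) everywhere; 0-based voxel coordinates.
- Voxel size is explicit and isotropic (µm); there is no silent default.
- Ratios are fractions in [0, 1] internally and percentages in summaries.
- Foreground connectivity is 26; wall perimeter uses the 6-boundary.
- Every stochastic operation takes an explicit seed and is bit-reproducible.
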