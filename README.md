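# retinotract

A tested, reusable pipeline for studying a retinotopically organised
white-matter tract on synthetic diffusion-MRI phantoms: curvature-ensemble
tractography on a tensor field, non-negative least-squares streamline
pruning, endpoint-based subdivision of the tract against a gradient-bearing
cortical ROI, along-tract FA/MD/RD profiles, fiber density and consistency
maps, and hits / false-alarms d′ quantification.

Everything runs end to end on a generated phantom, so no neuroimaging data
download is required.

## Layout

| Module | Role |
| --- | --- |
| `retinotract.phantom` | Synthetic study generator: grid + affine, seed/target ROIs, anterior–posterior gradient map, two ground-truth-labelled bundles (dorsal/ventral), tensor field, noisy multi-shell DWI |
| `retinotract.formats_io` | NIfTI-1, TCK, TRK and FSL bval/bvec I/O with round-trip guarantees |
| `retinotract.tensor_model` | Log-linear diffusion-tensor fit; FA / MD / RD scalar maps |
| `retinotract.tracking_life` | Deterministic curvature-constrained tracker, ensemble merging, stick-model NNLS pruning |
| `retinotract.streamline_ops` | Resampling, length, 2 mm ROI intersection, exclusion-plane filtering, mask dilation |
| `retinotract.subdivision_stats` | 50/50 major-axis ROI split, endpoint classification (PRO1/PRO2), d′, medial→lateral endpoint histogram |
| `retinotract.maps_profiles` | Normalized density maps, FWHM-smoothed consistency maps, 100-node tract profiles |
| `retinotract.pipeline` | One-config orchestration with JSON report; manual-vs-automatic comparison |

## CLI

```bash
retinotract phantom --seed 42 --out phantom_dir        # generate a phantom
retinotract run --out run_dir                          # full default pipeline
retinotract run --config cfg.json                      # custom RunConfig (JSON)
retinotract stats --hits 0.901 --false-alarms 0.269    # d' from rates
retinotract track / prune / filter / classify / profile / maps  # single stages
```

Exit codes: 0 success, 2 usage, 3 data/format, 4 model.

The full run writes every intermediate in its standard format (NIfTI, TCK,
CSV, JSON) plus `report.json` with counts, proportions, detection statistics,
tract-length summaries and artifact checksums. Runs are deterministic under
fixed seeds: identical configs produce byte-identical classification tables.

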