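# octava

Fully automatic analysis of en-face macular OCTA angiograms:

* **FAZ segmentation** — localizes and measures the foveal avascular zone
  on 3×3 mm superficial-plexus scans (smoothing → Otsu vessel map →
  morphological sealing → avascular-candidate extraction → false-positive
  filtering by area/centrality/compactness → refinement and area in mm²).
* **Vessel density** — Otsu binarization, two-subiteration parallel
  thinning to a one-pixel skeleton, and skeleton-pixel density per zone of
  an ETDRS grid (1 mm foveal disk + 3 mm parafoveal ring split into upper,
  nasal, temporal, lower quadrants; nasal/temporal swap with laterality).
* **VA estimation** — epsilon-SVR (standardized features, linear kernel by
  default) regressing decimal visual acuity from the FAZ area plus the 10
  (SCP-only) or 20 (SCP+DCP) zonal densities, evaluated with seeded 5-fold
  cross-validation (Pearson r, p-value, MSE on the decimal scale, per-fold
  and train-refit MSE, optional subgroup MSE).
* **Synthetic fixtures** — seeded vessel-lattice image generator with
  exact geometric ground truth, and a cohort generator with a known linear
  feature→VA law, so the whole pipeline is testable without any data
  download.

## CLI

```sh
octava simulate --out sim/ --n-visits 20 --seed 1   # synthetic image cohort
octava faz sim/V0000_scp3.png --meta sim/V0000_scp3.png.json
octava density sim/V0000_dcp6.png --meta sim/V0000_dcp6.png.json --center auto
octava analyze  --cohort sim/cohort.csv --out results/   # per-visit biomarkers
octava estimate --cohort results/biomarkers.csv --out results/ --experiment scp_dcp
octava run      --cohort sim/cohort.csv --out results/ --experiment scp_dcp --seed 1
```

`run` performs everything: per-visit biomarker extraction (failed visits
are excluded with a logged reason; the run aborts if more than half fail),
then cross-validated VA estimation.  Outputs: `biomarkers.csv`,
`predictions.csv` (visit, real VA, estimated VA, fold) and `metrics.json`
— byte-identical across reruns with the same config and seed.

### Cohort CSV format

Columns: `visit_id, va_decimal, laterality, path_scp3, path_scp6,
path_dcp3, path_dcp6` (paths relative to the CSV). Extra columns such as
`treated` or `lens_status` are carried through and used for subgroup MSE.
Each image may have a `<name>.json` sidecar with
`{extent_mm, plexus, laterality, visit_id}`.

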