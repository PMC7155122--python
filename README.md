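# granule-sizer

High-throughput morphometry of endothelial secretory granules
(Weibel-Palade bodies, WPBs) from two-channel fluorescence plates, with
a fully synthetic test bench.

## The problem

Endothelial cells store von Willebrand factor (vWF) in rod-shaped
granules whose lengths are quantized in 0.5 µm steps — from 0.5 µm to
more than 5 µm — because vWF is co-packaged as half-micron quanta.
Agonists can release these granules *size-selectively*: preferential
exocytosis of the longest, most pro-haemostatic organelles. Detecting
that selectivity from imaging means segmenting tens of thousands of
near-diffraction-limited rods per condition, measuring each one, and
asking whether the **long-area fraction**

```
phi = ( Σ area_i · 1[length_i > 2 µm] ) / ( Σ area_i )
```

of the granules *remaining* in the cells falls after stimulation.
Random (length-independent) release leaves φ unchanged; preferential
release of long WPBs lowers it, of short WPBs raises it.

`granule-sizer` implements that workflow end to end for image analysts
and quantitative cell biologists:

- **synthgen** — a forward model of the microscope (40×/NA 0.6, Gaussian
  PSF, Poisson + read noise, 16-bit quantization) that renders fields of
  nuclei and rod-shaped granules with exact ground truth, plus a
  logistic length-dependent release model
  `p(L) = p_base + p_max / (1 + exp(-(L - L₀)/s))` that nests both
  random and size-selective release.
- **wpb_segmentation** — local adaptive thresholding of the pro-vWF
  channel, sub-resolution object removal at the Rayleigh limit
  (0.61 λ/NA), threshold-free rod-length measurement from
  intensity-moment anisotropy, and nucleus counting by
  distance-transform watershed.
- **exosite_segmentation** — extracellular vWF exocytic-site
  segmentation: Gaussian denoise, moment-preserving (Tsai) global
  threshold, marker-based watershed splitting of touching sites, and
  the proportion of sites > 2 µm² normalized to controls.
- **size_stats** — well-level aggregation (wells, not fields, are the
  unit of inference), one-way ANOVA with Monte-Carlo Dunnett
  comparisons against a control, two-way ANOVA with Šidák-adjusted
  contrasts, percent-released and fold-inhibition arithmetic, and the
  size-selection verdict.
- **validation** — object-level scoring (precision/recall/F1, length
  bias and RMSE) of any segmentation against reference annotations by
  greedy nearest-centroid matching.

## Worked example

```python
from granule_sizer import (
    AcquisitionModel, LengthLaw, PlateDesign, aggregate_wells,
    calibrate_release_model, detect_size_selection,
    sample_granule_population, segment_wpbs, summarize_image)
from granule_sizer.synthgen import apply_release_by_condition, render_plate
from granule_sizer.wpb_segmentation import summaries_to_dataframe

law = LengthLaw.truncated_geometric()          # quantal length law
model = calibrate_release_model(law, 0.15)     # 15% relative fall in phi
acq = AcquisitionModel(field_shape=(256, 256))
design = PlateDesign(conditions=("Unstimulated", "Stimulated"),
                     wells_per_condition=16, fields_per_well=3,
                     cells_per_field=(6, 10), granules_per_cell=(20, 35))

truth = sample_granule_population(design, law, acq, seed=5)
truth = apply_release_by_condition(truth, {"Stimulated": model}, seed=6)
summaries = []
for f, img in render_plate(truth, acq, seed=7):
    _, records = segment_wpbs(img.vwf, acq, image_id=f.image_id)
    summaries.append(summarize_image(records, n_nuclei=len(f.nuclei),
                                     image_id=f.image_id,
                                     condition=f.condition, well=f.well))
wells = aggregate_wells(summaries_to_dataframe(summaries))
print(wells.groupby("condition")["mean_long_area_fraction"].mean())
print(detect_size_selection(wells, control="Unstimulated", seed=1))
```

prints (seed-exact):

```
condition
Stimulated      0.185228
Unstimulated    0.223458
Name: mean_long_area_fraction, dtype: float64
    condition         verdict  fraction_estimate  fraction_p_adjusted  ...
0  Stimulated  long-selective           -0.03823              0.00028
```

The measured long-area fraction falls from ≈0.22 to ≈0.19 — a ~17%
relative fall, consistent with the 15% drop built into the release
model — and the Dunnett-adjusted comparison on 16 wells per condition
flags the stimulated condition as long-selective.

## Command line

```bash
granule-sizer generate    --config cfg.yaml --seed 1 --out plate/
granule-sizer segment-wpb --in plate/ --out results/
granule-sizer summarize   --images results/images.csv --out results/
granule-sizer compare     --wells results/wells.csv --control Unstimulated --out results/
granule-sizer validate    --truth plate/ --results results/objects.csv --out results/
granule-sizer run-experiment --seed 1 --out run/   # all of the above
```

A plate on disk is `root/<condition>/<well>/<field>_<channel>.tif`
(16-bit grayscale) with per-field ground truth JSON; every run writes a
manifest (config, seed, output hashes) and all CSVs are bit-reproducible
for a fixed config and seed.

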