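# Methods

## Scientific model

Weibel-Palade bodies (WPBs) are modelled as straight rods of quantized
length `L = k × 0.5 µm` (k = 1…12 by default) and uniform
sub-diffraction width `W = 0.2 µm`. Quantization reflects the linear
co-packaging of pre-sized half-micron vWF quanta; the uniform width
means the footprint of a granule is a stadium (rectangle with
semicircular caps) of area `A(L) = L·W + π(W/2)²`. The default length
law is a geometric distribution over quantum counts, `P(k) ∝ (1-p)^(k-1) p`
with `p = 0.5`, truncated and renormalized at 12 quanta. This gives a
long-tailed, distinctly non-normal distribution spanning 0.5–6 µm with
mean length ≈ 1.0 µm and a population long-area fraction (area carried
by granules > 2 µm) of ≈ 0.186 — a realistic regime in which long
granules are a small numerical minority but a substantial area
fraction, so the headline statistic is informative but not saturated.

Agonist stimulation is modelled as independent Bernoulli removal of
granules with probability

```
p(L) = p_base + p_max / (1 + exp(-(L - L0) / s))
```

(`L0` midpoint, `s` steepness, both in µm). The family nests the two
competing hypotheses exactly: `p_max = 0` or `s → ∞` is
length-independent ("random selection") release, which provably leaves
the expected long-area fraction of the retained population unchanged;
`p_max > 0` at finite `s` removes long granules preferentially.
`calibrate_release_model` inverts the closed-form retained-fraction
expression (a weighted sum over the 12 support points) with Brent's
method to find the `p_max` producing a prescribed relative fall — the
simulations here use a 15% relative fall, the magnitude of biological
interest, at `p_base = 0.2`, `L0 = 2 µm`, `s = 0.3 µm`.

## Forward optical model

The synthetic microscope mimics a high-content plate reader with a 40×
air objective, NA 0.6: pixel size 0.325 µm, emission 0.52 µm, Gaussian
PSF with σ = 0.21·λ/NA ≈ 0.18 µm, Rayleigh limit 0.61·λ/NA ≈ 0.53 µm,
16-bit quantization, 512×512 px fields. Only the objective and NA are
anchored to the real instrument class; pixel size, noise levels
(background 100 counts, read noise SD 2, photon scale 200 counts per
unit fluorophore density) and field size are declared defaults, all
configurable. Granules are drawn anti-aliased on a 4× supersampled
grid, blurred with the PSF, integrated to camera pixels, Poisson
sampled, read-noise corrupted, offset and quantized. Rendering is a
pure function of (truth, acquisition, seed): identical seeds give
bit-identical images. A granule whose footprint would leave the field
is re-placed at sampling time, never clipped; placement also rejects
centroids inside nuclei. Nuclei are non-overlapping ellipses
(semi-axes 4–6 × 3–4.5 µm) with a smooth centre-weighted profile in
channel 1. Exocytic sites are disks whose areas follow a two-component
log-normal mixture (puncta around 0.5 µm², spreads around 3.5 µm²,
large-component weight 0.3); a configurable fraction of sites is
placed touching a neighbour to exercise watershed splitting.

What the generator does *not* emulate: cell boundaries and
cytoplasmic background structure, granule curvature and 3-D
orientation, spatially varying illumination, chromatic offsets between
channels, and optical sectioning. Passing tests therefore demonstrate
correctness of the measurement pipeline under a faithful but idealized
image-formation model, not robustness to every artefact of real plates.

## Segmentation

**WPBs.** Foreground = pixels above their local 51×51 block mean plus
an offset of 8× the read-noise SD. The block (≈17 µm) is larger than
any granule but smaller than illumination gradients. The offset was
chosen by validation against ground truth: lower offsets (e.g. 3×
read noise) admit the PSF skirt around each rod, bridging neighbours
and measurably hurting object recall and length accuracy. Connected
components (8-connectivity) smaller than the resolution-limit disk
(π(0.53/2)² ≈ 0.22 µm²) are removed as unresolvable. Summed record
areas equal the post-filter foreground area exactly.

**Length.** Two measures are provided. For binary masks,
`measure_length` uses the skeleton's longest geodesic path (Dijkstra
over the 8-connected skeleton, diagonal steps √2) plus one estimated
rod width (twice the mean medial distance) as end-cap compensation,
falling back to the ellipse major axis for compact objects. On
*thresholded* masks of diffraction-limited rods, however, the mask
border sits on the blur skirt, ~1 px outside the true footprint per
side, and any mask-derived measure inherits that dilation (~+1 µm bias
at this PSF scale). `segment_wpbs` therefore measures length from
intensity-weighted second moments: the PSF, pixel integration and the
rounded caps all contribute *isotropically* to the covariance, so the
anisotropy `D = σ²_major − σ²_minor` is threshold-free, and the
uniform-stadium relation

```
D = L (L²/6 + πrL/4 + 2r²/3) / (2L + πr)
```

is inverted for `L` (cap radius `r` estimated from the minor-axis
moment after removing PSF and pixel-sampling terms, capped at half the
resolution limit). Neighbouring objects are excluded from the moment
support. Against ground truth this yields bias ≈ −0.1 µm and RMSE
≈ 0.19 µm for granules ≥ 1 µm, versus ≈ 1 µm RMSE for skeleton-based
measurement of the same masks.

**Nuclei.** Otsu threshold of a 1 µm-blurred nuclear channel, hole
filling, removal of regions below 20 µm², then watershed from regional
maxima of the distance transform (minimum separation 2 µm) to split
touching nuclei. A field with zero nuclei makes per-cell metrics
undefined: such ratios propagate as NaN, never as zero, and are
excluded from well means metric-by-metric.

**Exocytic sites.** Gaussian denoise at σ = half the PSF σ (so
resolution is not degraded), then a global moment-preserving (Tsai)
threshold per image (per image, not per plate, because illumination
varies by field): with raw histogram moments m₁–m₃, the representative
levels z₀ < z₁ solve `z² + c₁z + c₀ = 0`,
`c₀ = (m₁m₃ − m₂²)/(m₂ − m₁²)`, `c₁ = (m₁m₂ − m₃)/(m₂ − m₁²)`, the
below-class mass is `p₀ = (z₁ − m₁)/(z₁ − z₀)`, and the threshold is
the gray level whose cumulative histogram fraction is closest to p₀
(the construction that actually preserves the three moments; ties break
to the lower level). Degenerate (constant) histograms return an
explicit no-threshold result; a numerically complex root pair falls
back to the median split with a logged warning. Touching sites are
split by marker-based watershed flooding. Markers are the h-maxima of
the Euclidean distance transform (h = 0.5 px, suppressing the spurious
ridge maxima the discrete transform produces between heavily
overlapping blobs) merged at a minimum separation of 2 px; a component
whose maxima are all suppressed still receives one label. The labels
partition the foreground exactly. Site area is reported at
the binary-mask level, keeping the > 2 µm² classification well defined.

## Statistics

Fields are pseudo-replicates: all inference runs on unweighted well
means (the screening design acquires 9 fields per well, ≥ 8 — here 16 —
wells per condition). Dunnett many-to-one comparisons use t statistics
on the pooled one-way-ANOVA error variance; the familywise adjustment
is the seeded Monte-Carlo distribution of max|t| at the observed group
sizes (default 100 000 draws; simulation-scale tests use 4 000). The
Monte-Carlo estimate is clamped to be ≥ the raw p so adjusted never
undercuts raw by sampling error; with a single contrast the procedure
reduces to the pooled two-sample t test, which the tests verify, and
it agrees with an independent multivariate-t implementation to < 0.01.
Two-way ANOVA (with interaction, type-II sums of squares via
statsmodels) supports factorial layouts; selected cell contrasts are
tested with the pooled residual error and Šidák-adjusted,
`p_adj = 1 − (1 − p)^m`. All tests are two-tailed at α = 0.05.

The size-selection verdict compares `mean_long_area_fraction` per well
against the control with Dunnett adjustment: a significant fall is
"long-selective", a significant rise "short-selective", otherwise
"non-selective"; the per-cell WPB-count comparison is reported
alongside so "many granules released but fraction unchanged" is
distinguishable from "no release".

Secretion tables: percent released = 100·releasate/(releasate+lysate);
fold inhibition = released-with-inhibitor / released-without (1 = no
effect, < 1 = inhibition). By default the percent-released ratio is the
numerator basis, with a flag to use raw releasate instead.

## Numerical and design choices

- Mask-level areas are blur-dilated, so the *measured* long-area
  fraction exceeds the ground-truth population value by a roughly
  condition-independent factor (≈ 0.22 measured vs ≈ 0.19 true at
  default settings). The factor cancels in between-condition
  comparisons, which is what the assay interprets; estimator-fidelity
  checks against ground truth are run on the truth-level statistics.
- Validation matches objects one-to-one by greedy ascending centroid
  distance within a 0.5 µm gate (point annotations are the realistic
  gold standard for sub-diffraction rods; IoU would be unstable at
  these widths). Greedy matching is verified against optimal
  assignment on small scenes.
- Watershed ties and label orders follow deterministic scan order;
  every stochastic routine takes an explicit seed; CSVs render floats
  at fixed precision so repeated runs are byte-identical.
- Simulation scales: the type-I calibration runs 200 replicate
  experiments on ground-truth statistics at the full 16-well × 9-field
  design; the power simulation renders 20 replicate experiments at 16
  wells × 3 fields of 256×256 px with 6–10 cells per field, keeping the
  well count (the unit of inference) at full design while rendering a
  reduced field load. The acceptance script scores segmentation on a
  4-well × 6-field plate at full 512×512 default optics.

## Known limitations

- The release model is monotone in length; "short-selective" release
  (disproportionate loss of short granules) can be asserted on data but
  is not generated by the logistic family.
- No cell-boundary segmentation: per-cell normalization uses nucleus
  counts only.
- Moment-based lengths assume one rod per connected component;
  unresolved crossings or end-to-end contacts bias the measure, which
  is the main residual error term in the validation scores.
- No mixed-effects modelling of the plate/well hierarchy; wells are
  treated as independent units within a plate.
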