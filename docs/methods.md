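# Methods

## Scientific model

Astroglial aquaporin-4 (AQP4) is normally *polarized*: concentrated in the
perivascular endfeet that ensheath brain microvessels, with much lower
density over the astrocyte soma and fine processes. Loss of this
polarization — less endfoot signal, more diffuse parenchymal signal — is a
hallmark of aging and of Alzheimer-type pathology, and it degrades
perivascular (glymphatic) CSF–ISF exchange. `perivaq` implements the three
measurement families used to quantify this phenotype in 2-D fluorescence
micrographs, plus the statistics that compare them across groups, and a
synthetic-micrograph generator that plants every quantity so the entire
pipeline is verifiable by parameter recovery.

### Human dual-threshold analysis

Post-mortem human cortex carries heavy autofluorescence and lipofuscin, so
endfoot-resolved profiling is not practical; quantification is
threshold-based per 1000×1000-px ROI (six gray-matter and six white-matter
ROIs per section; hippocampal CA1–CA3 ROIs drawn individually):

- **vessel class** — pixels ≥ the *vessel threshold* `T_v` (the bright
  vessel-edge/endfoot signal);
- **cellular class** — pixels in the half-open band `[T_c, T_v)` (astrocyte
  fine-process signal above the *cellular threshold* `T_c`);
- **polarization ratio** = mean(vessel class) / mean(cellular class);
- **cellular area coverage** = |pixels ≥ `T_c`| / ROI area (the vessel class
  is deliberately a subset of the covered area, while it is excluded from
  the ratio's denominator — including it would bias the ratio toward 1);
- **mean IF** = unthresholded ROI mean;
- **p-tau density** = AT8-positive somata / mm² (manual count, or an
  intensity-percentile + area gate of 20–400 µm² when counting from an
  image).

Thresholds are experiment-wide constants chosen by a blinded reviewer; the
`auto_thresholds` helper proposes a percentile pair (defaults: 99.5th for
vessel, 90th for cellular) purely as a reviewable starting point. An ROI in
which either class is empty yields an *undefined* ratio that propagates as
a missing value, never as a zero or an imputation. Subject-level values are
arithmetic means over the valid ROIs of a region, recording `n_used`
(out-of-focus ROIs are excluded, mirroring routine practice of dropping 1–2
frames per dataset).

### Rodent radial profiling

Vessel lumens are segmented from the lectin (endothelial) channel by Otsu
threshold → morphological closing → connected components. Diameter is twice
the maximum inscribed-disk radius from the in-lumen distance transform,
minus one pixel (the transform reaches background pixel *centers*, half a
pixel beyond the wall on each side). Vessels are **capillaries** when
diameter < 10 µm, **large** otherwise; a measured diameter of exactly 10 µm
is classed large, a deterministic convention for a boundary the <10 / >10
definition leaves open.

- **Capillaries**: endfoot IF = mean AQP4 in the 0–1.5 µm annulus outside
  the wall; neuropil reference = the 5–15 µm annulus, excluding other
  vessels' lumens and endfoot bands. The 1.5-µm band width matches the
  large-vessel endfoot compartment; 5–15 µm keeps the reference local while
  clearing endfoot contamination (both configurable). A vessel whose
  endfoot annulus is clipped below 50% by the image border is skipped and
  logged.
- **Large vessels**: intensity is sampled along the line through the vessel
  center perpendicular to its principal axis (image x-axis, with a log
  note, for near-circular cross-sections), one pixel per step out to 68 µm
  per side. In-lumen samples are excluded; distance is counted from the
  wall, the first tissue sample sitting one pixel (0.42 µm at the default
  sampling) from it — the same convention as the Euclidean distance
  transform, so line-sampled and EDT-binned profiles are directly
  comparable. The two half-profiles are folded and averaged per bin with
  sample-count weighting; missing bins are excluded, never interpolated. A
  profile truncated below 68 µm on *both* sides is flagged.
- **Compartments**: perivascular endfoot [0, 1.5) µm, perivascular
  astrocyte [1.5, 20) µm, neuropil [20, 68] µm from the wall (the outer
  bound treated as inclusive). `diameter_association` fits per-group OLS of
  compartment IF on diameter and tests slope differences through the
  group × diameter interaction (partial F).
- **Puncta**: GFP puncta are seeded at local maxima and sized by the
  connected area above half the seed intensity; the headline metric is the
  count ratio of large (≥ 2 µm²) to small (≤ 1 µm²) puncta, with areas in
  (1, 2) µm² belonging to neither class and a zero small-count flagged
  undefined. `gfp_localization_ratio` compares mean GFP in the
  0–1.5 µm perivascular band of any wall against the remaining non-lumen
  tissue.

### Tracer coverage

CSF tracer influx (intracisternal) and efflux (intraparenchymal) are
quantified as thresholded area fractions per region (cortex, hippocampus,
striatum, diencephalon, plus whole slice; efflux splits each region at the
midline into ipsi-/contralateral halves). One uniform threshold per
experiment is applied to every animal and slice. Slices are integrated at
the standard coronal levels (influx: +1, 0, −1.5, −2.5, −3.5 mm from
bregma; efflux: +2.5, +1.5, 0, −1, −2 mm) as the area-weighted ratio
Σ covered / Σ region area — robust to unequal region areas across levels
and to excluded slices, which simply drop out of both sums.

### Statistics

All tests return a uniform `StatsResult` with raw and adjusted p-values
(adjusted ≥ raw always, enforced by computing both from the same pooled
error):

- one/two-way ANOVA with Dunnett (k−1 contrasts vs a reference), Tukey
  (all pairs) or Sidak corrections; zero within-group variance with
  distinct means degenerates gracefully to F = ∞, p = 0;
- random-intercept mixed models (REML) for vessels/ROIs nested in animals
  or subjects. statsmodels' MixedLM supplies estimates; fixed effects are
  tested on t with *between–within* denominator degrees of freedom: a term
  constant within clusters is judged against df = (clusters − cluster-level
  parameters), not the number of pseudo-replicates. With 12 animals this
  keeps type-I error at nominal 5% where a plain Wald z is liberal (~8%).
  Variance components (cluster and residual SD) are reported;
- OLS regression with covariate control; partial-regression coordinates are
  the two residual vectors, whose slope equals the multiple-regression
  coefficient exactly (Frisch–Waugh–Lovell);
- Welch t-test by default (no equal-variance assumption); two constant
  equal samples return p = 1 by logged convention.

Missing values are dropped listwise per model with logged counts.

## Synthetic data: what it emulates, what it does not

Generators are deterministic given spec + seed (no global random state) and
return the planted truth alongside the image.

- **Vessel scenes** (`generate_vessel_scene`): straight tubes (capillaries)
  or disks (penetrating vessels in cross-section) on a neuropil baseline,
  with an endfoot ring (default 1.5 µm) at the wall, a diffuse
  perivascular-astrocyte halo out to 20 µm whose amplitude rises linearly
  with vessel diameter, a lectin lumen channel, optional Poisson shot and
  Gaussian read noise, and optional lipofuscin granules. Default sampling
  0.42 µm/px. Labels (lumen/endfoot/pv-astro/neuropil) tile the raster
  exactly and the noiseless compartment means are recorded, giving every
  recovery test an exact oracle.
- **Human ROI cohorts** (`generate_human_roi`, `generate_cohort`): slide
  background (10 AU), a speckled fine-process tier (100 AU, 25% of
  pixels), and endfoot rings at *contrast* × 100 AU around three vessels;
  subject ratios are drawn per diagnostic group (worked-example defaults:
  CN 2.0, MCI 1.8, AD 1.5, SD 0.2 — a graded depolarization), and
  cognitive/pathological covariates (MMSE, CDR-SoB, CERAD, Braak, p-tau
  density) follow linear links with noise, clipped to their clinical
  ranges. At contrast 1.0 the rings are rendered at the cellular level —
  the depolarized phenotype in which no intensity threshold can separate
  endfeet from the rest of the astrocyte; recovery of that column is
  therefore checked against the label raster (see "Numerical choices").
- **Rodent cohorts** (`generate_rodent_measures`): per-vessel compartment
  intensities drawn from planted group means (aged defaults: endfoot −30%,
  perivascular astrocyte +40% including its diameter slope, neuropil
  unchanged) with a per-animal random intercept (SD 5 AU) and vessel-level
  noise (SD 12 AU), 6 animals × 15 vessels per group. Replicate
  power/type-I simulations run at this measurement level; single cohorts
  are additionally rendered and measured at pixel level in the test-suite
  to show the two levels agree.
- **Tracer slices** (`generate_tracer_slices`): stylised elliptical coronal
  sections with a cortex shell and three disjoint deep regions; the tracer
  front fills each region from its shallowest (surface-nearest) pixels
  until the planted fraction is covered (±1 px quantization), then gets a
  soft edge and noise.
- **Puncta fields** (`generate_puncta_field`): non-overlapping Gaussian
  blobs whose half-maximum contour encloses exactly the requested area
  (σ = √(area / 2π ln 2)); rejection-sampled placement errors out rather
  than overlapping.

Not emulated: realistic optics (PSF beyond Gaussian blur), 3-D stacks,
vascular network topology and curvature, staining batch effects,
arterio-venous identity, spectral bleed-through. Passing recovery tests
therefore demonstrate correctness of the *measurement operators and
statistics* under the stated image model, not robustness to every artefact
of real tissue.

## Numerical choices

- Intensity scales are arbitrary (AU); only contrasts are meaningful.
- Distance convention: first tissue pixel = 1 px from the wall, everywhere
  (profiles, annuli, EDT oracles).
- Vessel diameter: 2 × max inscribed EDT radius − 1 px.
- At planted contrast 1.0 the dual-threshold ratio is *provably* undefined
  on a noiseless image: two nonempty classes split at `T_v` cannot both
  average 100 AU (members below `T_v` ≤ 100 average < 100). The recovery
  suite reads that column from the ground-truth labels; all contrasts > 1
  exercise the threshold operator itself, exactly at zero noise.
- Dunnett p-values integrate a multivariate t by quasi–Monte Carlo; the
  integration rng is fixed so reruns are byte-identical.
- Simulation replicate counts (500 t-test / 500 ANOVA / 1000 mixed-model
  type-I; 100 phenotype cohorts; 100 variance-component fits; 2000 power
  draws) are sized so binomial noise is small against the calibration
  bands while the whole verification layer stays inside a few minutes.
- Degenerate inputs fail loudly: constant ROIs (thresholds undefined),
  single clusters (mixed model), collinear designs (regression, naming the
  offending pair), misordered compartment boundaries (config validation
  before any computation).

## Known limitations

- 2-D only; puncta analysis is a 2-D reimplementation of what is often done
  on rendered 3-D volumes, so absolute areas are not comparable to volume
  pipelines.
- Vessels near the image border inflate the inscribed-radius diameter
  (background beyond the border is invisible to the EDT); severely clipped
  vessels are skipped by the annulus edge policy rather than corrected.
- Vessels within ~0.4 µm of the 10-µm class boundary can be assigned to
  either class by pixel quantization.
- The mixed model fits a single random intercept; random slopes and
  crossed designs are out of scope.
- `auto_thresholds` is a convenience, not a substitute for reviewed,
  experiment-wide manual thresholds; percentile pairs collapse on heavily
  quantized histograms and the function refuses rather than guessing.
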