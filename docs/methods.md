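# Methods

## Scope and data model

The package implements a harvest-year authentication analysis for spring
barley kernels. Four data modalities enter the analysis:

1. **FT-NIR spectra** — absorbance vs wavenumber, acquisition grid
   12,500→3,600 cm⁻¹ in 16 cm⁻¹ steps (557 points, stored descending),
   three replicates per sample.
2. **Stable-isotope deltas** — δ¹³C (vs V-PDB), δ¹⁵N (vs air N₂), δ¹⁸O
   (vs V-SMOW), one triplet per sample, in ‰.
3. **¹H-NMR betaine region** — intensity vs chemical shift over at least
   3.275–3.235 ppm, one spectrum per sample.
4. **Daily weather** — precipitation, mean and maximum temperature for the
   growing region, one calendar year per table.

The study design is two cultivars × two harvest years with group sizes
Quench 19/20 and Steffi 22/25 (2017/2018).

## Preprocessing choices

**Rubber-band baseline.** 64 equidistant anchor candidates are placed on
the wavenumber axis; the baseline is the linear interpolation of the lower
convex hull of the anchors; ten refinement passes pull each anchor down to
the current baseline and re-hull. The exact anchor-placement and pulling
rules of commercial implementations are not standardized; this
hull-envelope formulation is fixed here so results are bit-reproducible.
The corrected spectrum is provably non-negative at every anchor.

**Binning.** The 11,000–4,000 cm⁻¹ range is divided into 300 equal buckets
(width 7000/300 ≈ 23.33 cm⁻¹) and each bucket value is the trapezoidal
integral of the piecewise-linear interpolant — an area, not a point
average, which makes binning exactly linear and additive (the 300 values
sum to the total integral). Because the 16 cm⁻¹ instrument grid has no
points exactly at 4,000/11,000 cm⁻¹, a spectrum is accepted if it covers
the range to within one grid spacing; edge values are held constant over
the sub-spacing overhang.

**Replicates** are averaged after baseline correction and before binning
(one row per sample). Binning is linear, so averaging before or after
binning is equivalent; a pipeline switch (`average_replicates=False`)
instead enters each replicate as its own row with duplicated isotope
values.

## Statistics

**Directional U.** The Mann–Whitney–Wilcoxon statistic is reported as
U = #{(a,b) : a > b} + ½·#ties with the 2017 group first, so U = 0 means
every 2017 value lies below every 2018 value. p-values are exact (full
enumeration) when n_a·n_b ≤ 400 and the pooled data are tie-free,
otherwise a normal approximation with tie and continuity corrections is
used; the result records which path was taken. Exact and approximate
p agree to well within 0.01 for groups of 15 or more.

**Kruskal–Wallis filter.** Per-variable H with midrank ties and the
standard tie-correction divisor. Variables are ranked by descending H with
ties broken by ascending variable name (a deterministic, if arbitrary,
rule — made explicit so selections are reproducible). Constant variables
get H = 0, never an error. For two tie-free classes, ranking by H is
equivalent to ranking by |U − n_a n_b/2| (verified exhaustively on small
tables in the test suite).

**PCA and the 95 % radius.** PCA is computed by SVD of the autoscaled
matrix (no further centering); explained variance per component is
100·σ_k²/Σσ_i²; each component's sign is fixed so its largest-magnitude
loading is positive. The class threshold is a *circle*, not an ellipse:
the radial scale s_c = √(½·mean squared centroid distance) is the
isotropic-bivariate-normal scale estimate, and r_c = s_c·√χ²₂;₀.₉₅
(χ²₂;₀.₉₅ = 5.99146) is the 95 % radius. The circular rule follows the
stated Euclidean-distance criterion; confidence *ellipses* are treated as
a display device only. Classification uses exactly two components by
default (configurable).

**Cross-validation.** 100 random stratified 90/10 splits. Stratification
(rather than fully random splits) prevents degenerate single-class
training sets at n ≈ 40. Feature selection, autoscaling, PCA and the
centroid thresholds are all refit inside each training fold, so no test
information leaks into the model; a test asserts that corrupting held-out
rows changes nothing fitted from the training rows. Whether the original
analysis selected features once globally or per fold is not determinable;
per-fold is the default because it is the leakage-free choice, and a
global pre-selection can be emulated by selecting first and running CV on
the reduced table.

**Unassigned is incorrect.** A sample outside every class radius is left
unassigned and counted against accuracy — the conservative reading. A
consequence worth noting: under label permutation the CV "chance" level is
not 50 % but roughly 50 % times the assignment rate (≈ 30 % in practice),
because the rejection option removes mass from both correct and incorrect
assignments.

**Climate.** De Martonne I_DM = RR/(TM+10); classes are half-open
intervals per the "below 20 / below 30" wording: [0, 20) semi-dry to dry,
[20, 30) humid to Mediterranean, [30, ∞) humid. Hot days use a strict
tmax > 25 °C rule over June 1–August 31. The 30-year reference-period
precipitation means are *derived* constants — back-calculated from the
reported (total, percent-of-reference) pairs 573.9 mm = 106 % (annual) and
285.1 mm = 155 % (June–August) — not station measurements.

**Betaine.** Peak intensity is the windowed maximum within ±0.003 ppm of
3.255 ppm (height, not fixed-point read-off), which absorbs the small
chemical-shift variation between sample preparations; an integral mode is
available. Confidence bands on group mean spectra are pointwise t-based
intervals, not simultaneous bands, matching the per-point dotted-line
display convention.

## The synthetic-data generator

Raw measurements for this kind of study are typically not deposited, so
the generator is a first-class module that emulates the study conditions
at the processed-data level; all analyses run identically on real files
(CSV + two-column spectra) via the `files` mode.

**What it emulates.**

* Six Gaussian NIR bands at 8264, 6800, 6300, 5665, 5170 and 4854 cm⁻¹
  on a smooth convex background, with 2018 amplitude shifts of
  +0.06/−0.08/−0.04/+0.05/−0.07/+0.05 absorbance (lipid and protein up,
  moisture and starch down) — directions follow the known drought
  response of kernels; magnitudes are calibrations.
* Isotope triplets drawn normally around the per-group medians
  (Quench: −27.1/−25.2 ‰ δ¹³C, 3.0/5.0 ‰ δ¹⁵N, 29.6/28.2 ‰ δ¹⁸O;
  Steffi: −26.7/−26.0, 4.5/4.7, 26.9/26.8). No dispersion statistics are
  reported for any variable, so the sds (0.3–0.6 ‰) are calibrations
  chosen to reproduce the qualitative pattern: Quench δ¹³C groups fully
  separated (U = 0 with probability > 0.99), Steffi δ¹³C weakly but
  significantly separated (sd 0.45 ‰, so it stays out of the top-50
  variables while remaining MWW-significant), Steffi δ¹⁵N/δ¹⁸O heavily
  overlapping.
* A betaine Lorentzian (half-width 0.0015 ppm) at 3.255 ppm with N(0,
  0.001 ppm) shift jitter and year amplitudes 0.55 ± 0.05 (2017) vs
  1.00 ± 0.06 (2018) — every 2018 sample higher than every 2017 sample
  with overwhelming probability.
* Daily weather hitting the study-year targets exactly: annual/June–August
  precipitation 573.9/285.1 mm (2017) and 377.1/77 mm (2018) enforced by
  rescaling gamma-distributed daily draws; hot-day counts 28 and 48
  calibrated exactly by a uniform temperature shift; annual mean
  temperatures 9.8 and 10.9 °C, which place the two years in the humid-to-
  Mediterranean and semi-dry-to-dry De Martonne classes respectively.

**Within-class structure (the key design decision).** Within a
cultivar-year group, NIR variability is modelled as a *bounded*
two-dimensional sample state drawn uniformly from a disc (radius 0.06
absorbance in band-amplitude space): one mode along the harvest-year band
signature (samples differ in individual drought exposure) and one
orthogonal compositional mode on the same bands. On top of this, each
band's center jitters uniformly by ±3 cm⁻¹ per sample (moisture- and
temperature-driven band-position variation) and each replicate carries
i.i.d. N(0, 0.002) detector noise.

Two reasons, both load-bearing:

* *Attainability of perfect classification.* With an unbounded (Gaussian)
  sample state, ~5 % of training samples fall outside their own class's
  95 % radius *by construction*, capping expected resubstitution accuracy
  near 95 % at any effect size. A uniform disc has maximal within-class
  distance 2σ per axis, strictly inside the χ²₂ radius 2.45·σ, so a
  bounded, approximately isotropic 2-D state makes 100 % classification a
  property of the population rather than a run of luck. Real reference
  datasets of this size that report 100 % are consistent with effectively
  bounded biological variation.
* *Realistic rank structure for feature selection.* With amplitude-only
  variation, every band bin separates the years perfectly and ~70+
  variables tie at the maximal Kruskal–Wallis score, which makes top-50
  selection an artifact of the tie-break. The band-center jitter breaks
  this saturation on band flanks, grading H smoothly across each band, so
  the selected set spans all six bands and the isotope variables compete
  on real signal.

**What it does not emulate.** Instrument physics (interferograms, FID
processing, detector response), scatter effects requiring SNV/MSC
correction, inter-modal correlation (a sample's isotope state is drawn
independently of its NIR state), pedology/fertilization effects on δ¹⁵N,
and any geographic variation — the study design holds origin fixed.
Passing tests therefore demonstrate that the analysis chain is correct and
that the reported outcomes follow from the stated group differences; they
do not validate the chain against instrument artifacts absent from the
generator.

**Determinism.** Every generator derives its stream from
`(seed, modality-tag, cultivar, year)`, so outputs are bit-identical for
identical configurations and insensitive to call order.

## Numerical conventions and degenerate inputs

* Medians are the standard mid-order statistic (mean of the two central
  order statistics for even n); no interpolation variants.
* Autoscaling uses the n−1 sd and refuses zero-variance columns by name.
* Two-sided exact MWW p-values follow the 2·min(P≤, P≥) convention capped
  at 1 (for {1,3} vs {2,4} full enumeration gives U = 1, p = 2/3).
* A class with fewer than two samples, or with zero score dispersion,
  cannot parameterize a threshold circle and is an error.
* Stratified splits round the per-class training count to the nearest
  integer; invalid splits (empty test set, a training class below two) are
  redrawn with a bounded retry.
* Seeds are plain integers; the acceptance script reduces its seed modulo
  2³¹.

## Problem sizes

Default test and acceptance runs use the full study geometry (86 samples,
3 NIR replicates, 557-point spectra, 303 fused variables, 100 CV
iterations); the complete suite runs in well under a minute on one CPU, so
no scaled-down surrogate geometry is needed.

## Known limitations

* The circular threshold ignores within-class anisotropy; strongly
  elongated score clouds are penalized relative to an elliptical
  (Mahalanobis) rule. This mirrors the stated classification criterion.
* The exact/approximate p-value switch threshold (n_a·n_b ≤ 400, tie-free)
  is a pragmatic default; both paths are exposed.
* Reference-period climate normals are derived, not authoritative.
* Generator dispersions are calibrations, not measurements; conclusions
  about *rates* (e.g. CV accuracy distributions) are conditional on them.
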