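# Methods

## Reference-interval model

Each measurement is modelled cross-sectionally as Gaussian at every
gestational age (GA), with age-varying mean and SD:

* **Mean**: OLS polynomial in centered GA (t = GA − 30 weeks). A quadratic
  is used for every 2D and 3D measurement except cortical volume, whose
  growth is multiplicative and is fitted as ln y = α + k·t (so the mean is
  exp(α + k·t) and the absolute growth rate is k·mean). Exponential-family
  residuals are returned on the original measurement scale, because the
  centile equation mean + K·SD applies to raw values, not logs.
* **SD**: the absolute residuals are scaled by √(π/2) — the half-normal
  mean correction, E|r|·√(π/2) = σ for r ~ N(0, σ²) — and regressed on
  centered GA by OLS: a straight line for all measurements, a quadratic
  for cortical volume. The exact scaled-residual variant is a modelling
  choice; the half-normal construction is the standard one for this
  family of reference models and is what we implement.
* **Centiles**: centile_p(t) = mean(t) + K(p)·SD(t), K(p) the
  standard-normal quantile computed at run time (any p is supported;
  charts default to 5/50/95). z = (y − mean)/SD, percentile = 100·Φ(z).

Centering at 30 weeks is for numerical conditioning only; predictions are
invariant (to ~1e−10) under joint shifts of the ages and the center, and
the centering constant is stored with the model.

**SD positivity.** A reference model whose SD curve is zero or negative
anywhere inside the observed GA domain is unusable, so fitting *fails
loudly* (`DegenerateSDError`) rather than flooring the curve. At reference
sample sizes (n ≈ 127) with an SD that widens roughly ten-fold across
gestation, the fitted SD polynomial can dip below zero near the young edge
for some samples; the cohort-level helper (`fetalcentiles.fitting`)
therefore performs explicit, logged model-family adequacy selection,
falling back from a quadratic to a linear SD, and reports when no family
is adequate. The analysis drivers surface such refusals instead of hiding
them.

**Repeated scans** from the same fetus (17 twice, 1 thrice) are treated as
independent observations in all fits, a deliberate simplification of the
longitudinal correlation structure; with ≤ 3 scans per subject and 108
subjects the impact on the mean curve is negligible, but centile widths
are very slightly optimistic.

## Growth metrics

* Absolute growth rate = analytic derivative of the mean curve
  (b + 2c·t, or k·mean for the exponential family); tested against
  central differences to 1e−6 relative.
* Relative growth rate (RGR) between two points = 100·(ln V₂ − ln V₁)/
  (GA₂ − GA₁) %/week. Growth tables report both a per-row instantaneous
  relative rate (100·mean′/mean) and the endpoint-span RGR, because
  published summaries mix conventions; the endpoint formula applied to the
  tabulated 22- and 38-week means does not reproduce some historically
  printed summary rates, so no attempt is made to match those.
* Derived 2D quantities: head circumference = 1.62 × (skull BPD + skull
  OFD); linear extra-cerebral CSF = skull BPD − brain BPD (negative values
  allowed but flagged); ventricular asymmetry uses the symmetric
  denominator 100·(L − R)/((L + R)/2), antisymmetric under side swap.
* Allometric exponent = OLS slope of ln y on ln x between structure
  volumes.
* Growth-table cells are rounded to 2 dp half-away-from-zero.

## Agreement statistics

ICC is the two-way, absolute-agreement, single-measure coefficient
ICC(A,1), computed from the ANOVA mean squares; absolute agreement is the
appropriate variant for method comparison since it penalises constant
offsets. Bland–Altman limits are bias ± 1.96·sample SD of differences.
Percentage error per pair is 100·|a − b|/mean(a, b); no intra-observer
correction is applied. Spearman correlation uses mid-ranks for ties (via
scipy) with a brute-force rank-then-Pearson oracle in the tests.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes —
it is the test bed, not a model of raw MR images:

* **Truth curves** are anchored by least squares to the published average
  volumes at 22/26/30/34/38 weeks for the five volumetric structures
  (quadratic; exponential for cortex). The published record contains no
  per-structure SD magnitudes, so SD truth is a convention: linear in GA,
  anchored to a coefficient of variation of 8% of the mean at 21 weeks
  rising to 12% at 39 weeks (mimicking the reported widening of the
  volume range from about 30 weeks). For the exponential-mean cortex the
  same CV anchors are interpolated with a quadratic, since a straight SD
  line against an exponential mean would let the CV balloon mid-gestation
  and is systematically negative at the young edge. These SDs are
  synthetic and are labelled as such.
* **GA distribution**: triangular on 21.29–38.86 weeks with mode 29.5 —
  unimodal, seedable, and close to the reported scan-age histogram.
  Repeat-scan visits are drawn ≥ 2 weeks after the previous one, inside
  the range.
* **Noise**: additive Gaussian per scan and structure; negative draws are
  resampled (≤ 100 tries) to preserve the Gaussian model rather than
  truncating it. Left and right lateral ventricles share a subject-level
  random effect (half the side variance) plus independent noise scaled so
  the SD of their sum equals the truth SD of the total; the configured
  laterality offset (default 17.91% of the side mean) makes left > right,
  and male fetuses carry a 10% larger total-ventricle mean (the published
  sex effect is significant but unquantified; 10% is our choice).
* **Cohort structure** defaults: 108 subjects (57M/51F), 17 scanned
  twice and 1 thrice (127 scans), recruitment groups 83/15/5/5, plus one
  singly-scanned annotated subject per configured exclusion reason
  (defaults: the published frequencies summing to 20), and follow-up
  scores for 81 subjects (75%).

What the generator does **not** emulate: segmentation error structure
beyond additive noise, longitudinal within-subject growth correlation
(repeat scans are fresh draws around the mean curve), skewness or
heavy tails, and any GA-estimation error. Passing tests therefore
demonstrate that the pipeline recovers the generating model under its own
assumptions — not that real fetal measurements satisfy those assumptions.

## Exclusion pipeline

Subject-level rules are evaluated in declaration order and a subject is
attributed to the first matching reason only: infection, delivery
complications, chromosomal abnormality, developmental delay (GMDS DQ < 88
or SQ < 84; Bayley scaled < 7 or composite < 85; ASQ z < −2 — thresholds
are strict "below"), IUGR, seizures, and no-contact (no postnatal contact
AND no delivery summary; missing follow-up alone never excludes). Image
quality is handled at scan level: a motion-corrupted scan is dropped and
the subject excluded only if no usable scan remains (a subject-level
policy is available behind a flag, since the original granularity is
ambiguous). Excluding a subject removes all of that subject's scans, and
the audit reconciles exactly: evaluated = excluded + included, per-reason
counts sum to the excluded total.

## Calculator

GA at scan = 40 − (EDD − scan date)/7 in decimal weeks, rounded to 2 dp
(day resolution; no rounding down to completed weeks), validated to
15–43 weeks with a 4-week post-EDD sanity bound. Reports are fully
reproducible from the serialized model JSONs; unknown measurements are
listed as skipped rather than dropped, and out-of-domain ages are flagged
as extrapolation rather than refused.

## Problem sizes and tolerances

Monte-Carlo fidelity checks use 5000-subject cohorts (3-standard-error
bands); parameter-recovery checks use 2000 subjects, at which mean curves
are recovered well within 2% and SD curves within ~5% at 25/30/35 weeks
(SD estimates from scaled absolute residuals carry relative standard
errors of a few percent at this n, so the SD bound is looser than the
mean bound). Coverage checks simulate 4000 points from a fitted model and
use 3σ binomial bands around 5%; the n = 127 |z| > 1.645 fraction is
checked against the binomial 95% band [5%, 16%]. OLS fits are verified
against explicit normal-equation solves to 1e−8 relative. The whole suite
runs in a few seconds on one CPU.

## Known limitations

* Gaussian-only centiles (no Box–Cox/LMS skewness), by design.
* Cross-sectional treatment of repeat scans (above).
* The SD-family adequacy fallback can leave a structure without a
  reference model at small n when no polynomial family stays positive;
  this is surfaced, not silently repaired.
* The synthetic truth's SD convention is a documented invention; any
  quantity that depends on absolute SD magnitudes (centile widths, ICC of
  simulated raters) is only meaningful relative to that convention.
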