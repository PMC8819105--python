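# Methods

## The assay and its analysis model

The pipeline analyzes a live-cell reporter assay in which FGF/SRF
pathway activity is read out as luminescence. One *experiment* is a
plate carrying, for a single chemical, three well roles: background
(vehicle without bFGF stimulus), vehicle+bFGF, and chemical+bFGF at
each concentration of a descending dilution series; wells are read on a
shared time grid over the 0–24 h window after stimulation, with the
chemical applied one hour before the stimulus. The analysis does not
model the biology of the response; it quantifies, per concentration,
how far the chemical's log fold-change time course departs from the
vehicle's, and aggregates that departure into a single score.

### Normalization

Reads are divided by the mean background signal at the same time point
(RLU), min-max scaled over the whole experiment pooled (all wells,
replicates, times), then each series is divided by the mean scaled
vehicle series per time point and log-transformed. Two decisions here
were genuinely open:

* **Background division, not subtraction.** The background step is
  described ambiguously in such protocols ("compared to"); division is
  used, making RLU a unitless signal-to-background ratio that cancels
  detector gain. Subtraction would leave arbitrary detector units in
  all downstream quantities.
* **Ratio floor ε.** Min-max scaling maps the pooled minimum to exactly
  0, so the chemical/vehicle ratio of scaled values can blow up (or hit
  0/0 at the stimulus time, where all stimulated wells sit at
  baseline). A small additive floor, default ε = 10⁻³ of the scaled
  range, is applied to numerator and denominator. The floor is recorded
  in the normalization metadata; results are insensitive to its exact
  value over 10⁻⁴–10⁻².

The fold-change logarithm is natural by default (configurable to base 2
or 10); a base change multiplies every ABC value by one global
constant and nothing else, which the tests verify.

### Splines at fixed effective degrees of freedom

Log fold-change courses are smoothed with penalized cubic regression
splines: a B-spline basis with knots at the distinct observation times
and a roughness penalty on the integrated squared second derivative.
The smoothing level is parameterised by effective degrees of freedom —
the trace of the smoother matrix — and matched to the target (default
6) by root finding on the penalty weight, to a tolerance of well under
0.05 df. Six degrees of freedom resolve the response shapes of interest
(ramp-and-hold, single pulse) without chasing replicate noise on a
49-point grid. Lines lie in the penalty's null space, so straight-line
data are reproduced exactly at any smoothing level. Replicates are
pooled as independent observations. Because the smoother depends only
on the design (times, df, evaluation grid), not the responses, the
fitted operator is cached and reused across wells, which makes the
1000-replicate calibration runs cheap.

The control curve a(t) is fitted to the vehicle replicates' own log
fold changes against the vehicle mean — near zero but not identically
zero, mirroring how both curves are fitted in practice; a flat a ≡ 0 is
available as a configuration flag.

### The ABC statistic

With a(t) and b(t) evaluated on a 0.5 h grid over [0, 24] h, node
distances h_i = |a(t_i) − b(t_i)| are accumulated by the plain
trapezoid rule. Positive and negative parts of (b − a) are accumulated
the same way; because the pointwise decomposition |d| = d⁺ + d⁻
commutes with the trapezoid rule, the two signed areas sum to the ABC
exactly, with no sub-grid crossing refinement. The 0.5 h evaluation
grid was chosen because, for curves as smooth as df-6 splines, the
trapezoid sum is within 0.1% of fine-grid quadrature (tested); the raw
measurement grid can be used instead by setting the evaluation step.
Per-chemical scores sum the ABC over the concentration series. The
single-endpoint comparator |b(24) − a(24)| is computed alongside to
expose the false-negative mechanism: an early pulse that decays by 24 h
leaves no endpoint signal but a large ABC.

Per-replicate scores (replicate r's chemical curves against the pooled
control) provide both the trend-test groups and the replicate
distribution for effect sizes. How the replicate variance of a score
should be constructed is not standardized; this per-replicate
construction is the package's choice and is labelled as such.

### Dose–response and exposure planning

Viability is (Abs_sample − Abs_blank)/(Abs_vehicle − Abs_blank),
unclipped (the upper asymptote absorbs values above 1). The
four-parameter log-logistic model is fitted by least squares over a
fixed, deterministic multi-start grid (both slope signs, four slope
magnitudes, five inflection doses spanning the tested range; lowest SSE
wins), with the fit canonicalized to d ≥ c. The IC50 is the absolute
50%-viability crossing, solved by bracketed root finding on log dose to
10⁻⁶ relative tolerance; it coincides with the inflection dose e when
c = 0 and d = 1 but not otherwise, and is reported as not estimable
when the fitted curve never crosses 0.5 on the tested range. The
maximum exposure concentration is the IC50 when estimable, else the
solubility cap, flagged when the implied vehicle fraction exceeds 1%
(PBS) or 0.1% (DMSO).

### Classification statistics

* **Trend.** The Jonckheere–Terpstra statistic counts, over ordered
  group pairs, higher-concentration observations exceeding
  lower-concentration ones (ties ½), one-sided for an increasing
  trend at α = 0.001. For pooled n ≤ 8 the p-value is exact by full
  permutation enumeration; otherwise a normal approximation with
  tie-corrected variance is used. A fully tied sample is assigned
  p = 0.5 by convention. Note the normal approximation is *not*
  accurate to 0.01 p-units at n ≤ 8 (discrepancies up to ~0.17 at the
  smallest shapes) — that inaccuracy is the reason for the exact path.
* **ROC.** The AUC is the pair-concordance probability (ties ½),
  computed from midranks. Candidate cutpoints are the midpoints
  between adjacent distinct scores plus the two trivial rules; the
  operating threshold minimizes the Euclidean distance to the
  (FPR 0, TPR 1) corner, ties broken toward higher specificity.
  Youden-style alternatives were considered and rejected: the corner
  distance is the stated selection rule of the assay. The call rule is
  score ≥ threshold → positive (boundary counts positive).
* **Effect size.** Hedges' g against the threshold is the one-sample
  standardized difference J·(mean − threshold)/sd over replicate sums,
  with J = 1 − 3/(4(n − 1) − 1); g ≥ 0.2 marks a meaningful effect.

## The synthetic generator

The generator emulates the study conditions: 3 replicates per
condition, 0.5 h reads over 0–24 h, a 5-point 2× dilution series,
chemical at −1 h and stimulus at 0 h. Its mean model is

* background wells: L = B;
* vehicle wells: L_v(t) = B·(1 + A·g(t)), g(t) = (t/t_p)·e^{1−t/t_p},
  unit peak at t_p = 5 h (the observed 4–6 h peak);
* chemical wells: L_c(t) = L_v(t)·exp(δ(c)·w(t)), with Hill
  concentration dependence δ(c) = δ_max·c^h/(c^h + EC50^h) and a
  unit-peak profile w(t): sustained 1 − e^{−t/4} (ramp saturating by
  ~10 h) or transient (t/4)·e^{1−t/4} (pulse at 4 h), plus a constant
  profile as a testing hook.

Observed reads multiply the mean by exp(ε), ε ~ N(0, σ²) independent
per read, drawn in a fixed well order from one explicitly seeded
stream. Lognormal multiplicative noise (default σ = 0.1, a ~10%
reader CV) is an assumption; no noise law is implied by the instrument.

Because disruption is multiplicative on the log scale, the true log
fold change is exactly δ(c)·w(t), and the exact ABC at any
concentration is |δ(c)|·∫w dt, evaluated by fine quadrature
(`noiseless_abc_truth`). This makes end-to-end recovery testable: at
σ = 0 the pipeline's sum of ABC lands within ~2% of the exact value
(5% tolerance in the tests, covering spline and scaling bias), and the
error shrinks monotonically as σ drops through 0.1 → 0.02 → 0.

**Amplitude regime.** The default stimulus amplitude is A = 100-fold,
a strong reporter induction. This is not incidental: because the
min-max scale subtracts the pooled minimum *before* the vehicle ratio
is taken, the scaled ratio equals the raw fold change only where the
stimulated signal is well above baseline. At weak induction (A ≈ 1–10)
the subtraction distorts the log fold change severely — up to several
fold near the window edges — and the pipeline's ABC no longer tracks
the generator's truth. The distortion is a property of the
scale-then-ratio normalization itself, not of the generator; analyses
of weakly induced reporters with this normalization should be
interpreted with care.

**What the generator does not emulate:** plate-position and edge
effects, signal drift and substrate depletion, photobleaching,
well-to-well cross-talk, non-Hill concentration dependence, and
feedback dynamics that change disruption sign over time (as some real
non-developmental toxicants show). Passing recovery tests therefore
demonstrate correctness of the computation under the stated model, not
robustness to these real-data features.

## Calibration and validation results computed by the suite

The test suite and acceptance script recompute, from scratch: the
validation-panel AUCs (all-chemical, limb subset, replotted limb set)
and the operating threshold with its 18 calls; exact agreement of the
AUC implementation with brute-force pair counting and of the
trend-test exact path with full enumeration over every group shape with
pooled n ≤ 8; a trend-test type-I error of ≈ α over 1000 simulated
null chemicals; 4PL inflection-dose recovery within 10% at absorbance
noise 0.02; and the transient-pulse endpoint/ABC ratio (< 1%), the
quantitative form of the single-endpoint false negative.

## Known limitations

* The scaled-ratio distortion at weak induction, above.
* Replicate ABC values on one plate share a fitted control curve and a
  scaling; the trend test treats them as exchangeable across
  concentration groups, which holds under the null but induces mild
  positive correlation between group summaries.
* The ROC threshold is derived in-sample from the reference panel; no
  cross-validation or confidence intervals are provided, matching the
  assay's design stage.
* The Hedges' g construction against a fixed threshold treats the
  threshold as known, not estimated; its sampling variability is
  ignored.
* Problem sizes in the calibration studies (49-point grids, 1000 null
  replicates, 100 random ROC instances, enumeration to n ≤ 8) were
  chosen to estimate each quantity to well within its test tolerance.
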