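# Methods

This note documents the models, parameter choices and numerical
conventions behind wormloco, and what the synthetic generators do and
do not emulate.

## 1. Image pipeline

**Model.** A corral recording is a T×H×W grayscale stack (default
T = 120 frames at 1 Hz). The locomotion score is the fraction of the
analysis ROI visited by worm bodies over the recording, divided by the
group size. The pipeline is median background → absolute-difference
subtraction → maximum projection → IsoData threshold → foreground
count.

**Assumptions.** Worms are the only moving objects; the background
(agar, corral wall, illumination) is static over 2 minutes; each worm
occupies any given pixel in fewer than half the frames. Where that last
assumption fails (a worm parked for ≥ 50% of frames), the parked
footprint joins the median background and is *not* counted — which is
the intended semantics: the assay measures area covered while moving.
A fully static scene therefore scores 0 with a `no_foreground` flag,
and a constant ROI is reported the same way rather than erroring.

**Numerical conventions.**

- Median over an even frame count: mean of the two central order
  statistics.
- Subtraction uses |frame − background|, making the score invariant to
  intensity inversion (dark worms on bright agar or the reverse). This
  is asserted as a property test.
- IsoData: classic Ridler–Calvard iteration on a 256-bin histogram of
  ROI pixels, min–max rescaled. Start at the histogram midpoint;
  iterate t ← round((mean of bins ≤ t + mean of bins > t)/2) until the
  bin index is stable; if one side of the split is empty, step toward
  the populated side. The returned threshold is the stable bin's centre
  mapped back to the intensity scale; foreground is strictly greater
  than the threshold. Other intermeans dialects differ by less than one
  bin on bimodal images (cross-checked against scikit-image in the
  tests).
- Coordinates are 0-based pixels; rectangular ROI bounds are half-open;
  the ROI (the cropped corral) is the "total area" denominator.

## 2. Worm-video simulator

**Kinematics.** Each worm is a chain of `n_segments` points spanning
`body_length`. The tangent angle along the body follows a travelling
sine wave φ(u, t) = heading + A_eff·sin(2π(u/λ − f·t) + phase), the
discrete body integrating tail-ward from the head in equal arc-length
steps — the minimal generator of S-shaped crawling. The head advances
along its local tangent at the effective speed; headings reflect
specularly off the corral wall; a random heading drift (`turn_rate`)
adds exploration.

**Intoxication.** A factor i ∈ [0, 1] depresses speed by (1 − s·i) and
bend amplitude by (1 − a·i), defaults s = 0.7, a = 0.5: a fully
intoxicated worm still creeps with narrow bends rather than freezing.
The heading drift is scaled by the effective-speed ratio (turning
requires propulsion), so at s = a = 1 and i = 1 the worm is exactly
stationary — a useful degenerate case for tests.

**Rendering.** Frames are a flat background plus a linear illumination
ramp (to exercise the threshold's uneven-lighting robustness) plus
i.i.d. Gaussian noise; each centerline point is stamped as a filled
disk of radius body_width/2 at the chosen polarity and contrast, and
intensities are clipped to the 8- or 16-bit range. Everything is
deterministic given the seeds.

**Scales.** No camera geometry is implied by the assay description, so
all rendering scales are configuration. Defaults: 320×320 px image,
150 px corral radius, 40 px worms 5 px wide, crawl speed 5 px/s. These
were chosen so that a group of ~10 worms covers roughly 20–50% of the
corral in 2 minutes; with a much smaller corral the footprint union
saturates the ROI and the score stops discriminating intoxication
levels.

**Not emulated:** realistic biomechanics (proprioceptive feedback,
reversals and omega turns, wall-following), food effects, body-size
differences, shadows or reflections, camera vignetting beyond the
linear ramp, or any ethanol pharmacokinetics. Passing tests on this
generator show the *pipeline* behaves correctly on controlled scenes,
not that real recordings are free of segmentation pathologies.

## 3. Yoked trial-table generator

For each yoked pair in generation g:

- plate effect p ~ N(0, σ_plate), shared by the pair's two groups;
- baselines B_c, B_e ~ N(µ_g, σ_B);
- on-ethanol scores E_c = B_c·(r + p + ε) and
  E_e = B_e·(r + p + δ_g + ε′), with ε, ε′ ~ N(0, σ_res);
- scores truncated at 0 (truncation rate logged; a design that would
  truncate more than half of its scores is rejected as degenerate).

Noise is multiplicative on the baseline because the analysed quantity
is the ratio L = E/B: the normalised values are then exactly
r + p + ε (+ δ_g), and the yoked difference D = δ_g + (ε′ − ε). The
plate effect cancels identically in D — this is the mechanism that
makes yoked normalisation informative, and it is asserted as a test
(sd(D) = √2·σ_res regardless of σ_plate).

**Default conditions** (chronic paradigm): 32/27/38 pairs in F1/F2/F3,
r = 0.5, δ = 0 except δ_F3 = +0.07, σ_plate = 0.05,
σ_res = 0.1475/√2 so that sd(D) ≈ 0.1475 and the F3 effect size is
d ≈ 0.47 (medium). The intermittent preset uses 23/6/7 pairs,
δ_F3 = −0.133 and σ_res = 0.127/√2 (d ≈ 1.05, hypersensitivity
direction). Baseline means are 0.020/0.020/0.016 area-fraction units
(F3 lower, matching the direction of the generation effect) with
σ_B = 0.003 — small enough (> 5σ from zero) that baseline draws stay
positive, which downstream normalisation requires. Worm counts are
uniform on [8, 16].

## 4. Statistical layer

- **ANOVA:** fixed-effects OLS on raw scores with factors generation,
  lineage, condition and all interactions; Type III sums of squares
  with sum-to-zero contrasts by default (the pair counts are
  unbalanced), Type I behind a flag. Type III is inestimable with empty
  cells; those are listed in the error. Zero residual SS (noise-free
  inputs) is reported as an error rather than an infinite F. When the
  design cannot support the ANOVA at all (e.g. a single-generation
  imaged experiment), the report flags it and the per-generation tests
  still run.
- **Tukey HSD** on the generation main effect when it is significant
  (Tukey–Kramer for unequal n), verified in tests against a direct
  studentized-range computation.
- **t-tests:** two-sided paired t on (L_e, L_c) per generation and the
  equivalent one-sample t of D against 0; the identity (t, df, p equal
  to ≤ 1e-12) is asserted across two independent implementations.
  df = n − 1 throughout. Cohen's d is computed on the difference
  scores, d = mean(D)/sd(D), the convention that reproduces published
  paired-design effect sizes from their printed means and SDs.
- **Normality gate:** Shapiro–Wilk on each generation's D distribution
  at α = 0.05. Failures are warned about and recorded in the report
  flags; the analysis still runs and never silently switches to a
  nonparametric test. No multiple-testing correction is applied across
  the three generations' t-tests; the report records how many tests
  were run so readers can judge.
- Degenerate groups (all differences identical, n < 3) have their
  tests skipped with an explicit flag, never dropped silently.

## 5. Calibration checks and problem sizes

The acceptance layer re-derives, at run time: the effect sizes and t
statistics implied by published summary statistics; the dosing volume
(280 µL for 400 mM in 12 mL); the type-I error of the F3 one-sample t
under the null generator (2000 replicate experiments of 37 pairs,
expected 0.05 ± 0.02); its power at δ_F3 = 0.07, sd(D) ≈ 0.1475,
n = 37, compared against a 20 000-draw Monte-Carlo noncentral-t oracle
(agreement within 3 percentage points); and the mean percent area per
worm of fully rendered and scored videos at intoxication 0/0.5/1
(20 trials per level, strictly decreasing). These problem sizes keep a
complete run to a couple of minutes on one CPU while leaving Monte-
Carlo error well inside the stated tolerances.

## 6. Known limitations

- The worm simulator's disk-stamped bodies have no width taper or
  self-occlusion handling; overlapping worms merge into one blob
  (acceptable because the score counts area, not individuals).
- Type III ANOVA with sum contrasts is one convention among several
  for unbalanced factorials; Type II is not offered.
- The XLSX import assumes one row per (pair, lineage, condition)
  trial after column mapping; wide-format workbooks must be reshaped
  first.
- Blind-label coding hides lineage identity in intermediate CSVs only;
  the run log necessarily contains the unblinding key.
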