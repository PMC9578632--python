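# wormloco

Locomotion-based quantification of acute ethanol intoxication in
*Caenorhabditis elegans*, with the yoked-trial statistics used in
transgenerational inheritance experiments and a synthetic assay
simulator so the whole pipeline runs without any recordings.

## Who this is for

Labs that assay ethanol (or other depressant) sensitivity in worms by
video: groups of 8–16 animals are confined in copper corrals on an agar
plate and recorded for 2 minutes at 1 Hz, first at baseline and again
after 20 minutes on an ethanol-infused plate. Intoxicated worms crawl
slowly with flattened postures and therefore visit less of the corral.
The package converts each recording into a single locomotion score,
and converts a whole experiment — control-lineage and ethanol-lineage
groups yoked pairwise on shared plates across generations F1–F3 — into
a statistical report.

## The measurement

For one corral stack `I(t, y, x)` of T frames:

1. **Median background** `B(y,x) = median_t I(t,y,x)` — a pixel visited
   by a moving worm in fewer than half the frames keeps its background
   value.
2. **Subtraction** `D(t,y,x) = |I(t,y,x) − B(y,x)|` — polarity-agnostic,
   so worms darker or brighter than the agar both work.
3. **Maximum projection** `P(y,x) = max_t D(t,y,x)` — the union of
   everywhere a worm went.
4. **IsoData threshold** (Ridler–Calvard iterative intermeans on a
   256-bin histogram of ROI pixels): iterate
   `t ← (mean≤t + mean>t)/2` to its fixed point; robust to uneven
   illumination.
5. **Area covered per worm** `= #{P > t} / #ROI / n_worms` — the
   locomotion score. Lower on ethanol.

## The statistics

Per group, locomotion on ethanol is normalised to its own baseline,
`L = score_EtOH / score_baseline` (1 = no effect, < 1 = intoxication).
Per yoked pair, the **yoked difference** `D = L_etoh-line − L_control-line`
cancels plate-level variation; `D > 0` means relative resistance of the
ethanol lineage. The report contains a three-factor fixed-effects ANOVA
(generation × lineage × condition, all interactions, Type III SS with
sum-to-zero contrasts) on raw scores with Tukey HSD post hocs, a
Shapiro–Wilk normality gate on each generation's `D` distribution,
two-sided paired t-tests on `(L_e, L_c)` with the algebraically
identical one-sample t-test of `D` against 0, and Cohen's
`d = mean(D)/sd(D)`.

A dosing helper computes treatment-plate volumes: 400 mM in a 12 mL
agar plate requires `400 × 12 / 17.13 ≈ 280 µL` of pure ethanol
(17.13 M from density 0.789 g/mL and molar mass 46.07 g/mol).

## Worked example

Simulate a chronic-paradigm experiment (97 yoked pairs: 32/27/38 in
F1/F2/F3, a +0.07 lineage effect confined to F3) and analyse it:

```python
from wormloco import RunConfig, run_experiment
report, artifacts = run_experiment(
    RunConfig(mode="simulate", out_dir="demo", seed=7))
print(report.format_table())
```

```
Three-factor ANOVA on raw area-per-worm scores
term                                         F           p  Significant?
Generation                               63.75   1.445e-24  Yes
Lineage                                0.04552      0.8312  No
Condition                                 1296  6.742e-124  Yes
Generation:Lineage                      0.1063      0.8992  No
Generation:Condition                     14.01   1.349e-06  Yes
Lineage:Condition                        1.196      0.2747  No
Generation:Lineage:Condition              1.01      0.3652  No

Per-generation tests on normalised locomotion / yoked differences
generation    paired t  one-sample t           p   Cohen d  Significant?
F1               0.685         0.685      0.4984     0.121  No
F2             -0.6669       -0.6669      0.5107    -0.128  No
F3               3.325         3.325    0.002005     0.539  Yes
```

Reading the output: ethanol strongly depresses locomotion everywhere
(Condition), generations differ in raw locomotion (Generation), but the
lineage effect surfaces only after yoked normalisation — the F3 paired
test is significant (p = 0.002, medium effect d = 0.54) while F1 and F2
are not, the signature the generator was asked to produce. The paired-t
and one-sample-t columns are equal by construction.

The same analysis runs on real data: `wormloco score` turns a directory
of multi-page TIFF stacks plus a metadata CSV into a trial table, and
`wormloco analyze` accepts any trial CSV/XLSX (with an optional column
map for foreign headers). `wormloco dose`, `wormloco simulate` and
`wormloco run` cover the rest; see `wormloco --help`.

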