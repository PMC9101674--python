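# hingepoint

Threshold estimation for biomarker dose–response relationships, with
threshold-stratified survival analysis.

## The problem

How much circulating vitamin D is "enough"? Serum 25-hydroxyvitamin D
(25(OH)D) drives calcium absorption and suppresses parathyroid hormone
(PTH), but both responses saturate: below some 25(OH)D level calcium falls
and PTH rises, above it they plateau. Such sufficiency thresholds are
usually read off scatterplots by eye or imposed from consensus guidelines.
`hingepoint` estimates them from patient-level data, the way a
post-hoc analysis of a randomized vitamin D supplementation trial in
digestive-tract cancer patients would: estimate the threshold from the
biomarker curves, then ask whether the supplement's effect on relapse-free
survival (RFS) is confined to patients near or below that threshold.

The package is aimed at biostatisticians reproducing or extending this
style of analysis. Because patient-level trial data of this kind are
typically available only on request, `hingepoint` ships a calibrated
synthetic-cohort generator so the entire pipeline is testable end to end.

## What it computes

Three estimators of the same threshold, plus the downstream survival
analysis:

1. **LOWESS screening** (`hingepoint.smoothing`) — tricube-weighted local
   linear smoothing (bandwidth 0.8 by default) for visual assessment of
   whether the scatter looks piecewise linear.

2. **Hinge regression, a univariate MARS** (`hingepoint.mars`) — models the
   biomarker as an additive combination of hinge functions
   max(0, x − t) and max(0, t − x):

   * *forward pass*: greedily adds the mirrored hinge pair whose knot t
     most reduces the residual sum of squares, refitting all coefficients
     by least squares at each step (candidate knots: the observed 25(OH)D
     values);
   * *backward pass*: deletes terms one at a time, scoring each nested
     model by generalized cross-validation,
     GCV = RSS / (n·(1 − C/n)²) with C = #terms + 2·#knots;
   * *model-size selection*: 10-fold cross-validation repeated 100 times;
     the size with the smallest mean held-out RSS is refitted on all data.

   The fitted model's knots are the thresholds; segment slopes and plateau
   levels are read off the fitted function.

3. **Segmented regression** (`hingepoint.breakpoint`) — fits 26 ordinary
   least-squares lines to the data below each candidate cut (15–40 ng/mL
   in 1 ng/mL steps), selects the cut maximizing R², fits a second line to
   the remaining points, and reports the intersection of the two lines
   (with a bootstrap CI on its ordinate) as the threshold.

4. **Stratified survival** (`hingepoint.survival`) — Nelson–Aalen
   cumulative hazards, Kaplan–Meier RFS at 5 years, per-stratum Cox
   hazard ratios (Efron ties), and the three-covariate interaction model
   (arm, high-25(OH)D group, their product) whose product-term Wald p
   tests whether the treatment effect differs across strata.

The generator (`hingepoint.datagen`) draws arm-specific truncated-normal
25(OH)D levels, maps them through continuous piecewise-linear calcium and
PTH response curves with Gaussian residuals, and attaches exponential
relapse times with stratum-by-arm hazards and administrative censoring.
See `docs/methods.md` for every default and the reasoning behind it.

## Worked example

Simulate the default 357-patient cohort (143 placebo, 214 vitamin D) and
estimate thresholds:

```
$ hingepoint simulate --seed 1 --out cohort.csv
wrote 357 patients to cohort.csv
$ hingepoint thresholds cohort.csv --seed 1 --out report
calcium: hinges [15.9, 90.6] (R2=0.158); piecewise intersection 15.5
pth: hinges [35.1] (R2=0.129); piecewise intersection 14.5
```

The calcium model found its main hinge at 15.9 ng/mL — the level below
which fitted calcium declines — close to the generator's 17 ng/mL, with a
weak-signal second knot at the sparse upper edge of the data (single-cohort
fits scatter; the seed-replicated studies below average this out). The PTH
model put its hinge at 35.1 ng/mL against a generating value of 29; its
R² of 0.13 shows how little of the PTH variance the curve explains, which
is exactly why threshold estimates from one cohort carry several ng/mL of
uncertainty. `report/` contains the full bundle: LOWESS curves, the R²
profile over candidate cuts, fitted models as JSON, and the stratified
survival table, e.g.

```
$ hingepoint survival cohort.csv --threshold 17 --threshold 29
             stratum   n  n_events  rfs_placebo  rfs_vitamin_d  hr_treatment ...
         low (<= 17) 103        25        0.81          0.73          1.44
intermediate (17-29) 173        43        0.65          0.85          0.38
        high (>= 29)  81        26        0.64          0.70          0.81
```

(column subset shown): the simulated treatment effect is concentrated in
the intermediate stratum, mirroring the generator's hazard configuration
(hazard ratio 0.49 there, 1.0 elsewhere).

Everything is also available as a library:

```python
from hingepoint import datagen, fit_mars, extract_thresholds

cohort = datagen.simulate_cohort(datagen.default_cohort_spec(), seed=1)
model, cv = fit_mars(cohort["x25ohd_y1"], cohort["pth_y1"], seed=1)
print(model.hinges, model.segment_slopes)
```

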