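# Methods

This note documents the models behind `hingepoint`, the defaults and why
they were chosen, the numerical decisions, and the known limitations. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic cohort generator

The generator (`hingepoint.datagen`) emulates a two-arm randomized
vitamin D supplementation trial in post-surgical digestive-tract cancer
patients, at the published summary level. One record per patient: arm,
baseline and year-1 serum 25(OH)D (ng/mL), calcium (mg/dL), intact PTH
(pg/mL), relapse-free survival time (years) and event indicator.

**25(OH)D distributions.** Year-1 levels are truncated normals calibrated
to the published patient-characteristics table: placebo n=143 at
21.3 ± 9.7 ng/mL, vitamin D n=214 at 44.0 ± 17.3 ng/mL. Baseline levels
are not printed per arm; both arms use the placebo-like 21.3 ± 9.7, since
supplementation had not started at baseline (config-exposed). Draws below
a physiological floor (default 4 ng/mL) are redrawn, not clamped, so the
density stays continuous; the redraw raises the pooled year-1 mean by
about +0.6 ng/mL over the untruncated weighted mean of 34.9.

**Biomarker response curves.** Calcium and PTH at each timepoint are a
continuous piecewise-linear function of the concurrent 25(OH)D plus
Gaussian noise. Defaults follow the published fitted models:

| curve    | hinges (ng/mL) | segment slopes            | anchor        |
|----------|----------------|---------------------------|---------------|
| calcium  | 17, 47         | 0.04, 0, 0.006 mg/dL per ng/mL | (17, 9.3 mg/dL) |
| PTH      | 29             | −0.96, 0 pg/mL per ng/mL  | (29, 20.1 pg/mL) |

Residual standard deviations are not printed anywhere; the defaults
(calcium 0.4 mg/dL, PTH 17 pg/mL) reproduce the published model R² of
roughly 0.08 (calcium) and 0.14 (PTH) at the trial's sample size, which
the fitted R² values in the test runs confirm (≈0.05–0.25 across seeds).

**Treatment effect on calcium.** `treatment_calcium_shift` (an additive
offset on year-1 calcium for treated patients with deficient baselines)
defaults to **0.0**. The response curve already transmits the
supplementation effect: a treated patient starting at 25(OH)D ≤ 17 sits at
curve level ≈ 9.10 mg/dL at baseline and, after rising to the treated-arm
year-1 distribution, at ≈ 9.32 — a paired change of ≈ +0.22 mg/dL, which
is the published-scale +0.20. A nonzero default would double-count the
mechanism. The field remains for sensitivity studies.

**Survival.** Baseline 25(OH)D strata (bounds 17 and 29 ng/mL by default,
convention low = (−∞,17], intermediate = (17,29), high = [29,∞)) each get
an exponential relapse hazard λ = −ln(RFS₅)/5 in the placebo arm, scaled
by a stratum hazard ratio in the treated arm. Published values pin the
intermediate stratum (placebo 5-year RFS 0.71, HR 0.49); the low and high
strata are reported only as "no significant effect", so their defaults —
placebo RFS₅ 0.72 and 0.75, HR 1.0 — were chosen once for consistency
with the printed >17 ng/mL placebo RFS of 72% (a mix of the intermediate
and high strata). Censoring is administrative at 5.5 years minus a uniform
accrual offset over 1 year; the source trial does not describe its
censoring structure.

**Randomness.** One master seed; each patient consumes an independent
substream derived from (seed, patient_id), so cohorts are reproducible and
invariant to generation order. An optional `missing_y1_fraction` knocks
out the whole year-1 panel for a random subset, mimicking patients not
measured at year 1.

**What the generator does not emulate.** Baseline and year-1 25(OH)D are
drawn independently within arm (no within-patient tracking), so placebo
patients also show regression-to-the-mean in curve-linked biomarkers.
Because PTH is anchored at the fitted plateau of 20.1 pg/mL, simulated
marginal PTH means (~21–25 pg/mL) are far below the published marginal
means (~43–47 pg/mL) — the source reports both numbers, and they cannot
be reconciled by any curve-plus-noise model; the curve anchor was kept
because the threshold analysis estimates the curve, not the margin. No
cancer-site, stage, age or sex effects; exponential hazards (constant over
follow-up); a single composite relapse/death event. Passing recovery tests
therefore show that the estimators find piecewise-linear structure at
trial-like noise and sample size — not that real biomarker curves are
piecewise linear.

## LOWESS screening

Tricube kernel, local degree 1, zero robustifying iterations by default
(all overridable); the source analysis names only the bandwidth (0.8), so
kernel/degree/robustness follow the common defaults of the ecosystem it
used. Evaluation is at the sorted deduplicated observed x values (uniform
grid available for plotting). The local window is floored at 3 neighbours
so a local line is always determined; with that floor the smoother
reproduces an exact line at any bandwidth and n ≥ 3 (a property test).
LOWESS output is used qualitatively; no confidence bands.

## Hinge regression (univariate MARS)

**Basis and forward pass.** Mirrored hinge pairs max(0, x−t), max(0, t−x)
with candidate knots at all distinct observed x values except the two
extremes (an endpoint knot makes one mirror identically zero). No
minspan/endspan thinning: at n ≈ 357 every observed level is a legitimate
candidate, and the replicated studies showed the occasional edge knot does
not move the threshold summaries. The greedy step refits all coefficients
by least squares for every candidate (vectorized over candidates through
stacked normal equations with a ~1e−10 ridge for the scan only; the winner
is refitted exactly), stops at `max_terms` (default 6, i.e. three pairs)
or when the relative RSS improvement falls below 1e−8 of the total sum of
squares. Ties go to the smallest knot. Degree is fixed at 1 (one
predictor, additive).

**Backward pass and GCV.** Terms are deleted one at a time (the deletion
least increasing RSS), giving one model per size; each is scored by
GCV = RSS / (n(1 − C/n)²), C = n_coefficients + 2·n_knots (penalty
config-exposed). C ≥ n yields an infinite score rather than an error.

**Size selection.** 10-fold cross-validation, repeated (default 100;
ties in mean held-out RSS go to the smaller size). The selected size is
then refitted on all data with a search dedicated to that size: a fresh
forward pass capped at the size (rounded up to a whole pair, pruned down),
and an exact scan over all single bases when the selected size is 1. This
matters: taking the size-s model out of the full six-term expansion's
pruning sequence inherits knots optimized jointly for the large model, and
in replicated runs at PTH-like noise it shifted the recovered hinge by
about −4 ng/mL; the dedicated refit removes that bias (the brute-force
single-knot fit and the refitted model agree).

**Reading thresholds off the model.** `extract_thresholds` reports hinges,
per-segment slopes (exact derivatives of the fitted function) and segment
levels (fitted value at the segment midpoint within the data range). A
segment is classified as a plateau when |slope| < 0.1 in normalized units
(0.1 × y-range/x-range of the training data): under the default noise the
sampling sd of a fitted plateau slope is itself ≈ 0.08 normalized, so a
plateau must be read as "flat to within sampling noise"; a strict 0.01
would classify almost nothing as flat at this n. `primary_hinge` returns
the steep-to-flat transition (the hinge with the largest drop in absolute
slope), which is the sufficiency threshold in this application; the
plateau level is the widest flat segment beyond it.

**Display.** Hinges are reported to 0.1 ng/mL in text reports and rounded
to integers when used as stratification thresholds; full precision is kept
internally.

## Segmented regression

For candidate cuts 15–40 ng/mL in 1 ng/mL steps (26 candidates — the grid
is inclusive; the candidate count is logged), an OLS line is fitted to the
points with x ≤ cut; the cut maximizing R² wins, with ties (within 1e−9,
which occurs on noiseless data where every cut below the break gives
R² = 1) resolved to the **largest** tied cut, maximizing the data entering
the lower segment. Points exactly at the cut belong to the lower segment.
A second line is fitted to the remaining points, and the threshold is the
intersection of the two lines; near-parallel segments (slope difference
below 1e−8 relative) return a flagged no-intersection result instead of a
wild abscissa, as do intersections outside the observed range. The CI on
the intersection ordinate is a percentile bootstrap over patients (1000
resamples, seeded) with the selected cut held fixed — re-running the cut
search per resample would mix selection variability into a CI that
describes a fixed pair of lines. An optional upper-threshold search
(window 40–70 ng/mL by default) reuses the machinery on x ≥ candidate and
always carries a reliability flag (steep-segment slope significant and
intersection inside the data), because near-plateau segments intersect
unstably.

**Known bias.** On replicated PTH-like cohorts the R²-selected cut usually
lands above the true hinge (lower-segment R² keeps growing with range at
σ = 17 pg/mL), so the "steep" line is diluted by plateau points and the
intersection falls ~4 ng/mL below the generating hinge; the noiseless
procedure is exact. The hinge-regression stage does not share this bias,
which is a concrete reason to prefer it — the package's replication study
(`studies.intersection_recovery_study`, asserted in the test suite at the
±3 ng/mL recovery standard) documents the failure rather than hiding it.

## Survival analysis

Nelson–Aalen cumulative hazards (no smoothing; jumps dᵢ/nᵢ), Kaplan–Meier
RFS at a 5-year horizon (last value with a warning if follow-up ends
earlier), Cox proportional-hazards fits with Efron tie handling (the
implementation offers only Efron — lower bias than Breslow at ties — and
rejects other choices explicitly), Wald CIs on the log scale. Monotone
likelihood / separation is caught and returned as a flagged non-converged
fit. Strata on baseline 25(OH)D use the boundary convention above, which
reproduces the published "≤17", "18–28", "≥29" labels for integer
thresholds. The per-stratum treatment effect is reported from the
stratum-restricted fit; the three-covariate interaction model (arm, high
group, product) is fitted separately and its product-term Wald p reported
— both views are in the report because a reader may want either. RFS is
time to relapse or death, whichever first; the generator emits one
composite event, so no competing-risk machinery.

## Baseline statistics

Fisher's exact test for 2×2 categorical contrasts; two-sample t between
arms and paired t within arm for continuous variables (both reported,
labelled); zero-variance variables are reported as incomparable, not
fatal. Normality of t-based inference is checked by bootstrapping the
one-sample t statistic (default 1000 resamples) and inspecting the
replicates with a Shapiro–Wilk test and a QQ slope/intercept against the
standard normal. Levene's test (mean-centered) checks homogeneity of
variance. No multiple-testing correction anywhere, matching the analysis
style being reproduced (two-sided α = 0.05 throughout). Patients missing a
stage's inputs are excluded from that stage only, with counts logged.

## Replication studies and problem sizes

`hingepoint.studies` runs the package's reproducibility experiments, used
identically by the test suite and `scripts/acceptance.py`:

* **Hinge recovery** — 25 cohorts of 357 patients (seeds base..base+24),
  hinge model per cohort with 10-fold CV and 20 repetitions, medians over
  seeds of first/second hinge, primary hinge, pre-hinge slope magnitude,
  and plateau level. 20 repetitions (vs the single-fit default of 100) is
  the replication design: across 25 cohorts the size selection already
  averages 5000 fold-fits, and the medians are insensitive to the per-fit
  repetition count.
* **Intersection recovery** — segmented regression on the same 25 PTH
  cohorts; median intersection abscissa.
* **Calibration check** — pooled year-1 25(OH)D mean of one default cohort.
* **Survival recovery** — 2000 patients per arm from the intermediate
  stratum's hazard model; treated-arm Kaplan–Meier RFS at 5 years and the
  Cox hazard ratio.
* **Paired-change study** — 1000 treated patients with deficient baselines
  (the treated arm is oversampled five-fold and filtered); mean year-1
  minus baseline calcium.

## Limitations

* Threshold estimates at these signal-to-noise levels scatter by several
  ng/mL per cohort; only seed-replicated medians are stable. Single-cohort
  hinges (as in the README example) should be read with that uncertainty.
* The segmented-regression intersection is biased low at realistic noise
  (above); the hinge-regression threshold is the better estimator here.
* The calcium second hinge (slope change of 0.006 mg/dL per ng/mL) is a
  weak-signal quantity: many replicate fits select a one-hinge model, and
  second-hinge summaries are computed over the subset of fits that found
  two.
* Greedy forward selection is not exact on multi-kink noiseless data (the
  first knot compromises between kinks); it is near-interpolating
  (RSS < 1e−4 of TSS) with one extra pair available.
* The generator's independence of baseline and year-1 25(OH)D, its
  plateau-anchored PTH margin, and its constant hazards are simplifications
  (detailed above); conclusions about real cohorts require real data.
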