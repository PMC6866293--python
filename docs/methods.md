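# Methods

## The response model

The stimulus-locked BOLD excursion of a stimulation block is modeled as a
trapezoid in percent-signal-change units with four free parameters:
baseline `b` (%), amplitude `a` (%), plateau onset `t_peak` (s from block
onset) and baseline return `t_return` (s from block onset). The descending
edge is anchored at stimulus offset (`t_fall_start` = 20 s by default) and
is **not** fitted: time-to-baseline is defined relative to the end of the
stimulus, so the descent is referenced there. The rising edge is anchored
at block onset (t = 0): the measurement origin for time-to-peak is t = 0,
and fixing the rise onset there keeps the model identifiable with four
parameters on the 16 samples of a 48-s block. Reported metrics are
time-to-peak = `t_peak`, time-to-baseline = `t_return − t_fall_start`, and
amplitude = `a`.

## Fitting

For fixed breakpoints the model is linear in (b, a), so the fit profiles
them out: every candidate pair (`t_peak` ∈ (0, 20], `t_return` ∈ [20, 48]
on a 0.25 s grid — much finer than the 3 s sampling) gets its closed-form
least-squares (b, a) and SSE; the grid optimum is then refined by a
deterministic hierarchical zoom (local 21×21 rescans with the step shrunk
×8 per level, 8 levels, from the three best coarse cells, clipped to the
parameter box). The zoom was chosen over a simplex search because the SSE
surface is piecewise quadratic in the breakpoints and a simplex stalls on
the plateaus created by box clipping. The returned SSE is never worse than
any coarse-grid candidate, and a flat trapezoid is inside the model family,
so SSE never exceeds the total sum of squares of the de-meaned input.
Degenerate inputs: a constant series returns amplitude 0, baseline equal to
the constant, and the documented tie-break `t_peak` = smallest grid value,
`t_return` = stimulus offset. Candidates with `t_return = t_fall_start`
have an instantaneous descent (the profile is 0 immediately after the
plateau).

## Subject-level pipeline

* **GLM.** Task regressor = stimulus boxcar convolved with the canonical
  double-gamma HRF (gamma-density lobes of shape 6 and 16, unit scale,
  undershoot ratio 1/6; impulse peak ≈ 5 s), built on a 0.1 s grid, sampled
  at the volume times t = k·TR, mean-centered. Model columns: task,
  intercept, optionally discrete-cosine drift terms for a 48 s high-pass
  cutoff (off by default: the default generator plants no drift). No
  prewhitening and no temporal derivative — adequate for temporally
  independent noise; both are extensions, not defaults. The task t
  statistic (df = n − rank) maps to Z through the one-sided tail with sign
  preserved. Voxels with numerically zero residual variance get Z = 0 when
  the task beta is also ≈ 0, else a ±38 sentinel with a warning — never
  infinity.
* **ROI.** The top ceil(0.2·N) in-mask voxels by Z; ceil guarantees a
  non-empty ROI for any positive fraction; ties at the cut break by
  ascending linear voxel index for determinism.
* **Blocks.** The ROI-mean series is reshaped to blocks of
  (20 s + 28 s)/TR = 16 samples; the percent-change denominator is the
  grand mean over **all** blocks, computed once before rejection and never
  recomputed — discarding a spike block therefore still influences retained
  blocks through that denominator, a deliberate, tested coupling.
* **Rejection.** A block is discarded iff max |percent change| strictly
  exceeds 3% (a block peaking exactly at 3.0% is retained). The statistic
  is the within-block maximum of |·| — the natural spike detector; a
  mean-|·| variant is available via the `statistic` argument. If every
  block is discarded the subject is reported unfittable rather than
  silently dropped.

## Synthetic data

The subject generator plants
`baseline_level · (1 + trapezoid(t mod 48 s)/100)` in a chosen active-voxel
set (baseline_level 1000 arbitrary units), adds i.i.d. Gaussian noise per
voxel-timepoint and a single run-length cosine drift. Defaults for the
planted response — amplitude 1% of baseline, t_peak 6 s, t_return 28 s —
are physiologically plausible primary-visual-cortex values chosen to be
well inside the identifiable range; they are free parameters of the
simulation, not measured values. Real fMRI features deliberately absent:
temporal autocorrelation (AR noise), motion, spatial noise correlation and
smoothness, physiological (cardiac/respiratory) cycles. Passing recovery
tests therefore demonstrates correctness of the extraction chain, not
robustness to those artifacts.

The cohort generator draws, per subject: age, gender (Bernoulli),
education (normal truncated at ≥ 8 years), CAG repeat length (gene carriers
only), eight visual-cortex region thicknesses (group-specific means/SDs for
controls and premanifest/manifest HD, with mild age-related thinning,
−0.004 mm/yr), and five cognitive test raw scores across two domains (one
timed test with inverted orientation). Cognition is linked to the thickness
of an anchor region (lateral occipital) at 0.13 mm per domain-Z point, plus
small age and education effects and a latent residual (SD 1.5 Z) chosen so
the thickness–cognition partial η² lands in the 0.2–0.6 range typical of
such cohorts. Group sizes default to 18/21/20. Because the age effect on
thickness is linear and included in the ANCOVA, the planted
covariate-adjusted group difference equals the difference of group
thickness means by construction — which is what the coverage calibration
checks. All generators are pure functions of (spec, seed).

## Group statistics

Compound Z-scores standardize each test against the **control** group's
mean/SD (config-switchable to whole-sample standardization), flip timed
tests so higher = better, and average within domain; control-group domain
means are 0 by construction. ANCOVA contrasts fit OLS of the outcome on
non-reference group indicators + covariates; the indicator coefficient is
the adjusted difference with t-based 95% CI. Gender enters as a single
indicator. Association regressions restrict to gene carriers and report
the predictor's B, SE and partial η² = SS_pred/(SS_pred + SS_res) with
Type-III (drop-one) SS — for a single-df term equal to t²/(t² + df_res),
cross-checked against the drop-one oracle in tests. Covariate sets are
arguments, not constants, because different analyses legitimately use
different sets (age/gender vs age/gender/education vs + CAG). The
Bonferroni helper returns α/m and leaves the family size m to the caller.

## Problem sizes and determinism

Test and acceptance runs use deliberately small instances: 12×12×6 grids
(864 voxels) for end-to-end recovery, 10,000 voxels for null calibration,
2,000 cohorts of n = 20/group for CI coverage, 50 noisy blocks against an
exhaustive 0.05 s breakpoint-grid oracle. These sizes give stable Monte
Carlo estimates (binomial SE ≈ 0.2% at 10,000 draws, ≈ 0.5% at 2,000
cohorts) while keeping the whole suite fast. Every stochastic step takes an
explicit seed; the pipeline derives per-subject streams from one root seed
via `SeedSequence`, and identical config + seed reproduce numeric outputs
byte-for-byte (the manifest timestamp is excluded from that guarantee).
File writes are atomic (temp-then-rename).

## Known limitations

* The trapezoid is fit to the retained-block **average**, not jointly to
  all blocks; between-block variability is not propagated into the fit.
* The sentinel Z (±38) compresses all perfect-fit voxels to one value;
  rank-based ROI selection among them falls back to the index tie-break.
* The ANCOVA assumes homoscedastic Gaussian residuals; no robust/sandwich
  option is exposed.
* The 5.42 min scan duration sometimes quoted for such protocols is shorter
  than 7 × 48 s = 5.6 min; the generator exposes
  `n_discard_initial_volumes` to emulate discarded dummy volumes rather
  than guessing the cause.
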