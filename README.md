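# vasoreact

Vascular reactivity of the visual cortex from block-design task fMRI, plus
the cohort statistics that typically accompany it in clinical neuroimaging
studies of Huntington's disease (HD).

## What it does

In a block-design visual stimulation experiment (seven blocks of a 20 s
flickering checkerboard followed by 28 s of rest, one volume every
TR = 3 s), the BOLD response of the most stimulus-responsive cortex is a
roughly trapezoidal excursion in percent signal change. `vasoreact`
implements the full extraction chain:

1. **Subject-level GLM** — the stimulus boxcar convolved with a canonical
   double-gamma HRF is regressed voxelwise against the 4-D run; the task
   t statistic is mapped (sign-preserving) to a standard-normal **Z map**.
2. **Functional ROI** — the top 20% most activated voxels of that Z map.
3. **Percent-change blocks** — the ROI-mean series is cut into
   stimulus + rest blocks and expressed as 100·(x − m)/m with m the grand
   mean over all blocks; blocks whose |percent change| exceeds 3% are
   discarded as non-physiological.
4. **Trapezoid fit** — the retained-block average y(t) is fit by least
   squares with the piecewise-linear model

   ```
   f(t) = b + a·t/t_peak            0 ≤ t < t_peak
        = b + a                     t_peak ≤ t ≤ 20 s
        = b + a·(t_ret − t)/(t_ret − 20)   20 s < t < t_ret
        = b                         otherwise
   ```

   via profiled breakpoint search (closed-form b, a per candidate
   (t_peak, t_ret) on a 0.25 s grid, then a deterministic local zoom),
   yielding **time-to-peak** (t_peak), **time-to-baseline** (t_ret − 20 s)
   and **amplitude** (a, % signal change).
5. **Cohort statistics** — compound cognitive Z-scores (tests standardized
   against the control group, timed tests sign-flipped, averaged per
   domain), ANCOVA simple contrasts of each HD group vs controls with
   age/gender/education covariates, thickness–cognition regressions in gene
   carriers (B, SE, partial η²), and Bonferroni α adjustment.

Because no participant MRI data ship with the package, a first-class
synthetic module generates both levels of input: 4-D BOLD runs with a
planted trapezoid in a known voxel set (plus Gaussian noise and slow
drift), and cohort tables with group-dependent thickness and
thickness-linked cognition.

## Worked example

```python
from vasoreact import (StimulusParadigm, TrapezoidParams,
                       simulate_block_response, fit_trapezoid)

paradigm = StimulusParadigm()            # 7 × (20 s on + 28 s off), TR 3 s
planted  = TrapezoidParams(baseline=0.0, amplitude=1.0, t_peak=6.0, t_return=28.0)
series   = simulate_block_response(planted, paradigm, noise_sd=0.15, seed=42)
fit      = fit_trapezoid(series, paradigm)
print(fit.time_to_peak, fit.time_to_baseline, fit.amplitude)
```

prints

```
6.00 7.00 0.902
```

— the response reached its plateau 6.0 s after block onset (exactly the
planted value), returned to baseline 7.0 s after stimulus offset (planted
8.0 s) and rose 0.90% above baseline (planted 1.0%); the deviations are the
effect of 0.15% measurement noise on a single 16-sample block. The
`examples/` directory has one narrative script per capability, including the
full subject pipeline and the cohort statistics; a thin CLI (`vasoreact
simulate | fit-subject | group-stats | run-all | make-demo-config`) wraps
the same functions for shell use on NIfTI/CSV files.

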