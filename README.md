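# serialbias

Serial-dependence analysis for continuous direction-report experiments.

## The problem

In continuous report tasks, what an observer reports on one trial is biased by
what they saw on the previous trial — usually *toward* it (attractive serial
dependence), but in delayed pointing-direction estimation the bias can be
*repulsive*, and it can flip to attraction when a distracting task (a
color-word Stroop task) fills the memory delay. Measuring these biases cleanly
requires several non-standard steps, which this package implements as a tested,
reusable pipeline for researchers in visual psychophysics and working memory:

1. **Cardinal-anisotropy correction** (`serialbias.anisotropy`). Reports are
   attracted to or repelled from the cardinal directions, and response noise
   varies with distance to the nearest cardinal. Per participant, trials are
   binned into four 90° bins centered on cardinals or obliques (whichever fits
   better — repulsion puts a discontinuity at the cardinals that only
   oblique-centered bins can handle); a fourth-degree polynomial of
   distance-to-bin-center models the mean error and a quadratic of
   distance-to-nearest-cardinal models the SD. The predicted bias is removed,
   and responses beyond ±3 × local SD are flagged as outliers.

2. **The density-asymmetry statistic** (`serialbias.bias`). Errors are
   *toward-coded* (positive = toward the previous stimulus), and serial bias
   is the normalized imbalance of error mass on the two sides, in percent:

   `asymmetry = 100 · (m₊ − m₋) / (m₊ + m₋)`

   With unit weights this is exactly `100·(n₊ − n₋)/(n₊ + n₋)`: +100 means
   every error leaned toward the previous stimulus, −100 every error away.
   A rolling Gaussian kernel over dissimilarity |Δ| (the absolute circular
   difference between consecutive targets) yields a continuous bias curve.

3. **Response-locked trajectory surfaces** (`serialbias.trajectory`). The
   toward-coded deviation of the cursor's pointing angle is smoothed over
   time-to-response × dissimilarity (Gaussian kernels, SD 120 ms and 20°) on a
   90 × 90 grid, per participant, with per-cell one-sample t-tests across
   participants and 4-connected clusters of significant same-sign cells. The
   first-frame / last-frame sign analyses ask whether the very first recorded
   cursor sample already leans the way the trial will end.

4. **Group statistics** (`serialbias.stats`). Paired/one-sample t-tests with
   Cohen's d, Cousineau–Morey within-subject CIs, Stroop congruency
   contrasts, and the RT-vs-dissimilarity slope (two-stage per-participant
   OLS by default, optional linear mixed model).

5. **A synthetic-experiment generator** (`serialbias.simulate`) with known
   ground truth — dissimilarity-tuned serial bias (derivative-of-Gaussian
   profile) with per-subject amplitudes correlated across conditions, cardinal
   anisotropy, heteroscedastic response noise, swap errors and outliers,
   RT effects, Stroop congruency effects, and response trajectories with an
   early repulsive lobe decaying into the final report — so every analysis
   stage can be validated by parameter recovery.

`serialbias.pipeline.run_pipeline` chains all stages and writes a JSON report;
runs are byte-for-byte reproducible given a seed.

## Worked example

```python
import serialbias as sb

sim = sb.SimulationConfig(n_participants=8, n_trials_per_condition=192,
                          block_size=96, trajectory_sample_rate=40.0, seed=6)
report = sb.run_pipeline(sb.PipelineConfig(simulation=sim,
                                           out_dir="scratch/pipeline_demo"))
```

prints (in `summary.txt`):

```
bias[NoStroop]: mean -2.60% [-8.07, 2.87], t(7) = -1.12, p = 0.2984
bias[Stroop]: mean -1.70% [-9.77, 6.37], t(7) = -0.50, p = 0.6332
condition contrast: diff -0.90%, t(7) = -0.18, p = 0.8606, d = -0.06
surface[NoStroop]: support 1157 ms, strongest repulsion t = -39.55 at -910 ms / 47 deg
surface[Stroop]: support 1077 ms, strongest repulsion t = -35.35 at -750 ms / 103 deg, strongest attraction t = 2.75 at 0 ms / 0 deg
second frame repulsive: 45.82% (n = 1447)
RT slope: -1.127 ms/deg [-1.582, -0.673]
```

Reading this: the per-condition density asymmetries are small and (at this
demo scale of 8 participants) not individually significant; the trajectory
surfaces show the strong mid-response repulsion at intermediate dissimilarity
in both conditions, with a terminal attraction cluster right at the response
only in the Stroop condition; and report RT falls by about 1 ms per degree of
dissimilarity from the previous target. At the study scale the generator
defaults emulate (33 participants × 480 trials/condition), the group
asymmetries separate reliably by condition.

The `examples/` directory holds one narrative script per capability
(simulation, anisotropy correction, bias estimation, trajectory surfaces,
RT/Stroop statistics, full pipeline); each prints what it computes and what
the numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the analytic endpoints of the density-asymmetry statistic from
scratch: it draws a seed-dependent sample in which every toward-coded error is
positive (all errors toward the previous stimulus) and one in which every
error is negative, runs the package's `density_asymmetry` on each, and writes
the two values (the statistic's +100/−100 endpoints) as JSON.
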