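# Methods

This note documents the models and procedures implemented in `serialbias`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Conventions

All angles are degrees. Absolute directions live on [0, 360); signed circular
differences on (−180, 180], with −180 mapping to +180. The previous-minus-
current target difference is Δ = wrap(previous − current); *dissimilarity* is
|Δ| ∈ [0, 180]. A response error e = wrap(report − target) is **toward-coded**
as e · sign(Δ): positive always means the report leaned toward the previous
trial's direction. Trials with Δ = 0 have no toward/away direction and are
excluded, as are first trials of a block (no predecessor) and trials whose
predecessor was an outlier (the chain is broken, since the "previous stimulus"
context of such a trial is unreliable; the source analyses do not state a
chain rule, this is this package's choice).

## Anisotropy correction

Model: within each of four 90° direction bins, the mean error is a
fourth-degree polynomial of the signed distance to the bin center; the
response SD is a quadratic of the absolute distance to the nearest cardinal,
fitted to the SDs of 5°-wide distance bins and floored at 0.5° (the floor
keeps the predicted SD positive; predictions use numpy's scaled-domain
polynomial basis, so they are invariant to the basis choice). Two bin schemes
are fitted — centers on cardinals {0, 90, 180, 270} or on obliques
{45, 135, 225, 315} — because repulsion from cardinals makes the error profile
discontinuous *at* the cardinals (sign flips across them), which a polynomial
can only absorb if the discontinuity sits at bin edges, whereas attraction is
smooth at cardinals and is best centered there. The scheme with the higher
total Gaussian log-likelihood under the heteroscedastic SD model wins (both
schemes score the same trials, so the likelihoods are comparable); exact ties
break to the cardinal scheme. Fitting uses two passes: trials beyond ±3 ×
local SD after the first pass are excluded from the second and added back
afterward. The correction subtracts the predicted mean error from every trial;
trials whose corrected error exceeds ±3 × predicted local SD are flagged
outliers but never dropped (flags are sticky downstream). The "±3 × SE" phrase
in the source is read as ±3 × predicted local SD, consistent with the fitting
exclusion. Correction is always per participant, pooling that participant's
conditions: the anisotropy is a property of the observer, not of the task.

Numerical caveat: a quartic cannot represent arbitrary bin-interior structure;
for a sin(4θ) anisotropy the fit leaves a ≤ ~0.35° RMS systematic residual
(the Legendre P₅ component), which is well below the bias amplitudes the
correction targets. Preconditions: ≥ 25 trials per bin (configurable); an
empty or under-filled bin raises an error naming the bin.

## Density asymmetry

The statistic is computed on nonzero toward-coded errors as
100 · (m₊ − m₋)/(m₊ + m₋), where m± are the (optionally weighted) masses of
positive and negative errors. Exact zeros are dropped: they carry no
toward/away information, and counting or splitting them would shrink the
statistic's ±100 endpoints. The default estimator is the counting form (the
normalization reduces densities to sign masses, and the ±100 endpoints are
exact); a Gaussian-KDE variant (`method="kde"`, integrating the smoothed
density on each side of zero) is provided for sensitivity analyses only. Note
the counting form has binomial sampling noise — SD ≈ 100/√n percentage points
per estimate — which sets the precision floor for per-subject estimates.

The rolling version evaluates the same statistic at each dissimilarity grid
point d with Gaussian weights exp(−(|Δᵢ| − d)²/(2 · SD²)), default SD 20°,
grid 0–180° in 2° steps. Points whose kernel mass falls below a floor
(default 5 effective trials) are flagged unsupported rather than reported.
Pointwise group inference uses uncorrected one-sample t-tests across
participants at each grid point (α = .05), mirroring the per-step readout
style of the source analyses.

`mean_error_bias` (the arithmetic mean of toward-coded errors, in degrees) is
provided as the magnitude-sensitive companion measure.

## Trajectory analysis

Pointing angles are response-locked (t = 0 at the button press). Each sample's
toward-coded deviation is wrap(pointing − target − predicted anisotropy at the
target) · sign(Δ); the anisotropy prediction is the trial-level one, which
treats the anisotropy as constant within a trial. Per participant, the bias
surface on the 90 × 90 grid is the kernel-weighted mean deviation with
separable Gaussian kernels (time SD 120 ms, dissimilarity SD 20°), implemented
as two matrix products per participant. The time axis is truncated to the
latest onset at which **every** participant still has ≥ 20 trials of at least
that duration (the bound is recomputed from the data, never hard-coded, since
it reflects each dataset's RT distribution). Cells a participant cannot
support are NaN and excluded from the group mean and t-tests (nan-aware).
Group inference is a per-cell one-sample t-test (α = .05); significant
same-sign cells are grouped into 4-connected clusters, each reporting size and
peak |t| location. No cluster-mass or multiple-comparison correction is
applied — the thresholding is deliberately pointwise. Surfaces can be
expressed in degrees (mean toward-coded deviation, the default) or percent
(mean sign × 100, the surface analogue of the density asymmetry).

Frame-sign analyses reduce each trial to the signs of its first, second and
last recorded deviations. Zero-sign frames are excluded. The first-frame
analysis reports, per condition × final-frame-sign stratum, the
across-participant mean first-frame sign with a one-sample t-test, plus a
paired between-condition t-test on participants' overall mean first-frame
sign. The first-to-last coupling is tested with a two-stage stand-in for a
random-slope logistic GLMM: per-participant logistic regressions of
(last sign > 0) on first-frame sign, then a one-sample t-test of the slopes;
separated or non-converged fits contribute a capped slope (±10, logged) so
degenerate participants cannot dominate. This tests the same directional
hypothesis as the mixed model while staying dependency-light; the number of
capped fits is reported alongside the test.

## Group statistics

Paired contrasts report t, df = n − 1, two-sided p, Cohen's d = mean
difference / SD of differences, and a t-based CI. Within-subject CIs follow
Cousineau–Morey: subject-center the participants × conditions matrix, rescale
the centered variances by C/(C − 1), build CIs from the adjusted SEs (with
C = 1 the ordinary CI is used, with a log note). The RT model regresses RT
(ms) on dissimilarity (deg), a condition indicator and their interaction —
per participant by OLS, then one-sample t-tests of the coefficients across
participants (participants with < 10 valid trials are excluded and logged).
A Gaussian linear mixed model with a random intercept and dissimilarity slope
(`method="mixed"`, via statsmodels MixedLM) is the optional one-stage route;
both target the same fixed effects, and the Gaussian noise family is an
assumption (the source reports ms-scale coefficients only). Conditions enter
contrasts in sorted label order, so with the default labels the reported
difference is NoStroop − Stroop.

## Synthetic-data generator

The generator's defaults state the emulated world at the scale of the study:
33 participants, two within-subject conditions (Stroop / NoStroop) of
5 blocks × 96 trials, uniform targets on [0, 360).

* **Serial bias.** Toward-coded shift b(Δ) = a · (Δ/w) · exp(−(Δ/w)²), a
  derivative-of-Gaussian with tuning width w = 40° (peak at w/√2 ≈ 28°),
  the standard descriptive shape for dissimilarity-tuned serial biases. The
  per-subject amplitude pair is bivariate normal across conditions with
  correlation 0.7 and SD 3 percentage points — chosen so that the predicted
  mix of stable-attractive, stable-repulsive and sign-switching observers
  matches the reported individual-difference pattern — around condition means
  of +1.90 (Stroop) and −1.61 (NoStroop) percentage points. Amplitudes are
  specified in asymmetry percent by default and converted to DoG degrees by
  the small-bias linearization asym ≈ 100·√(2/π)·E[b(Δ)]·E[1/σ(θ)] (the
  conversion needs σ > 0; use `bias_amplitude_unit="degrees"` for noise-free
  worlds). The conversion is exact to ~1% at these effect sizes.
* **Anisotropy and noise.** Default cardinal bias is 5° · sin(4θ) (repulsive
  sign); the alternative `"local"` shape family — V-shaped
  sign(d)·exp(−|d|/τ) repulsion (discontinuous at cardinals) vs a smooth DoG
  attraction of the distance-to-cardinal d, τ = 30° — exists because both
  signs of sin(4θ) are exactly symmetric between the two bin schemes and
  therefore cannot exercise scheme selection. Response noise SD is 9° at the
  cardinals rising by 3° toward the obliques (cosine modulation; the oblique
  effect). Swap errors (report near the previous target, rate 1%) and uniform
  outliers (0.5%) contaminate the reports.
* **RT.** RT = 0.96 s − 0.88 ms/deg · |Δ| + 66 ms (NoStroop) + subject
  intercept (SD 0.15 s) + subject slope (SD 0.2 ms/deg) + Gaussian noise
  (SD 0.25 s), floored at 0.2 s. First-of-block trials use |Δ| = 90 (the
  uniform mean) so their RT is defined.
* **Stroop.** Congruent trials are 40 ms faster and 1.5 accuracy points
  better around a 92% mean; the NoStroop condition presses a fixed key, so
  its "accuracy" against the color is near chance (1/3).
* **Trajectories.** Sampled at 60 Hz (a deliberate simplification of real
  mouse polling rates, for tractable table sizes); the last sample always
  equals the report exactly. The toward-coded profile is
  w(t) · (early lobe + trial jitter) + (1 − w(t)) · final error, built around
  target + cardinal bias (the anisotropy shifts the whole path, not just the
  endpoint). The early lobe is repulsive, −6° deep, peaked at 80°
  dissimilarity; w(t) = min(1, −t/0.8 s)² decays quadratically so the
  terminal segment dominates the last ~200 ms, confining the endpoint bias
  near the response as in the reported surfaces. The first frame's deviation
  is noisy (SD 25°) with a sign that agrees with the trial's final bias sign
  with probability 0.61; on attractive-ending trials the second frame is
  forced repulsive with probability 0.4297. All draws flow from one seeded
  generator, so tables are byte-reproducible.

What the generator does **not** emulate: practice/fatigue dynamics, response
history (only stimulus history drives the bias), hardware-specific initial
cursor behavior, biases longer than one trial back, RT distributions' skew,
and any dependence of trajectory noise on speed or distance. A green
parameter-recovery test therefore establishes that the pipeline measures what
the generator injects at realistic scales and noise levels — not that real
data satisfy the generator's independence assumptions.

## Numerical and design notes

* Counting asymmetry per subject has sampling SD ≈ 100/√480 ≈ 4.6 points at
  the emulated scale; recovered cross-condition correlations of per-subject
  biases are therefore strongly attenuated relative to the injected amplitude
  correlation (attenuation factor s²/(s² + 4.6²) for true between-subject SD
  s). The package reports the raw correlation, not a disattenuated one.
* The pipeline asserts trial conservation (in = used + excluded) at every
  stage and logs the counts; anisotropy outliers are flagged, never dropped,
  and excluded trials also invalidate the following trial's pairing.
* Reports are JSON with sorted keys; identical seeds give byte-identical
  reports. Non-finite values serialize as null.
* Degenerate inputs: asymmetry of an empty/all-zero sample raises
  ("undefined asymmetry"); unsupported bias-curve or surface cells are
  flagged/NaN, not errors; a single participant yields an "undefined
  correlation" note rather than a value; logistic separation falls back to a
  capped slope.
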