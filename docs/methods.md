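# Methods

## Model

Cortical temperature is modelled as a first-order relaxation process driven
by the scored sleep–wake state. With one update per epoch (epoch duration
Δt, exactly `epoch_s/3600` hours; 4 s → 1/900 h),

- wake or REM sleep: `T(t) = U(t) − (U(t) − T(t−1)) · exp(−Δt/τ_WR)`,
- NREM sleep: `T(t) = L(t) + (T(t−1) − L(t)) · exp(−Δt/τ_N)`,

where `T0` is the temperature immediately preceding the first epoch. Wake
and REM sleep share one time constant: REM sleep is sparse (~6 % of
recording time), so a separate REM rate buys little and costs a parameter.
We deliberately use the exact Δt = 1/900 h rather than a rounded
0.0011 h — the rounding drifts by about 1 % over 96 h.

The NREM update is written as exponential decay *toward* L. A literal
transcription of the usual pair of printed equations with the same sign
pattern as the wake equation, `T(t) = L − (T(t−1) − L)·exp(−Δt/τ_N)`,
reflects T across L and diverges for T > L; the decay form implemented here
is the one consistent with temperature falling monotonically toward the
lower asymptote during NREM sleep, which is the defining behaviour of the
state. This is the single place where we corrected an equation rather than
transcribing it.

### Asymptote modulation

The asymptote pair `[L(t), U(t)]` is the homeostatically defended range.
Two factors shift both asymptotes in parallel (the inter-asymptote distance
`U_base − L_base` is therefore constant over the recording):

**Prior wake prevalence.** For epoch *t*, the fraction of wake+REM epochs
in the window `[t + shift − size, t + shift)` (hours; `shift = 0` means the
window ends at the preceding epoch, negative shifts push it into the past).
The fraction is centered on the whole-recording wake+REM fraction and
doubled, spanning [−1, +1], then multiplied by `pw_scale` — so the scale
parameter is the maximum possible modulation, reached at 100 % wakefulness
in the window. Window positions before the recording start are backfilled
with the mean of the two baseline days at the same clock offset; if the
recording is shorter than 48 h (synthetic short tests), the whole-recording
mean prevalence is used instead. Window positions beyond the recording end
cannot be known and contribute zero modulation.

**Circadian sinusoid.** `offset(ZT) = −A · sin(2π (ZT − P)/24)`, added to
both asymptotes. The sign and phase convention fixes the trough of the
offset at ZT (6 + P) for a recording starting at light onset, i.e. near the
light-period midpoint for phases near zero. The phase enters in hours; a
convention that mixes radian time with an hour-valued phase is not
well-defined, and this is the unique sine-with-hour-phase reading that
reproduces a trough at ZT 5.37 for P = −0.63 h with A = 0.19 °C.

Model 0 disables both factors; Model 1 enables the prevalence factor;
Model 2 enables both.

### Parameters

| parameter | units | default / init | meaning |
|---|---|---|---|
| `L_base`, `U_base` | °C | observed min/max (fit init) | asymptote bases; bounded to observed range ± 2 °C |
| `tau_wr`, `tau_n` | h | 0.47 (fit init), bounds [0.01, 5] | gap-closure time constants (~63 % per τ) |
| `pw_size` | h | grid 0–10, step 0.25 | prevalence window size (0 disables) |
| `pw_shift` | h | grid −5.0…+0.5, step 0.1 | window end relative to evaluated epoch |
| `pw_scale` | °C | init 1.0, bounds [0, 3] | max asymptote modulation at 100 % wake |
| `circ_amp` | °C | init 0.1, bounds [0, 1] | circadian amplitude (0 disables) |
| `circ_phase` | h | init 0, bounds [−12, 12] | trough at ZT (6 + phase) |
| `T0` | °C | mean of first 5 min | initial temperature; not a free parameter by default |

The bundled `median_params.yaml` carries the published across-animal median
optimized values (L 34.26, U 36.28, τ_WR 0.21, τ_N 0.11, window 3.0 h /
−1.4 h / 1.01 °C, circadian 0.19 °C / −0.63 h) for the prediction workflow.
Note that medians are taken per column: the median lower and upper
asymptotes come from different animals, so their difference (2.02 °C) is
not the median per-animal inter-asymptote difference (1.85 °C).

## Fitting

The window size and shift translate to integer epoch offsets and are not
differentiable, so they are searched by brute force; at each grid point all
continuous parameters of the chosen model variant are optimized
simultaneously with L-BFGS-B under box bounds (objective tolerance 1e−9),
minimizing the mean squared error over the entire recording — baseline,
sleep deprivation, and recovery. The choice of L-BFGS-B matches the
published procedure by contract (bounded local minimization from the stated
initial point), not by algorithm identity. Initial values the original
procedure does not specify (the prevalence scale, circadian amplitude and
phase) start at 1.0 °C, 0.1 °C, and 0 h: mid-range, scaled to the
physiological magnitudes of those effects. A warning is emitted whenever a
fitted parameter lands on a bound (a healthy fit should be interior), and
for (near-)constant temperature traces, whose asymptote fit is degenerate.

Grid ties (equal MSE within floating-point slack) resolve to the smaller
window size, then the shift closest to zero — the least-structured model
among equals. Inner fits are warm-started from the neighbouring grid
point's solution by default; this is an efficiency device only and is
asserted in the test suite not to change the winning grid point. `T0` is
fixed from the first 5 min of data; an `optimize_T0` flag exists for
sensitivity analysis. Two grid presets ship: `full_grid` (41 × 56 points,
the full published search space) and `coarse_grid`
(sizes {2.0, 2.5, 3.0, 3.5, 4.0} h × shifts {−2.0, −1.7, −1.4, −1.1,
−0.8} h), a 25-point grid bracketing the median window at 0.25-h/0.3-h
granularity, used for the test suite and quick exploratory fits.

## Evaluation

Fits are summarized by the epoch-level RMS error and the Pearson r between
simulation and data; correlations are averaged after Fisher (atanh)
transformation. Hourly residuals (simulation − data, per-animal hourly
means) are tested against zero per hour by two-sided paired t-tests across
animals with Benjamini–Hochberg FDR correction across hours at q < 0.05;
the residual RMS is the RMS of the across-animal mean hourly residual
vector. When prediction and data differ by a constant level offset (a
common electrode artefact), `mean_level_adjust` shifts the data to the
prediction's mean without changing scale.

### Variance decomposition

The full-model output is disassembled into three factor traces: the
circadian trace is the full simulation minus the simulation with
`circ_amp = 0`; the prevalence trace likewise with `pw_scale = 0`; the
sleep–wake trace is, by default, the simulation with both factors off (the
natural basic-model analogue). An alternative reading — full output minus
the two difference traces — is available via `sw_trace_mode="residual"`;
the factor split shifts by a few points between the readings, the model
total does not. Unique fractions are var(trace)/var(data) at 4-s resolution
about each trace's own mean; the pairwise share of factors *i, j* is
var(trace_i + trace_j)/var(data) minus both unique fractions (algebraically
2·cov/var, and possibly negative, as shared variance can be suppressive).
Because the model is nonlinear in its factors, the six unique/shared
components do not sum exactly to the full model's variance fraction; the
three-way remainder is reported as `interaction_remainder`, not silently
distributed.

## Prediction without temperature data

The forward model needs an initial value. For recordings that start at
light onset, the wake/REM "occurrence" in the first 7 minutes (exactly 105
four-second epochs) predicts the temperature level in that window; the
bundled regression `T0 = 0.92265 · occurrence + 34.3282` (r = 0.98, fitted
on recordings min–max normalized to 34–36 °C) converts occurrence to T0,
after which the bundled median parameter set drives the simulation.
`fit_T0_regression` re-derives the coefficients on any paired dataset
(pooled OLS of normalized window means on occurrences). The influence of
the T0 estimate decays exponentially — initial-condition error is bounded
by |ΔT0|·exp(−elapsed/τ_max) — so predictions depend on the state sequence
alone within a few time constants.

## Synthetic data

The generator emulates the features the model is sensitive to, not real
electrophysiology. States form a semi-Markov chain with geometric bout
lengths at epoch resolution: mean bouts of 8 min wake / 4 min NREM /
1.2 min REM in the light phase, wake doubled in the dark phase (decided by
the Zeitgeber time at bout onset); NREM bouts end into REM sleep with
probability 0.75, else wake; REM always returns to wake. These values give
a REM fraction near 6 % of recording time (≈7 % light, ≈4 % dark) and a
nocturnal wake pattern. The default protocol is 96 h with a sleep
deprivation block (forced wake) over hours 48–54, mirroring the standard
two-baseline-days + 6-h-SD + recovery design. Temperature is the forward
simulation of a known parameter set (the bundled medians by default) plus
i.i.d. Gaussian measurement noise, SD 0.1 °C.

What passing tests on this generator do and do not show: recovery of
generating parameters demonstrates the fitting machinery is correct and
well-identified under the model's own assumptions at realistic state
statistics and noise; it does not validate the model against biology, probe
model misspecification (bout-length memory, state-dependent noise,
electrode drift), or inter-animal variability — the generator produces one
"animal" per seed with exact model dynamics.

## Numerical choices

- The simulation kernel is a compiled (numba) per-epoch loop; a cumulative
  formulation of the linear recurrence underflows over 86,400 epochs, so
  the loop is the right primitive. The test suite cross-checks it against
  an independent naive Python loop to 1e−10 °C.
- Prevalence windows use half-open epoch index ranges
  `[t + shift − size, t + shift)`; sizes and shifts are converted to epochs
  by rounding, exact for the 0.25-h and 0.1-h grids at 4-s epochs.
- The circadian offset inside the optimizer is expanded on precomputed
  sin/cos tables of ZT (angle-difference identity), so phase updates cost
  O(n) multiplies, not transcendentals.
- Temperatures serialize at full (shortest round-tripping) precision in the
  library writers; the CLI writes 6 decimals for byte-stable outputs.
- Fitting rejects traces with NaNs rather than imputing: the intended data
  are contiguous, and silent imputation would bias the time constants.

## Problem sizes

The test suite fits 96-h recordings (86,400 epochs) over the 25-point
coarse grid across 5 seeds, the scale at which the fit is well-conditioned;
the full 41 × 56 published grid is available as `FitConfig.full_grid()`
and runs in roughly an hour per recording on one core.

## Known limitations

- Wakefulness is a uniform state: locomotion bursts, handling, or other
  arousal-intensity effects on temperature are not represented.
- Ambient temperature, nesting, and group housing are outside the model;
  parameters fitted at one ambient temperature should not be assumed to
  transfer.
- Body temperature is not brain temperature at sub-minute scales (e.g. it
  does not rise in REM sleep); the model targets cortical measurements.
- The T0 regression is valid only for recordings starting at light onset
  under 12:12 LD; a warning is emitted otherwise.
- Explained-variance fractions compare variances, not means: a prediction
  with a constant level offset can decompose well yet need
  `mean_level_adjust` for a sensible RMS error.
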