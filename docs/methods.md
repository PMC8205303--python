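# Methods

## Model and assumptions

The forecaster treats one-step changes of a continuous series as a
finite set of categories and predicts the next category with an averaged
one-dependence (super-parent) Bayes classifier. The assumptions this
rests on:

- **Near-stationarity of differences.** The level series may trend and
  cycle, but its first differences are assumed to concentrate on a
  modest set of recurring values (approximately normal around the local
  slope for sensor data). Differencing plus rounding is what makes a
  categorical classifier applicable to a continuous series.
- **Short memory.** The next difference depends on the last `L−1`
  differences. Regimes with longer memory than the window cannot be
  captured.
- **Recurrence.** Prediction quality comes from counting previously
  seen windows; genuinely novel dynamics receive only smoothing mass and
  fall back to the class prior structure.

For a window `x = (x_1 … x_d)`, `d = L−1`, every class `y` is scored as

    P(y | x) ∝ Σ_i P̂(y, x_i) Π_j P̂(x_j | y, x_i)

with the Laplace estimates given in the README. Two deliberate choices
differ from textbook AODE:

- The inner product runs over **all** `j`, including `j = i`. Standard
  AODE excludes the super-parent from its own product; this model keeps
  it, which multiplies each term by the monotone factor
  `(|D_{y,x_i}|+1)/(|D_{y,x_i}|+A)` — it slightly sharpens the weight of
  well-supported super-parents and leaves the argmax structure intact.
- There is no minimum-frequency floor on super-parents (standard AODE
  often requires ~30 occurrences); the class-level threshold γ is the
  only filter.

The per-position value-set sizes `N_i`, `N_j` are all set to the global
alphabet size `A`, because every window position draws from the same
difference alphabet.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `L` | window length; `L−1` attributes condition each prediction | 3 (CLI) | one previous step is often enough (differences are near-Markov); larger L costs O(d²) per score and dilutes counts |
| `γ` | minimum relative class frequency, strict `>` for retention | 0.0 | filtering is opt-in; 0.01–0.05 suppresses sensor-outlier categories |
| `decimals` | rounding precision of the difference symbols | 2 | 0.01 mg/L matches typical DO sensor resolution; finer precision explodes the alphabet, coarser collapses signal |
| `split_fraction` | chronological train share | 0.9 | the customary 90/10 walk-forward split |

γ is interpreted over class labels only: a rare symbol is removed as a
*prediction target* but remains usable as an attribute (Laplace
smoothing handles its sparse counts). Filtering frequencies are measured
once, on the operator's input set — applying the filter twice with the
same γ may legitimately remove more, and the single pass is the
documented contract.

## Numerical choices

- **Rounding.** Symbols are produced by correctly-rounded half-to-even
  decimal formatting, with −0.0 normalized to +0.0. This makes
  discretization idempotent and makes the JSON model file (symbols as
  fixed-precision decimal strings) round-trip bit-exactly.
- **Underflow.** Each super-parent term's product of `d` conditionals is
  accumulated in the log domain; terms are exponentiated through
  log-sum-exp before the outer sum (a pure log-domain form is impossible
  because terms are added). Windows of ~50 attributes stay well inside
  double range.
- **Ties.** Argmax ties are broken deterministically: larger training
  class frequency, then smaller |symbol|, then smaller signed value —
  preferring the better-supported, more conservative (smaller-move)
  prediction.
- **Score normalization.** Scores are reported normalized to a
  probability vector for readability; the argmax is invariant to it.
- **WIA.** `1 − Σ(O−P)²/Σ(|P−ō|+|O−ō|)²`, clamped to [0, 1] against
  ~1e−16 floating residue (the triangle inequality makes it nonnegative
  mathematically). A constant observed series matched exactly is defined
  as WIA = 1.
- **Window count.** A stride-1 window of length L over Z symbols yields
  the standard Z − L + 1 samples.
- **Reconstruction.** `forecast_t = predicted_diff_t + observed_level_t`:
  each prediction is anchored on the *observed* current level, so errors
  do not compound across steps.
- **Degenerate inputs.** NaN levels are rejected, never imputed — the
  pipeline's premise is that it needs no data-altering preprocessing.
  A γ that removes every sample raises an explicit empty-model error
  naming γ and the maximum class frequency. MAPE and percentage-loss DM
  refuse zero observations.

## Diebold–Mariano test

For one-step forecasts the loss differential `d_t = g(e_A,t) − g(e_B,t)`
(absolute or absolute-percentage loss) has truncation lag h−1 = 0, so the
long-run variance reduces to the plain sample variance (ddof = 1); the
statistic `d̄ / √(s²/n)` is referred to a standard normal, two-sided.
The Harvey–Leybourne–Newbold small-sample scaling with a t(n−1)
reference is available behind a flag and off by default. Degenerate
cases are defined explicitly: identical losses give statistic 0 and
p = 1; zero variance with a nonzero mean gives ±inf and p = 0. Null
calibration is verified empirically in the test suite (rejection rate at
α = 0.05 over 500 exchangeable-error replicates).

## Synthetic generator

`generate_sinusoidal` emulates a 5-minute coastal DO sensor:
`level_t = base + amplitude·sin(2πt/period) + W_t + S_t`, with `W_t` a
random walk whose N(0, noise_sd²) increments live on the difference
scale — so first differences are exactly Gaussian around the cycle's
slope — and `S_t` a mean-reverting spike process (±magnitude for a few
steps, then reversion) mimicking abrupt mutation events with stable data
on both sides. Defaults: base 8.0 mg/L, amplitude 1.5 mg/L, period 288
samples (one day), noise sd 0.02 mg/L, spike probability 0.002/step,
magnitude 1.0 mg/L, duration 6 steps. `quantize_decimals` optionally
rounds the emitted levels to the sensor's reporting resolution; a
quantized noise-free cyclical series is *exactly* learnable (held-out
MAE 0, WIA 1), which anchors the perfect-agreement end of the metrics.

`generate_markov_diffs` samples difference symbols from a known
first-order Markov chain; its Bayes-optimal one-step accuracy
`Σ_s π_s max_t P[s,t]` is computable from the transition matrix, giving
an absolute yardstick for the classifier's accuracy at `L = 2`.

What the generator does **not** emulate: temperature/salinity covariates,
sensor drift and recalibration jumps, missing records, tidal (multi-)
periodicities, and heavy-tailed noise. Passing tests on synthetic data
therefore demonstrate correctness of the machinery and recovery of known
structure, not field performance on real ranch records.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so a
full pass stays in seconds while estimates remain stable: 200 random toy
models for the oracle-equivalence check, 4000-point noisy series and
5000-symbol Markov chains for the pipeline experiments, 500 replicates
for DM null calibration.

## Known limitations

- Forecast horizon is one step; multi-step recursive forecasting is out
  of scope.
- Accuracy depends on alphabet compactness: steep cycles or coarse noise
  at fine `decimals` spread counts thin. Tune `decimals` to the sensor's
  resolution, not finer.
- The γ filter assumes outliers are *rare categories*; a persistent
  regime change will defeat it.
- Cold start: with few training samples the smoothed scores are close to
  uniform and predictions lean on the tie-break rules.
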