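# Methods

This note documents the models, defaults and numerical choices behind
`sleepderiv`, and what the synthetic protocol does and does not establish
about real recordings.

## The analysis in brief

The pipeline classifies 30-s epochs of an ultradian nap protocol as awake
or sleep from cardiac interbeat (RR) intervals.  Labels come from protocol
events, not from the signal: wake episodes (lights-on to lights-off) are
awake; a nap with no sleep onset is awake; from sleep onset to the next
lights-on everything is sleep, *including* spontaneous wake intrusions
(wake after sleep onset, WASO).  Features are the raw RRI and its discrete
first/second derivatives; a small MLP separates the two states; a KPSS
test documents why the second derivative is the useful companion feature:
it is level-stationary where the raw series is not.

## Synthetic protocol and physiology

The reference data (nine healthy adults, 72-h alternating 1-h wake / 1-h
nap protocol) are private, so the package ships a generator that emulates
the statistical structure the analysis relies on.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `duration_h` | 72 | protocol length (36 wake blocks + 36 naps) |
| `wake_block_min` / `nap_block_min` | 60 / 60 | ultradian block lengths |
| `rri_mean_awake` / `rri_mean_sleep` | 800 / 950 ms | state-dependent mean RRI |
| `rri_sd_awake` / `rri_sd_sleep` | 30 / 55 ms | stationary SD of the AR(1) noise |
| `ar_coeff` | 0.8 | lag-1 autocorrelation of the noise |
| `drift_amplitude_ms` / `drift_period_h` | 60 ms / 24 h | sinusoidal circadian drift |
| `sleep_latency_mean_min` | 10 | exponential latency to sleep onset per nap |
| `waso_fraction` | per profile (S07–S15) | expected post-onset wake fraction |
| `waso_bout_mean_min` | 3 | mean wake-bout length after onset |
| `missing_fraction` | 0.15 | proportion of time removed as dropouts |
| `rc_mean_awake` / `rc_mean_sleep` | 16 / 13 breaths/min | breathing-rate means |
| `rc_sd_awake` / `rc_sd_sleep` | 1.5 / 0.8 breaths/min | breathing-rate noise SDs |

The WASO fractions for profiles S07–S15 (0.090, 0.088, 0.075, 0.056,
0.082, 0.285, 0.238, 0.213, 0.220) reproduce the per-subject mean
percentages of wakefulness after sleep onset observed in the reference
cohort; every other physiological default is invented but chosen to sit in
the middle of adult norms (resting RRI 0.8 s awake vs 0.95 s asleep;
short-term HRV larger in sleep; breathing slower in sleep).  The RRI model
is deliberately the *simplest* process with the two properties the
analysis needs — state-dependent short-term variability and a slow drift
that breaks level stationarity — namely AR(1) noise around a state mean
plus a 24-h sinusoid, rather than a mechanistic cardiac
(integral-pulse-frequency-modulation) model.  Innovations are scaled by
`sqrt(1 - ar_coeff**2)` so the configured SDs are *stationary* SDs and the
lag-1 autocorrelation equals `ar_coeff` exactly.

Three details matter downstream:

* **Transition ramps.** State means switch through a ~60-s moving-average
  ramp.  Abrupt steps would inject large second-derivative spikes at every
  lights event — an artifact real physiology does not produce — and would
  hand the classifier an unrealistically easy cue.
* **WASO chain calibration.**  Post-onset wake intrusions follow a 2-state
  per-epoch Markov chain with mean wake-bout length `waso_bout_mean_min`.
  Because every nap starts the chain in sleep (the onset epoch), the
  finite-window wake fraction of a chain whose *stationary* fraction is f
  falls short of f.  The generator therefore solves, per nap, for the
  stationary fraction whose *expected finite-window* fraction equals the
  configured `waso_fraction`; the per-nap mean WASO percentage is then an
  unbiased estimate of the configured value (verified to within sampling
  error over 40 independent protocols).
* **Dropouts.**  Missing data are removed as contiguous blocks
  (exponential lengths, mean 5 min) until the removed time is within 1% of
  `missing_fraction`, mimicking recording problems rather than isolated
  beat artifacts.  Surviving beats flanking a gap carry a `gap_mask` flag,
  and no derivative stencil, KPSS segment or feature row ever spans a gap.

What the generator does **not** emulate: REM/NREM substructure, respiratory
sinus arrhythmia coupling between the RC and RRI channels, ectopic beats,
movement artifacts, or inter-subject differences beyond the WASO profile.
Passing tests on this generator demonstrate that the pipeline's operations
are correct and that the method's qualitative claims (stationarity
dichotomy, second-derivative accuracy gain, RRI/∇²RRI anticorrelation)
follow from the assumed physiology — not that the absolute accuracies
transfer to clinical recordings.

## Labeling conventions

Epochs are 30 s, anchored at the record start, half-open `[start, end)`.
The reference protocol does not state how epochs partially overlapping a
lights event were scored; here a boundary epoch takes the label covering
the strict majority of the epoch, ties resolving to awake.  Time before
the first event and any nap without an onset are awake (the protocol
default state).  `sleep_offset` events are validated and carried through
the format but unused by the labeling rule, which runs onset→lights-on.

## Derivatives

Both differentiators act sample-wise on the RRI sequence (unit index step
by default; a time-step mode using the local beat spacing exists but is
off by default, since the analysis treats the tachogram as an evenly
indexed sequence):

* Gregory–Newton (forward), second-order truncation:
  `d1[i] = (Δx_i − Δ²x_i/2)/h`, `d2[i] = (Δ²x_i − Δ³x_i)/h²`.  Trailing
  points fall back to the highest-order stencil that fits; the final
  points with no forward neighbor are NaN.
* Central: `d1[i] = (x[i+1] − x[i−1])/2h`, `d2[i] = (x[i+1] − 2x[i] +
  x[i−1])/h²`, endpoints NaN.

Feature rows are restricted to beats where the chosen method's full
stencil fits inside one gap-free segment, so the derivative columns of an
ablation arm are never one-sided estimates.  On noisy series the forward
GN stencil's statistical center sits one sample ahead of the central
stencil's; `derivative_method_agreement()` aligns the two on their
stencil centers before correlating.  Under the default AR(1) physiology
the two second-derivative estimates correlate at ≈0.94 (→ 1 as the signal
gets smoother); same-index comparison would be misleadingly low.

Min–max normalization bounds are always fitted on the training split only
and reused (with clipping) on validation/test — the conventional
anti-leakage choice, made explicit because near-unit-range features
otherwise silently leak test extrema into training.

## KPSS level-stationarity test

The statistic is `eta = n^-2 Σ S_t² / s²(l)` with `S_t` the partial sums
of the demeaned series and `s²(l)` the Bartlett long-run variance with
weights `1 − j/(l+1)`.  Only the constant-mean (level) variant is
implemented; the analysis never poses a trend-stationary null.  Default
bandwidth is the short rule `l = floor(4 (n/100)^0.25)`, overridable.
p-values interpolate the standard asymptotic critical-value table
{10%: 0.347, 5%: 0.463, 2.5%: 0.574, 1%: 0.739} and clamp to its range,
so strong rejections print 0.01 and comfortable non-rejections print 0.1 —
the conventional reporting for this table.  The implementation matches an
independent reference to ~1e-15 at matched lags, has nominal 5% size on
white noise, and essentially unit power against random walks at n = 1000.

## Classifier and ablation

The MLP has 3 hidden layers × 8 ReLU units and a logistic output, trained
with Adam at constant learning rate 0.01 on binary cross-entropy.  (The
reference description is internally inconsistent about depth — five hidden
layers in one place, three-by-eight in the experiments section; the
experiment configuration wins, and both are configurable.)  Epochs (50)
and batch size (256) are this package's choices, exposed in `MLPConfig`.
By default training runs all epochs in one optimized pass and records the
training loss per epoch plus the final validation loss; `val_curve=True`
drives the epochs mini-batch by mini-batch to record the validation loss
after every epoch (several times slower, same model family).  Training is
deterministic given the config seed and a fixed thread count.

Splits are 70/5/25.  `sample` mode shuffles beats — the conventional
protocol, which allows beats from one session on both sides of the split —
while `grouped` mode assigns whole 30-min windows to one split and is the
leakage-safe comparison.  Both are reported; the ablation's claim is the
*ordering* of arms, not absolute accuracy.  Metrics are accuracy and
class-frequency-weighted precision/recall/F1 (macro available), computed
from the package's own confusion-matrix arithmetic and cross-checked
against scikit-learn in the tests.  The classification threshold is fixed
at 0.5; an optional per-window majority vote smooths predictions before
scoring.

The four arms are RC, RRI, RRI+∇RRI and RRI+∇²RRI, run on identical
splits per seed.  Whether the reference analysis fed the network per-beat
pairs or flattened 30-min vectors is ambiguous; the default here is
per-beat classification with the 30-min window available for grouping and
vote smoothing, which keeps every arm's sample count identical and makes
the ablation a controlled comparison.

## Problem sizes

Defaults used by the test suite and the acceptance script: ten 72-h
recordings (~2.6×10⁵ beats each) for the stationarity dichotomy; 420 h of
protocol (≥200 naps with onset) per profile for WASO recovery; a 12-h
recording (~4×10⁴ beats) and ten seeds for the ablation; 200 series of
n = 1000 for KPSS size/power.  These sizes give the statistical checks
comfortable resolution while keeping a full run in the low minutes on a
single CPU.

## Known limitations

* The simulator's Gaussian AR(1) noise underestimates the heavy tails and
  nonstationarity-within-state of real HRV; absolute classifier
  accuracies on synthetic data (low-to-mid 90s) exceed what the method
  achieves on real cohorts.
* KPSS p-values are table-clamped to [0.01, 0.1]; they are reporting
  conventions, not exact tail probabilities.
* The per-nap WASO calibration corrects the finite-window mean; higher
  moments (per-nap SD) are whatever the two-state chain implies and were
  not matched to cohort values.
* No frequency-domain HRV features, no multi-stage sleep scoring, no
  R-peak detection: the pipeline starts from a clean RRI series.
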