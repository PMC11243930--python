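# sleepderiv

Sleep/wake detection from RR-interval (RRI) series using finite-difference
derivative features.

The autonomic nervous system leaves a strong fingerprint in beat-to-beat
heart timing: during sleep, parasympathetic dominance makes RR intervals
longer and more variable; during wakefulness, sympathetic tone shortens
them.  A single-sensor ECG therefore carries enough information to tell
whether a subject is awake or napping.  The raw RRI sequence, however, is
non-stationary — its mean drifts with circadian phase — which hurts
statistical classifiers.  The second discrete derivative of the RRI
sequence, ∇²RRI, removes the slow trend (it is level-stationary by the
KPSS test where the raw series is not) while retaining the state-dependent
short-term variability, so feeding (RRI, ∇²RRI) to a small feed-forward
network improves sleep/wake accuracy over RRI alone.

`sleepderiv` is a tested, reusable implementation of that analysis for
researchers working with interbeat-interval recordings from ultradian
nap protocols:

* **simulator** (`sleepderiv.simulate`) — a 72-h alternating 1-h wake /
  1-h nap protocol with sleep-state-dependent AR(1) RRI physiology,
  circadian drift, per-subject wake-after-sleep-onset (WASO) profiles
  S07–S15, breathing rate, and ~15% contiguous recording dropouts.  The
  reference cohort is private, so every downstream stage is exercised on
  this generator.
* **labeling** (`sleepderiv.labeling`) — event-log driven awake/sleep
  epoch labels (lights_on/lights_off/sleep_onset/sleep_offset; everything
  from sleep onset to the next lights-on is "sleep", wake intrusions
  included) and per-nap WASO statistics.
* **derivatives** (`sleepderiv.derivatives`) — Gregory–Newton
  (forward-difference) and central (Taylor) first/second derivatives,
  min–max normalization, and gap-aware per-beat feature assembly with
  30-min windows.
* **stationarity** (`sleepderiv.stationarity`) — a from-scratch KPSS
  level-stationarity test (Bartlett-kernel long-run variance, p-value
  interpolated in the standard critical-value table and clamped to
  [0.01, 0.1]).
* **experiment** (`sleepderiv.experiment`) — a 3×8 ReLU MLP with sigmoid
  output trained by Adam (lr 0.01, binary cross-entropy) on a 70/5/25
  split, and the four-arm feature ablation {RC, RRI, RRI+∇RRI, RRI+∇²RRI}.
* **report** (`sleepderiv.report`) — per-state summary tables and the
  pairwise correlation matrix behind the usual exploratory plots.

## Worked example

```python
import sleepderiv as sd

cfg = sd.profile_config("S10", duration_h=12.0, seed=7)
rec = sd.simulate_recording(cfg)                      # events, states, beats, resp
labels = sd.label_epochs(rec.events, rec.states.span)
beats, beat_labels = sd.attach_labels(rec.beats, labels)

print(sd.stationarity_report({"S10": rec.beats}).round(3))
rep = sd.run_ablation(beats, beat_labels, rec.resp, seeds=(0, 1, 2))
print(rep.summary().round(2))
```

Output:

```
subject series     n  lags  statistic  p_value
    S10    RRI 10332    12      7.473     0.01
    S10  d2RRI 10330    12      0.001     0.10

           accuracy  precision  recall     f1
arm
RC            89.17      89.28   89.17  89.20
RRI           93.58      93.69   93.58  93.52
RRI+dRRI      93.98      94.05   93.98  93.94
RRI+d2RRI     95.04      95.08   95.04  95.01
```

Reading it: on the longest gap-free stretch (10 332 beats) the raw RRI
series rejects level stationarity (KPSS statistic 7.47, p at the table's
lower clamp 0.01) while its second derivative is comfortably stationary
(0.001, p at the upper clamp 0.1).  In the ablation, adding ∇²RRI to the
raw RRI raises mean test accuracy by ≈1.5 points over RRI alone, and the
first derivative helps less — the same ordering the method predicts.
Absolute accuracies depend on the simulator's idealized physiology and
should not be compared with clinical numbers.

The same pipeline is scriptable from a shell:

```bash
sleepderiv simulate --profile S10 --hours 72 --seed 7 --out rec/
sleepderiv label --events rec/events.csv --beats rec/beats.csv --out labels.csv
sleepderiv features --beats rec/beats.csv --labels labels.csv --set rri,d2rri --out features.csv
sleepderiv kpss --beats rec/beats.csv --subject S10 --out kpss.csv
sleepderiv ablate --profile S10 --seeds 0..9 --out ablation.json
```

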