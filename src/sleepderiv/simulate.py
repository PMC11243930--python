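"""Synthetic ultradian sleep-protocol generator.

Emulates a 72-h laboratory protocol of alternating 1-h wake episodes and
1-h nap opportunities, producing the four artifacts every downstream stage
needs: an event log, a ground-truth 30-s state sequence, a beat-by-beat
RR-interval series, and a breathing-rate series.

The RR-interval model is an AR(1) process around a state-dependent mean with
a slow sinusoidal circadian drift:

    rri_i = mu_state(t_i) + A * sin(2*pi*t_i / P) + e_i,
    e_i   = phi * e_{i-1} + innovation,   innovation ~ N(0, sd_state * sqrt(1 - phi^2))

so that ``sd_state`` is the stationary short-term SD of the noise and the
lag-1 autocorrelation equals ``phi``.  Sleep RRIs are longer and more
variable than wake RRIs by construction, mirroring the parasympathetic
dominance of sleep, and the drift term makes the raw series level
non-stationary.  State-mean transitions are smoothed with a ~60-s moving
average so that state changes do not inject artificial derivative spikes.

Wake intrusions after sleep onset (WASO) follow a two-state epoch-level
Markov chain calibrated so the long-run post-onset wake fraction equals
``waso_fraction``; per-subject fractions for profiles S07–S15 come from the
reference cohort's observed WASO percentages.  Recording dropouts are
injected as contiguous multi-minute blocks totalling ``missing_fraction``
of the record.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .series import (
    EPOCH_S,
    SLEEP,
    WAKE,
    BeatSeries,
    EventLog,
    RespSeries,
    StateSequence,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimRecording",
    "GenerationError",
    "PROFILES",
    "profile_config",
    "generate_protocol",
    "generate_rri",
    "generate_rc",
    "inject_missing",
    "simulate_recording",
]


class GenerationError(RuntimeError):
    """Simulation parameters produced a physically impossible signal."""


#: Observed mean post-onset wakefulness fraction per subject profile.
PROFILES: dict[str, float] = {
    "S07": 0.090,
    "S08": 0.088,
    "S09": 0.075,
    "S10": 0.056,
    "S11": 0.082,
    "S12": 0.285,
    "S13": 0.238,
    "S14": 0.213,
    "S15": 0.220,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated protocol and physiology.

    Durations are positive; fractions lie in [0, 1); RRI means/SDs must be
    physiologically plausible (300–2000 ms, SD < mean).
    """

    duration_h: float = 72.0
    wake_block_min: float = 60.0
    nap_block_min: float = 60.0
    rri_mean_awake: float = 800.0
    rri_mean_sleep: float = 950.0
    rri_sd_awake: float = 30.0
    rri_sd_sleep: float = 55.0
    ar_coeff: float = 0.8
    drift_amplitude_ms: float = 60.0
    drift_period_h: float = 24.0
    sleep_latency_mean_min: float = 10.0
    waso_fraction: float = PROFILES["S10"]
    waso_bout_mean_min: float = 3.0
    missing_fraction: float = 0.15
    rc_mean_awake: float = 16.0
    rc_mean_sleep: float = 13.0
    rc_sd_awake: float = 1.5
    rc_sd_sleep: float = 0.8
    subject_id: str = "S10"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_h", "wake_block_min", "nap_block_min", "drift_period_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 <= self.waso_fraction < 1):
            raise ValidationError("waso_fraction must lie in [0, 1)")
        if not (0 <= self.missing_fraction < 1):
            raise ValidationError("missing_fraction must lie in [0, 1)")
        if self.sleep_latency_mean_min < 0:
            raise ValidationError("sleep_latency_mean_min must be non-negative")
        if self.waso_bout_mean_min <= 0:
            raise ValidationError("waso_bout_mean_min must be positive")
        if not (-1 < self.ar_coeff < 1):
            raise ValidationError("ar_coeff must lie in (-1, 1)")
        for name in ("rri_mean_awake", "rri_mean_sleep"):
            mean = getattr(self, name)
            if not (300.0 <= mean <= 2000.0):
                raise ValidationError(f"{name}={mean} outside physiological 300–2000 ms")
        for sd_name, mean_name in (
            ("rri_sd_awake", "rri_mean_awake"),
            ("rri_sd_sleep", "rri_mean_sleep"),
        ):
            sd, mean = getattr(self, sd_name), getattr(self, mean_name)
            if sd < 0 or sd >= mean:
                raise ValidationError(f"{sd_name} must satisfy 0 <= SD < mean")
        for name in ("rc_mean_awake", "rc_mean_sleep"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def profile_config(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` for one of the subject profiles S07–S15."""
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    kwargs = {"waso_fraction": PROFILES[name], "subject_id": name}
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


def generate_protocol(
    config: SimConfig, seed: int | None = None
) -> tuple[EventLog, StateSequence]:
    """Simulate the alternating wake/nap protocol.

    Returns the event log (lights events plus per-nap sleep_onset /
    sleep_offset when sleep occurred) and the 30-s ground-truth state
    sequence consistent with it.  Sleep latency within each nap is
    exponential with mean ``sleep_latency_mean_min`` (a nap whose latency
    exceeds the block has no onset); post-onset wake intrusions follow an
    epoch-level Markov chain with mean wake-bout length
    ``waso_bout_mean_min``, calibrated per nap so the expected post-onset
    wake fraction equals ``waso_fraction``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total_s = config.duration_h * 3600.0
    n_epochs = int(round(total_s / EPOCH_S))
    if not math.isclose(n_epochs * EPOCH_S, total_s, rel_tol=0, abs_tol=1e-6):
        raise ValidationError("duration_h must be a whole number of 30-s epochs")
    starts = EPOCH_S * np.arange(n_epochs)
    state = np.full(n_epochs, WAKE, dtype=object)

    # block schedule: wake first, then alternating naps
    records: list[tuple[float, str]] = []
    t = 0.0
    is_wake = True
    blocks: list[tuple[float, float, bool]] = []
    while t < total_s - 1e-9:
        length = (config.wake_block_min if is_wake else config.nap_block_min) * 60.0
        end = min(t + length, total_s)
        blocks.append((t, end, is_wake))
        records.append((t, "lights_on" if is_wake else "lights_off"))
        t = end
        is_wake = not is_wake
    if not blocks[-1][2]:
        records.append((total_s, "lights_on"))  # close the final nap

    f = config.waso_fraction
    wake_run_epochs = config.waso_bout_mean_min * 60.0 / EPOCH_S
    p_ws = min(1.0, 1.0 / wake_run_epochs)  # wake -> sleep per epoch

    def chain_probs(m: int) -> tuple[float, float]:
        """Per-epoch transition probabilities for an m-epoch post-onset span.

        The chain starts in sleep (the onset epoch), so over a finite span
        its expected wake fraction falls short of the stationary fraction;
        solve for the stationary fraction f* whose expected finite-span
        fraction equals the configured waso_fraction.
        """
        if f == 0:
            return 0.0, p_ws
        fstar = f
        for _ in range(50):
            p_sw = min(1.0, fstar * p_ws / (1.0 - fstar))
            rho = 1.0 - p_sw - p_ws
            if abs(1.0 - rho) < 1e-12 or m <= 1:
                break
            bias = 1.0 - (1.0 - rho**m) / (m * (1.0 - rho))
            if bias <= 1e-9:
                fstar = 0.95
                break
            new = min(0.95, f / bias)
            if abs(new - fstar) < 1e-12:
                fstar = new
                break
            fstar = new
        return min(1.0, fstar * p_ws / (1.0 - fstar)), p_ws

    for a, b, wake_block in blocks:
        if wake_block:
            continue
        latency_s = rng.exponential(config.sleep_latency_mean_min * 60.0)
        onset = a + EPOCH_S * math.ceil(latency_s / EPOCH_S)
        if onset >= b - 1e-9:
            continue  # no sleep this nap
        records.append((onset, "sleep_onset"))
        i0 = int(round((onset - starts[0]) / EPOCH_S))
        i1 = int(round((min(b, total_s) - starts[0]) / EPOCH_S))
        p_sw, p_ws = chain_probs(i1 - i0)
        asleep = True  # onset is by definition the first sleep epoch
        last_sleep_end = onset + EPOCH_S
        state[i0] = SLEEP
        for i in range(i0 + 1, i1):
            u = rng.random()
            if asleep:
                asleep = u >= p_sw
            else:
                asleep = u < p_ws
            if asleep:
                state[i] = SLEEP
                last_sleep_end = starts[i] + EPOCH_S
        records.append((last_sleep_end, "sleep_offset"))

    events = EventLog.from_records(records)
    states = StateSequence(starts, state)
    events.validate()
    states.validate()
    return events, states


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def _smoothed_per_second(
    states: StateSequence, wake_value: float, sleep_value: float, ramp_s: int = 60
) -> np.ndarray:
    """State-dependent value per second, smoothed by a ~60-s moving average."""
    per_epoch = np.where(states.state == SLEEP, sleep_value, wake_value).astype(float)
    per_sec = np.repeat(per_epoch, int(states.epoch_s))
    if ramp_s <= 1:
        return per_sec
    pad = ramp_s // 2
    padded = np.pad(per_sec, pad, mode="edge")
    kernel = np.ones(ramp_s) / ramp_s
    sm = np.convolve(padded, kernel, mode="same")[pad:-pad]
    return sm


def generate_rri(
    states: StateSequence, config: SimConfig, seed: int | None = None
) -> BeatSeries:
    """Generate the beat-by-beat RR-interval series for a state sequence.

    Each interval is the smoothed state mean at the current beat time, plus
    the circadian drift ``drift_amplitude_ms * sin(2*pi*t/drift_period_h)``,
    plus AR(1) noise with state-dependent stationary SD; beat times are the
    cumulative sums of the intervals.
    """
    states.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t0, t1 = states.span
    total_s = t1 - t0
    mean_sec = _smoothed_per_second(states, config.rri_mean_awake, config.rri_mean_sleep)
    sd_sec = _smoothed_per_second(states, config.rri_sd_awake, config.rri_sd_sleep)
    nsec = len(mean_sec)

    phi = config.ar_coeff
    innov_scale = math.sqrt(1.0 - phi * phi)
    amp = config.drift_amplitude_ms
    omega = 2.0 * math.pi / (config.drift_period_h * 3600.0)

    min_mean = min(config.rri_mean_awake, config.rri_mean_sleep)
    n_est = int(total_s * 1000.0 / max(min_mean - amp - 1.0, 1.0)) + 16
    normals = rng.standard_normal(n_est)

    times = np.empty(n_est)
    rri = np.empty(n_est)
    t = 0.0
    sec = 0
    eps = normals[0] * sd_sec[0]  # start at the stationary distribution
    i = 0
    while t < total_s:
        sec = min(int(t), nsec - 1)
        value = mean_sec[sec] + amp * math.sin(omega * t) + eps
        if value <= 0.0:
            raise GenerationError(
                f"non-positive RRI ({value:.1f} ms) at t={t:.1f}s; "
                "check rri_mean_*, rri_sd_* and drift_amplitude_ms"
            )
        times[i] = t0 + t
        rri[i] = value
        t += value / 1000.0
        i += 1
        if i >= n_est:  # pragma: no cover - generous pre-allocation
            raise GenerationError("beat count exceeded pre-allocation; RRI too short")
        sec_next = min(int(t), nsec - 1)
        eps = phi * eps + innov_scale * sd_sec[sec_next] * normals[i]
    return BeatSeries(times[:i], rri[:i], subject_id=config.subject_id)


def generate_rc(
    states: StateSequence, config: SimConfig, seed: int | None = None
) -> RespSeries:
    """Breathing-rate series on a uniform 1-s grid, AR(1) around state means."""
    states.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t0, _ = states.span
    mean_sec = _smoothed_per_second(states, config.rc_mean_awake, config.rc_mean_sleep)
    sd_sec = _smoothed_per_second(states, config.rc_sd_awake, config.rc_sd_sleep)
    n = len(mean_sec)
    phi = config.ar_coeff
    innov = rng.standard_normal(n) * sd_sec * math.sqrt(1.0 - phi * phi)
    eps = np.empty(n)
    e = rng.standard_normal() * sd_sec[0]
    for k in range(n):
        e = phi * e + innov[k]
        eps[k] = e
    rc = mean_sec + eps
    if np.any(rc <= 0):
        k = int(np.argmax(rc <= 0))
        raise GenerationError(
            f"non-positive breathing rate at t={k}s; check rc_mean_* and rc_sd_*"
        )
    return RespSeries(t0 + np.arange(n, dtype=float), rc)


# ---------------------------------------------------------------------------
# missing data
# ---------------------------------------------------------------------------


def inject_missing(
    beats: BeatSeries,
    fraction: float,
    seed: int | None = None,
    mean_gap_min: float = 5.0,
) -> BeatSeries:
    """Remove contiguous blocks of beats to emulate recording dropouts.

    Draws gap placements uniformly over the record and gap lengths from an
    exponential distribution with mean ``mean_gap_min`` minutes, until the
    removed proportion of recorded time is within 1% of ``fraction``.
    Surviving beats flanking each gap get their ``gap_mask`` flag set.
    """
    if not (0 <= fraction < 1):
        raise ValidationError("missing fraction must lie in [0, 1)")
    if fraction == 0:
        return BeatSeries(
            beats.beat_times.copy(),
            beats.rri.copy(),
            subject_id=beats.subject_id,
            gap_mask=beats.gap_mask.copy(),
        )
    rng = np.random.default_rng(seed)
    total_time = float(np.sum(beats.rri)) / 1000.0
    keep = np.ones(len(beats), dtype=bool)
    removed = 0.0
    t_lo = beats.beat_times[0]
    t_hi = beats.beat_times[-1]
    guard = 0
    while removed / total_time < fraction - 0.005:
        guard += 1
        if guard > 100000:  # pragma: no cover - defensive
            raise GenerationError("missing-data injection failed to converge")
        length = rng.exponential(mean_gap_min * 60.0)
        start = rng.uniform(t_lo, t_hi)
        hit = keep & (beats.beat_times >= start) & (beats.beat_times < start + length)
        if not np.any(hit):
            continue
        removed += float(np.sum(beats.rri[hit])) / 1000.0
        keep[hit] = False
    if not np.any(keep):
        raise GenerationError("missing-data injection removed every beat")

    new_times = beats.beat_times[keep]
    new_rri = beats.rri[keep]
    gap_mask = beats.gap_mask[keep].copy()
    # flag survivors on both sides of each removed block
    removed_idx = np.nonzero(~keep)[0]
    if len(removed_idx):
        kept_idx = np.nonzero(keep)[0]
        block_starts = removed_idx[np.r_[True, np.diff(removed_idx) > 1]]
        block_ends = removed_idx[np.r_[np.diff(removed_idx) > 1, True]]
        for a, b in zip(block_starts, block_ends):
            left = np.searchsorted(kept_idx, a) - 1
            right = np.searchsorted(kept_idx, b, side="right")
            if left >= 0:
                gap_mask[left] = True
            if right < len(kept_idx):
                gap_mask[right] = True
    out = BeatSeries(new_times, new_rri, subject_id=beats.subject_id, gap_mask=gap_mask)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# one-call recording
# ---------------------------------------------------------------------------


@dataclass
class SimRecording:
    """All artifacts of one simulated subject recording."""

    config: SimConfig
    events: EventLog
    states: StateSequence
    beats: BeatSeries
    resp: RespSeries

    def write_csvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv")
        self.states.to_csv(out / "states.csv")
        self.beats.to_csv(out / "beats.csv")
        self.resp.to_csv(out / "resp.csv")


def simulate_recording(config: SimConfig, seed: int | None = None) -> SimRecording:
    """Simulate a full recording: protocol, RRI, breathing rate, dropouts.

    Independent sub-seeds for the protocol, RRI, RC and missing-data stages
    are spawned deterministically from ``seed`` (or ``config.seed``).
    """
    root = np.random.default_rng(config.seed if seed is None else seed)
    sub = root.integers(0, 2**31 - 1, size=4)
    events, states = generate_protocol(config, seed=int(sub[0]))
    beats = generate_rri(states, config, seed=int(sub[1]))
    resp = generate_rc(states, config, seed=int(sub[2]))
    beats = inject_missing(beats, config.missing_fraction, seed=int(sub[3]))
    return SimRecording(config, events, states, beats, resp)
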