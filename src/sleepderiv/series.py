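"""Core time-series containers for sleep/wake HRV analysis.

Three signal containers and one event container are shared by every stage
of the pipeline:

* :class:`BeatSeries` — per-beat R-peak times (s) and RR intervals (ms),
  the raw cardiac signal.  Recording dropouts appear as time gaps; beats
  flanking a dropout carry a ``gap_mask`` flag so that no finite-difference
  stencil is ever evaluated across a gap.
* :class:`RespSeries` — breathing rate (breaths/min) on a uniform grid.
* :class:`StateSequence` — ground-truth physiological state (wake/sleep)
  per 30-s scoring epoch, the binary analogue of PSG staging.
* :class:`EventLog` — ordered protocol events (lights_on, lights_off,
  sleep_onset, sleep_offset) that drive labeling.

All containers round-trip through small plain CSV files.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WAKE",
    "SLEEP",
    "AWAKE",
    "EPOCH_S",
    "EVENT_TYPES",
    "ValidationError",
    "StateSequence",
    "BeatSeries",
    "RespSeries",
    "EventLog",
    "Nap",
]

#: physiological state vocabulary (ground truth)
WAKE = "wake"
SLEEP = "sleep"
#: label vocabulary (analysis labels; "sleep" label == "napping")
AWAKE = "awake"

#: standard PSG scoring epoch, seconds
EPOCH_S = 30.0

EVENT_TYPES = ("lights_on", "lights_off", "sleep_onset", "sleep_offset")

#: tolerance for beat-time / RRI consistency, seconds
_TIME_ATOL = 1e-9


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


# ---------------------------------------------------------------------------
# StateSequence
# ---------------------------------------------------------------------------


@dataclass
class StateSequence:
    """Ground-truth wake/sleep state on a contiguous 30-s epoch grid."""

    epoch_start_s: np.ndarray
    state: np.ndarray
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.state = np.asarray(self.state, dtype=object)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_start_s)

    @property
    def span(self) -> tuple[float, float]:
        """Half-open time interval covered by the epoch grid."""
        return float(self.epoch_start_s[0]), float(self.epoch_start_s[-1] + self.epoch_s)

    def validate(self) -> None:
        if len(self.epoch_start_s) != len(self.state):
            raise ValidationError("epoch_start_s and state must have equal length")
        if self.n_epochs == 0:
            raise ValidationError("empty state sequence")
        d = np.diff(self.epoch_start_s)
        if not np.allclose(d, self.epoch_s):
            raise ValidationError("epochs must be contiguous and non-overlapping")
        bad = set(self.state) - {WAKE, SLEEP}
        if bad:
            raise ValidationError(f"unknown states: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start_s": self.epoch_start_s, "state": self.state}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch_s: float = EPOCH_S) -> "StateSequence":
        return cls(df["epoch_start_s"].to_numpy(float), df["state"].to_numpy(object), epoch_s)

    @classmethod
    def read_csv(cls, path: str | Path, epoch_s: float = EPOCH_S) -> "StateSequence":
        return cls.from_frame(pd.read_csv(path), epoch_s)


# ---------------------------------------------------------------------------
# BeatSeries
# ---------------------------------------------------------------------------


@dataclass
class BeatSeries:
    """Per-beat R-peak times and RR intervals.

    ``beat_times[i]`` (s) is the onset of interval *i* and ``rri[i]`` (ms)
    its duration, so within a gap-free stretch
    ``beat_times[i+1] == beat_times[i] + rri[i] / 1000``.  When a recording
    dropout removes a block of beats, the surviving beats on either side are
    flagged in ``gap_mask`` and the time axis jumps; the RRI value stored on
    the left-flanking beat remains that beat's true interval.
    """

    beat_times: np.ndarray
    rri: np.ndarray
    subject_id: str = ""
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rri = np.asarray(self.rri, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(len(self.beat_times), dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] + self.rri[-1] / 1000.0 - self.beat_times[0])

    def _consistency_violations(self) -> np.ndarray:
        """Indices i where rri[i] does not reproduce beat_times[i+1]."""
        dt = np.diff(self.beat_times)
        return np.nonzero(np.abs(self.rri[:-1] / 1000.0 - dt) >= _TIME_ATOL)[0]

    def validate(self) -> None:
        n = len(self)
        if n == 0:
            raise ValidationError("empty beat series")
        if len(self.rri) != n or len(self.gap_mask) != n:
            raise ValidationError("beat_times, rri, gap_mask must have equal length")
        if np.any(self.rri <= 0):
            i = int(np.argmax(self.rri <= 0))
            raise ValidationError(f"non-positive RRI at beat {i}")
        if np.any(np.diff(self.beat_times) <= 0):
            i = int(np.argmax(np.diff(self.beat_times) <= 0))
            raise ValidationError(f"beat_times not strictly increasing at beat {i}")
        # every time/RRI inconsistency must be an announced gap
        for i in self._consistency_violations():
            if not (self.gap_mask[i] and self.gap_mask[i + 1]):
                raise ValidationError(
                    f"time/RRI inconsistency at beat {i} without gap_mask flags"
                )

    def segments(self) -> list[slice]:
        """Maximal gap-free runs of beats, as slices into the arrays.

        A segment boundary is placed wherever the stored RRI does not carry
        the time axis to the next beat (i.e., across a dropout).
        """
        breaks = self._consistency_violations()
        bounds = [0, *(breaks + 1), len(self)]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "rri_ms": self.rri,
                "gap_flag": self.gap_mask.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str = "") -> "BeatSeries":
        return cls(
            df["beat_time_s"].to_numpy(float),
            df["rri_ms"].to_numpy(float),
            subject_id=subject_id,
            gap_mask=df["gap_flag"].to_numpy(bool) if "gap_flag" in df else None,
        )

    @classmethod
    def read_csv(cls, path: str | Path, subject_id: str = "") -> "BeatSeries":
        return cls.from_frame(pd.read_csv(path), subject_id=subject_id)


# ---------------------------------------------------------------------------
# RespSeries
# ---------------------------------------------------------------------------


@dataclass
class RespSeries:
    """Breathing rate (breaths/min) sampled on a time grid."""

    sample_times: np.ndarray
    rc: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)

    def __len__(self) -> int:
        return len(self.sample_times)

    def validate(self) -> None:
        if len(self.sample_times) != len(self.rc):
            raise ValidationError("sample_times and rc must have equal length")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValidationError("sample_times not strictly increasing")
        if np.any(self.rc <= 0):
            raise ValidationError("non-positive breathing rate")

    def at_times(self, t: np.ndarray) -> np.ndarray:
        """Nearest-sample lookup of the breathing rate at arbitrary times."""
        idx = np.searchsorted(self.sample_times, t)
        idx = np.clip(idx, 1, len(self) - 1)
        left = self.sample_times[idx - 1]
        right = self.sample_times[idx]
        use_left = np.abs(t - left) <= np.abs(right - t)
        return self.rc[np.where(use_left, idx - 1, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.sample_times, "rc_bpm": self.rc})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "RespSeries":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["rc_bpm"].to_numpy(float))


# ---------------------------------------------------------------------------
# EventLog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Nap:
    """One nap opportunity: lights_off → lights_on, with optional onset."""

    lights_off: float
    lights_on: float
    onset: Optional[float] = None
    offset: Optional[float] = None


@dataclass
class EventLog:
    """Ordered protocol/sleep events.

    Lights events strictly alternate; every sleep_onset lies inside a
    lights_off→lights_on interval with at most one onset per nap.
    """

    time_s: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.event = np.asarray(self.event, dtype=object)

    def __len__(self) -> int:
        return len(self.time_s)

    def validate(self) -> None:
        if len(self.time_s) != len(self.event):
            raise ValidationError("time_s and event must have equal length")
        for i, ev in enumerate(self.event):
            if ev not in EVENT_TYPES:
                raise ValidationError(f"record {i}: unknown event type {ev!r}")
        if np.any(np.diff(self.time_s) < 0):
            i = int(np.argmax(np.diff(self.time_s) < 0))
            raise ValidationError(f"record {i + 1}: event times not increasing")
        lights = [
            (t, e) for t, e in zip(self.time_s, self.event)
            if e in ("lights_on", "lights_off")
        ]
        for (t0, e0), (t1, e1) in zip(lights[:-1], lights[1:]):
            if e0 == e1:
                raise ValidationError(
                    f"lights events do not alternate: {e0} at {t0:.0f}s then {e1} at {t1:.0f}s"
                )
            if t1 <= t0:
                raise ValidationError(f"repeated lights time at {t0:.0f}s")
        naps = self._nap_intervals()
        for t, ev in zip(self.time_s, self.event):
            if ev == "sleep_onset":
                if not any(a <= t < b for a, b in naps):
                    raise ValidationError(
                        f"sleep_onset at {t:.0f}s outside any lights_off→lights_on interval"
                    )
        for a, b in naps:
            n_onsets = int(
                np.sum((self.event == "sleep_onset") & (self.time_s >= a) & (self.time_s < b))
            )
            if n_onsets > 1:
                raise ValidationError(f"nap at {a:.0f}s has {n_onsets} sleep_onset events")

    def _nap_intervals(self) -> list[tuple[float, float]]:
        out = []
        off_t: float | None = None
        for t, ev in zip(self.time_s, self.event):
            if ev == "lights_off":
                off_t = float(t)
            elif ev == "lights_on" and off_t is not None:
                out.append((off_t, float(t)))
                off_t = None
        return out

    def naps(self) -> list[Nap]:
        """Nap opportunities with their (optional) sleep onset/offset."""
        out = []
        for a, b in self._nap_intervals():
            inside = (self.time_s >= a) & (self.time_s <= b)
            onsets = self.time_s[inside & (self.event == "sleep_onset")]
            offsets = self.time_s[inside & (self.event == "sleep_offset")]
            out.append(
                Nap(
                    lights_off=a,
                    lights_on=b,
                    onset=float(onsets[0]) if len(onsets) else None,
                    offset=float(offsets[-1]) if len(offsets) else None,
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "event": self.event})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: Sequence[tuple[float, str]]) -> "EventLog":
        records = sorted(records, key=lambda r: r[0])
        return cls(
            np.array([t for t, _ in records], dtype=float),
            np.array([e for _, e in records], dtype=object),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "EventLog":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["event"].to_numpy(object))
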