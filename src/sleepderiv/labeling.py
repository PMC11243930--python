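"""Event-based awake/sleep labeling and wake-after-sleep-onset statistics.

Labeling rules (two-state, "sleep" meaning "napping"):

* wake episodes — from lights_on to the following lights_off — are *awake*;
* a nap opportunity with no sleep onset is *awake* throughout;
* from a nap's sleep onset to the following lights_on everything is *sleep*,
  even if the subject spontaneously wakes inside that span (those wake
  intrusions are what the WASO statistics quantify).

Epochs are 30 s, anchored at the record start, half-open ``[start, end)``;
an epoch straddling a rule boundary takes the label covering the majority
of the epoch (exact ties resolve to awake).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    AWAKE,
    EPOCH_S,
    SLEEP,
    WAKE,
    BeatSeries,
    EventLog,
    StateSequence,
    ValidationError,
)

__all__ = [
    "LabelSeries",
    "WasoStats",
    "label_epochs",
    "attach_labels",
    "compute_waso_stats",
    "labels_to_events",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelSeries:
    """Per-epoch awake/sleep analysis labels on a contiguous 30-s grid."""

    epoch_start_s: np.ndarray
    label: np.ndarray
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.label = np.asarray(self.label, dtype=object)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_start_s)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.epoch_start_s[0]), float(self.epoch_start_s[-1] + self.epoch_s)

    def validate(self) -> None:
        if self.n_epochs == 0:
            raise ValidationError("empty label series")
        if not np.allclose(np.diff(self.epoch_start_s), self.epoch_s):
            raise ValidationError("epochs must be contiguous and non-overlapping")
        bad = set(self.label) - {AWAKE, SLEEP}
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start_s": self.epoch_start_s, "label": self.label})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, epoch_s: float = EPOCH_S) -> "LabelSeries":
        df = pd.read_csv(path)
        return cls(df["epoch_start_s"].to_numpy(float), df["label"].to_numpy(object), epoch_s)


def label_epochs(
    events: EventLog,
    record_span: tuple[float, float],
    epoch_s: float = EPOCH_S,
) -> LabelSeries:
    """Label every 30-s epoch of ``record_span`` as awake or sleep.

    The label rule is driven solely by the event log: sleep runs from each
    nap's sleep_onset to the following lights_on; everything else —
    including naps without an onset and time outside any logged event — is
    awake.  An empty event log therefore yields an all-awake record.

    Raises :class:`ValidationError` (listing the first violation) on a
    malformed event log.
    """
    events.validate()
    t0, t1 = float(record_span[0]), float(record_span[1])
    if t1 <= t0:
        raise ValidationError("record span must have positive length")
    n_epochs = int(math.ceil((t1 - t0) / epoch_s))
    starts = t0 + epoch_s * np.arange(n_epochs)

    sleep_cover = np.zeros(n_epochs)
    for nap in events.naps():
        if nap.onset is None:
            continue
        a, b = nap.onset, nap.lights_on
        overlap = np.clip(np.minimum(starts + epoch_s, b) - np.maximum(starts, a), 0, None)
        sleep_cover += overlap

    label = np.where(sleep_cover > epoch_s / 2.0, SLEEP, AWAKE).astype(object)
    return LabelSeries(starts, label, epoch_s)


def attach_labels(
    beats: BeatSeries, labels: LabelSeries
) -> tuple[BeatSeries, np.ndarray]:
    """Give each beat the label of the epoch containing it.

    Epochs are half-open ``[start, start + epoch_s)``; a beat exactly on a
    boundary belongs to the epoch it starts.  Beats outside the labeled span
    are dropped (the count is logged) and the trimmed series is returned
    alongside the per-beat label array.
    """
    lo, hi = labels.span
    keep = (beats.beat_times >= lo) & (beats.beat_times < hi)
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.info("attach_labels: dropped %d beats outside the labeled span", n_drop)
    trimmed = BeatSeries(
        beats.beat_times[keep],
        beats.rri[keep],
        subject_id=beats.subject_id,
        gap_mask=beats.gap_mask[keep],
    )
    idx = np.floor((trimmed.beat_times - lo) / labels.epoch_s).astype(int)
    return trimmed, labels.label[idx]


@dataclass
class WasoStats:
    """Wake-after-sleep-onset statistics over a record's naps.

    Per nap with a sleep onset, the wake time between onset and the next
    lights_on, in minutes and as a percentage of that span; naps with no
    onset are excluded and counted in ``n_excluded``.
    """

    per_nap: pd.DataFrame
    mean_min: float
    sd_min: float
    mean_pct: float
    sd_pct: float
    n_naps: int
    n_excluded: int


def compute_waso_stats(states: StateSequence, events: EventLog) -> WasoStats:
    """Wake time after sleep onset per nap, against ground-truth states.

    For each nap that has a sleep_onset, sums the wake-state epochs between
    the onset and the following lights_on; reports per-nap duration in
    minutes and as a percent of the onset→lights_on span, plus their mean
    and SD across naps.
    """
    events.validate()
    states.validate()
    rows = []
    n_excluded = 0
    epoch_min = states.epoch_s / 60.0
    for nap in events.naps():
        if nap.onset is None:
            n_excluded += 1
            continue
        sel = (states.epoch_start_s >= nap.onset) & (states.epoch_start_s < nap.lights_on)
        waso_min = epoch_min * float(np.sum(states.state[sel] == WAKE))
        span_min = (nap.lights_on - nap.onset) / 60.0
        rows.append(
            {
                "onset_s": nap.onset,
                "lights_on_s": nap.lights_on,
                "waso_min": waso_min,
                "waso_pct": 100.0 * waso_min / span_min if span_min > 0 else 0.0,
            }
        )
    per_nap = pd.DataFrame(rows, columns=["onset_s", "lights_on_s", "waso_min", "waso_pct"])
    n = len(per_nap)
    return WasoStats(
        per_nap=per_nap,
        mean_min=float(per_nap["waso_min"].mean()) if n else float("nan"),
        sd_min=float(per_nap["waso_min"].std(ddof=1)) if n > 1 else float("nan"),
        mean_pct=float(per_nap["waso_pct"].mean()) if n else float("nan"),
        sd_pct=float(per_nap["waso_pct"].std(ddof=1)) if n > 1 else float("nan"),
        n_naps=n,
        n_excluded=n_excluded,
    )


def labels_to_events(labels: LabelSeries) -> EventLog:
    """Derive a minimal event log whose labeling reproduces ``labels``.

    Each maximal sleep run [a, b) becomes lights_off/sleep_onset at *a* and
    lights_on at *b*; re-running :func:`label_epochs` on the result over the
    same span returns the original labels.
    """
    records: list[tuple[float, str]] = []
    lab = labels.label
    starts = labels.epoch_start_s
    in_sleep = False
    for i in range(labels.n_epochs):
        if lab[i] == SLEEP and not in_sleep:
            records.append((float(starts[i]), "lights_off"))
            records.append((float(starts[i]), "sleep_onset"))
            in_sleep = True
        elif lab[i] == AWAKE and in_sleep:
            records.append((float(starts[i]), "lights_on"))
            in_sleep = False
    if in_sleep:
        records.append((float(starts[-1] + labels.epoch_s), "lights_on"))
    return EventLog.from_records(records)
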