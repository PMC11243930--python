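"""Finite-difference derivatives of the RRI sequence and feature assembly.

Two discrete differentiators are provided:

* :func:`gn_derivative` — forward-difference Gregory–Newton formulas with
  second-order truncation,
      d1[i] = (Dx_i - D2x_i / 2) / h          (= (-3x_i + 4x_{i+1} - x_{i+2}) / 2h)
      d2[i] = (D2x_i - D3x_i) / h**2
  where D is the forward difference operator;
* :func:`central_derivative` — the familiar central (Taylor-expansion)
  stencils d1[i] = (x_{i+1} - x_{i-1}) / 2h and
  d2[i] = (x_{i+1} - 2 x_i + x_{i-1}) / h**2.

Both operate sample-wise on the RRI sequence with unit step by default
(``step_mode="index"``); a time-based step using the local beat spacing is
available but off by default.  Feature rows are assembled per gap-free
segment only — no stencil ever spans a recording dropout — and grouped
into non-overlapping 30-min windows for split grouping and vote smoothing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import BeatSeries, RespSeries, ValidationError

__all__ = [
    "FEATURES",
    "DerivativeSeries",
    "FeatureMatrix",
    "gn_derivative",
    "central_derivative",
    "derivative_method_agreement",
    "minmax_normalize",
    "minmax_denormalize",
    "build_features",
    "normalize_features",
]

logger = logging.getLogger(__name__)

#: canonical feature column order
FEATURES = ("rc", "rri", "drri", "d2rri")


def _check_deriv_args(x: np.ndarray, order: int, h: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if h <= 0:
        raise ValueError("step h must be positive")
    if len(x) < order + 2:
        raise ValidationError(f"sequence too short for order-{order} derivative")
    return x


def gn_derivative(x: Sequence[float], order: int, h: float = 1.0) -> np.ndarray:
    """Gregory–Newton forward-difference derivative of order 1 or 2.

    Returns an array aligned with ``x``; trailing points where the full
    second-order stencil does not fit fall back to the highest-order
    stencil available, and the final ``order`` points (no forward neighbor)
    are NaN.
    """
    x = _check_deriv_args(x, order, h)
    n = len(x)
    d = np.full(n, np.nan)
    d1x = np.diff(x)            # Dx_i = x_{i+1} - x_i
    d2x = np.diff(x, 2)
    if order == 1:
        d[: n - 2] = (d1x[: n - 2] - d2x / 2.0) / h
        d[n - 2] = d1x[n - 2] / h  # first-order fallback at the tail
    else:
        d3x = np.diff(x, 3)
        d[: n - 3] = (d2x[: n - 3] - d3x) / h**2
        d[n - 3] = d2x[n - 3] / h**2  # lowest-order fallback
    return d


def central_derivative(x: Sequence[float], order: int, h: float = 1.0) -> np.ndarray:
    """Central-difference derivative of order 1 or 2 (endpoints NaN)."""
    x = _check_deriv_args(x, order, h)
    n = len(x)
    d = np.full(n, np.nan)
    if order == 1:
        d[1:-1] = (x[2:] - x[:-2]) / (2.0 * h)
    else:
        d[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / h**2
    return d


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def derivative_method_agreement(x: Sequence[float], order: int = 2) -> float:
    """Pearson correlation between the Gregory–Newton and central estimates.

    The forward Gregory–Newton stencil for ``x_i`` draws on samples
    ``i..i+order+1``, so on noisy data its statistical center sits one
    sample ahead of the central stencil's; the two series are aligned on
    their stencil centers before correlating.  On smooth or strongly
    autocorrelated series the agreement is high.
    """
    g = gn_derivative(x, order)
    c = central_derivative(x, order)
    m = np.isfinite(g[:-1]) & np.isfinite(c[1:])
    return float(np.corrcoef(g[:-1][m], c[1:][m])[0, 1])


def minmax_normalize(
    x: Sequence[float], bounds: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Min–max scale ``x`` to [0, 1].

    With ``bounds=None`` the bounds are fitted on ``x`` (error on a
    degenerate range).  With supplied bounds the transform is applied as-is
    and out-of-range values are clipped to [0, 1], logging the count —
    the transform-mode behavior used on validation/test splits.
    """
    x = np.asarray(x, dtype=float)
    if bounds is None:
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if hi == lo:
            raise ValidationError("cannot fit min–max bounds on a constant sequence")
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        if hi <= lo:
            raise ValidationError("invalid bounds: max must exceed min")
    y = (x - lo) / (hi - lo)
    if bounds is not None:
        n_clip = int(np.sum((y < 0) | (y > 1)))
        if n_clip:
            logger.info("minmax_normalize: clipped %d values outside fitted bounds", n_clip)
        y = np.clip(y, 0.0, 1.0)
    return y, (lo, hi)


def minmax_denormalize(y: Sequence[float], bounds: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`minmax_normalize` for given bounds."""
    lo, hi = bounds
    return np.asarray(y, dtype=float) * (hi - lo) + lo


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


@dataclass
class DerivativeSeries:
    """First/second derivatives aligned with a gap-free beat segment."""

    d1: np.ndarray
    d2: np.ndarray
    method: str = "central"
    step_mode: str = "index"


@dataclass
class FeatureMatrix:
    """Per-beat feature rows with labels and 30-min window ids.

    ``frame`` holds one row per interior beat with columns ``time_s``,
    ``window_id``, ``label`` and one column per feature; ``bounds`` records
    the min–max normalization bounds once fitted (None while raw).
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...]
    dropped_rows: int = 0
    bounds: dict[str, tuple[float, float]] | None = None

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(object)

    @property
    def window_ids(self) -> np.ndarray:
        return self.frame["window_id"].to_numpy(int)

    def select(self, feature_names: Iterable[str]) -> "FeatureMatrix":
        """Restrict to a feature subset (an ablation arm), keeping all rows."""
        names = tuple(f for f in FEATURES if f in set(feature_names))
        missing = set(feature_names) - set(self.feature_names)
        if missing:
            raise ValidationError(f"features not present: {sorted(missing)}")
        cols = ["time_s", "window_id", "label", *names]
        sub_bounds = (
            {k: v for k, v in self.bounds.items() if k in names} if self.bounds else None
        )
        return FeatureMatrix(self.frame[cols].copy(), names, self.dropped_rows, sub_bounds)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _segment_derivatives(
    x: np.ndarray, t: np.ndarray, method: str, step_mode: str
) -> DerivativeSeries:
    if step_mode == "index":
        if method == "central":
            return DerivativeSeries(
                central_derivative(x, 1), central_derivative(x, 2), method, step_mode
            )
        return DerivativeSeries(gn_derivative(x, 1), gn_derivative(x, 2), method, step_mode)
    if step_mode != "time":
        raise ValueError("step_mode must be 'index' or 'time'")
    if method == "central":
        # non-uniform three-point stencils on the local beat spacing
        n = len(x)
        d1 = np.full(n, np.nan)
        d2 = np.full(n, np.nan)
        hl = t[1:-1] - t[:-2]
        hr = t[2:] - t[1:-1]
        d1[1:-1] = (x[2:] - x[:-2]) / (hl + hr)
        d2[1:-1] = 2.0 * (
            x[:-2] / (hl * (hl + hr)) - x[1:-1] / (hl * hr) + x[2:] / (hr * (hl + hr))
        )
        return DerivativeSeries(d1, d2, method, step_mode)
    # Gregory–Newton assumes a uniform step: use the segment's mean spacing
    h = float(np.mean(np.diff(t)))
    return DerivativeSeries(gn_derivative(x, 1, h), gn_derivative(x, 2, h), method, step_mode)


def build_features(
    beats: BeatSeries,
    beat_labels: np.ndarray,
    feature_set: Iterable[str],
    resp: RespSeries | None = None,
    window_min: float = 30.0,
    method: str = "central",
    step_mode: str = "index",
) -> FeatureMatrix:
    """Assemble the per-beat feature matrix for a labeled beat series.

    Derivatives are computed independently within each gap-free segment;
    rows whose stencil would cross a dropout (segment edges, or whole
    segments shorter than the stencil) are dropped and counted in
    ``dropped_rows``.  Requesting the ``rc`` feature requires a respiration
    series, resampled to beat times by nearest-sample lookup.
    """
    requested = set(feature_set)
    unknown = requested - set(FEATURES)
    if unknown:
        raise ValidationError(f"unknown features: {sorted(unknown)}")
    if not requested:
        raise ValidationError("feature_set must not be empty")
    if "rc" in requested and resp is None:
        raise ValidationError("feature 'rc' requested but no respiration series given")
    if len(beat_labels) != len(beats):
        raise ValidationError("beat_labels must align with beats")
    # rows are always defined on interior (stencil-valid) beats so that
    # every ablation arm scores the same samples
    names = tuple(f for f in FEATURES if f in requested)
    chunks = []
    dropped = 0
    for seg in beats.segments():
        t = beats.beat_times[seg]
        x = beats.rri[seg]
        n = len(x)
        if n < 4:
            dropped += n
            continue
        ds = _segment_derivatives(x, t, method, step_mode)
        valid = np.isfinite(ds.d1) & np.isfinite(ds.d2)
        dropped += int(np.sum(~valid))
        cols: dict[str, np.ndarray] = {"time_s": t[valid]}
        if "rc" in requested:
            cols["rc"] = resp.at_times(t[valid])
        if "rri" in requested:
            cols["rri"] = x[valid]
        if "drri" in requested:
            cols["drri"] = ds.d1[valid]
        if "d2rri" in requested:
            cols["d2rri"] = ds.d2[valid]
        df = pd.DataFrame(cols)
        df["label"] = beat_labels[seg][valid]
        chunks.append(df)
    if not chunks:
        raise ValidationError("no gap-free segment long enough for the stencil")
    frame = pd.concat(chunks, ignore_index=True)
    frame["window_id"] = np.floor(frame["time_s"] / (window_min * 60.0)).astype(int)
    frame = frame[["time_s", "window_id", "label", *names]]
    return FeatureMatrix(frame, names, dropped_rows=dropped)


def normalize_features(
    fm: FeatureMatrix, bounds: dict[str, tuple[float, float]] | None = None
) -> tuple[FeatureMatrix, dict[str, tuple[float, float]]]:
    """Min–max normalize every feature column.

    With ``bounds=None``, bounds are fitted on ``fm`` (the training split);
    pass the fitted bounds to transform validation/test splits without
    leakage (out-of-range values are clipped).
    """
    frame = fm.frame.copy()
    out_bounds: dict[str, tuple[float, float]] = {}
    for name in fm.feature_names:
        b = None if bounds is None else bounds[name]
        frame[name], out_bounds[name] = minmax_normalize(frame[name].to_numpy(), b)
    return FeatureMatrix(frame, fm.feature_names, fm.dropped_rows, out_bounds), out_bounds
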