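"""Level-stationarity (KPSS) testing of RRI series and their derivatives.

The test statistic for the null hypothesis "stationary around a constant
mean" is built from the partial sums of the demeaned series,

    eta = n**-2 * sum_t S_t**2 / s2(l),   S_t = sum_{i<=t} (x_i - xbar),

where ``s2(l)`` is the Bartlett-kernel long-run variance estimate with
weights ``w_j = 1 - j/(l+1)`` up to lag ``l``.  The default bandwidth is
the short rule ``l = floor(4 * (n/100)**0.25)``.  p-values are obtained by
linear interpolation in the standard level-stationarity critical-value
table and clamped to its tabulated range [0.01, 0.1] — a series that
rejects strongly reports 0.01, and one comfortably stationary reports 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .derivatives import central_derivative, gn_derivative
from .series import BeatSeries, ValidationError

__all__ = [
    "CRITICAL_VALUES",
    "KPSSResult",
    "kpss_level",
    "default_lags",
    "largest_gapfree_segment",
    "stationarity_report",
]

#: asymptotic critical values for the level-stationarity statistic
CRITICAL_VALUES: dict[float, float] = {0.10: 0.347, 0.05: 0.463, 0.025: 0.574, 0.01: 0.739}

_CRIT = np.array([0.347, 0.463, 0.574, 0.739])
_PVALS = np.array([0.10, 0.05, 0.025, 0.01])

_MIN_N = 20


@dataclass(frozen=True)
class KPSSResult:
    """Outcome of one level-stationarity test."""

    statistic: float
    n: int
    lags: int
    s2l: float
    p_value: float
    critical_values: Mapping[float, float]

    def rejects(self, alpha: float = 0.05) -> bool:
        """Whether level stationarity is rejected at significance alpha."""
        if alpha not in self.critical_values:
            raise KeyError(f"no critical value tabulated for alpha={alpha}")
        return self.statistic > self.critical_values[alpha]


def default_lags(n: int) -> int:
    """Short Bartlett bandwidth rule, l = floor(4 * (n/100)**0.25)."""
    return int(np.floor(4.0 * (n / 100.0) ** 0.25))


def kpss_level(x, lags: int | None = None) -> KPSSResult:
    """Test a series for stationarity around a constant mean.

    Parameters
    ----------
    x : array-like
        The series; must have at least 20 points and nonzero variance.
    lags : int, optional
        Bartlett-kernel truncation lag; defaults to :func:`default_lags`.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < _MIN_N:
        raise ValidationError(f"series too short for KPSS (n={n} < {_MIN_N})")
    e = x - x.mean()
    if np.all(e == 0):
        raise ValidationError("constant series has zero variance; KPSS undefined")
    if lags is None:
        lags = default_lags(n)
    if lags < 0 or lags >= n:
        raise ValidationError(f"lags must lie in [0, n); got {lags}")

    s = np.cumsum(e)
    eta_num = float(np.sum(s * s)) / (n * n)
    gamma0 = float(e @ e) / n
    s2l = gamma0
    for j in range(1, lags + 1):
        w = 1.0 - j / (lags + 1.0)
        s2l += 2.0 * w * float(e[j:] @ e[:-j]) / n
    statistic = eta_num / s2l
    p_value = float(np.interp(statistic, _CRIT, _PVALS))
    return KPSSResult(
        statistic=statistic,
        n=n,
        lags=lags,
        s2l=s2l,
        p_value=p_value,
        critical_values=dict(CRITICAL_VALUES),
    )


def largest_gapfree_segment(beats: BeatSeries) -> np.ndarray:
    """The RRI values of the longest dropout-free stretch of a recording."""
    seg = max(beats.segments(), key=lambda s: s.stop - s.start)
    return beats.rri[seg]


def stationarity_report(
    recordings: Mapping[str, BeatSeries],
    lags: int | None = None,
    min_n: int = 1000,
    method: str = "central",
) -> pd.DataFrame:
    """Per-subject stationarity table for raw RRI and its second derivative.

    For each recording the longest gap-free segment is tested twice: the
    raw RRI sequence, and its second derivative (unit index step).  Returns
    one row per (subject, series) with the statistic and interpolated
    p-value.
    """
    deriv = central_derivative if method == "central" else gn_derivative
    rows = []
    for subject, beats in recordings.items():
        x = largest_gapfree_segment(beats)
        if len(x) < min_n:
            raise ValidationError(
                f"subject {subject}: longest gap-free segment has {len(x)} beats "
                f"(< {min_n}); cannot test"
            )
        for series_name, values in (("RRI", x), ("d2RRI", deriv(x, 2))):
            res = kpss_level(values, lags=lags)
            rows.append(
                {
                    "subject": subject,
                    "series": series_name,
                    "n": res.n,
                    "lags": res.lags,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
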