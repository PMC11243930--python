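"""Descriptive summaries of the labeled feature set.

Numeric counterparts of the usual exploratory views: per-state moment and
quartile tables for each variable (the box-plot content) and the pairwise
Pearson correlation matrix (the pair-plot content).  Simulated recordings
show the expected physiology — longer, more variable RRIs in sleep — and a
negative correlation between the RRI and its second derivative.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .derivatives import FeatureMatrix
from .series import ValidationError

__all__ = ["state_summaries", "correlation_matrix"]


def state_summaries(fm: FeatureMatrix) -> pd.DataFrame:
    """Mean, SD and quartiles per (label, variable).

    Empty label groups are omitted with a warning.  Returns one row per
    (label, variable) with columns mean, sd, q25, q50, q75 and count.
    """
    rows = []
    for label, grp in fm.frame.groupby("label", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"state {label!r} has no samples; omitted")
            continue
        for name in fm.feature_names:
            v = grp[name].to_numpy(float)
            rows.append(
                {
                    "label": label,
                    "variable": name,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
                    "q25": float(np.percentile(v, 25)),
                    "q50": float(np.percentile(v, 50)),
                    "q75": float(np.percentile(v, 75)),
                    "count": len(v),
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(fm: FeatureMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations between feature columns.

    Symmetric with unit diagonal; zero-variance columns yield NaN entries
    and a warning.
    """
    if len(fm.feature_names) < 2:
        raise ValidationError("need at least two variables for a correlation matrix")
    if len(fm.frame) < 3:
        raise ValidationError("need at least three samples for a correlation matrix")
    data = fm.frame[list(fm.feature_names)]
    degenerate = [c for c in data.columns if data[c].std(ddof=0) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns {degenerate}; correlations undefined")
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
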