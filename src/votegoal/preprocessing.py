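"""Within-participant centering and scaling of ballot-level predictors.

Predictors entering the trial-level regressions (overall desirability,
relative desirability, trial order) are standardized with respect to each
participant: per-participant mean 0, sample standard deviation 1
(``ddof=1``).  The generative agents and the fitting code share these
helpers so simulated data and fitted models use identical preprocessing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

STANDARDIZED_COLUMNS = (
    "overall",
    "relative_signed",
    "relative_unsigned",
    "trial_order",
)
STD_SUFFIX = "_std"


class DegenerateInputError(ValueError):
    """A predictor has zero variance within a participant and cannot be scaled."""


def standardize(x) -> np.ndarray:
    """Center and scale a vector to mean 0, sample sd 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance predictor cannot be standardized")
    return (x - x.mean()) / sd


def unstandardize(z, mean: float, sd: float) -> np.ndarray:
    """Inverse of :func:`standardize` given the original mean and sd."""
    return np.asarray(z, dtype=float) * sd + mean


def standardize_within_participant(
    frame: pd.DataFrame,
    columns: Sequence[str] = STANDARDIZED_COLUMNS,
    group: str = "participant_id",
) -> pd.DataFrame:
    """Append ``<col>_std`` columns, standardized within each participant."""
    out = frame.copy()
    for col in columns:
        if col not in frame.columns:
            raise KeyError(f"column {col!r} not present")
        out[col + STD_SUFFIX] = np.nan
    for _, idx in frame.groupby(group, sort=False).indices.items():
        for col in columns:
            vals = frame[col].to_numpy(dtype=float)[idx]
            out.iloc[idx, out.columns.get_loc(col + STD_SUFFIX)] = standardize(vals)
    return out


def participant_stats(
    frame: pd.DataFrame,
    columns: Sequence[str] = STANDARDIZED_COLUMNS,
    group: str = "participant_id",
) -> pd.DataFrame:
    """Per-participant means and sample sds of the predictor columns."""
    rows = []
    for pid, g in frame.groupby(group, sort=False):
        for col in columns:
            vals = g[col].to_numpy(dtype=float)
            rows.append((pid, col, vals.mean(), vals.std(ddof=1)))
    return pd.DataFrame(rows, columns=[group, "column", "mean", "sd"])
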