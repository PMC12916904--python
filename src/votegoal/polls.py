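"""Two-proportion z tests for selection- vs rejection-framed poll questions.

Survey respondents asked who they would vote *for* (selection frame) opt
out -- answer "undecided" -- more often than respondents asked who they
would vote *against* (rejection frame).  The published analyses compare the
two undecided proportions with a pooled two-proportion one-tailed z test;
this module reconstructs the 2x2 counts from the reported group sizes and
undecided percentages and computes the test.

The Yates continuity correction is applied by default: the reported chi^2
statistics (20.3 and 10.6) are reproduced from the reconstructed counts
only with the correction on, so the corrected statistic is treated as the
reference form and the match is verified empirically in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

ALTERNATIVES = ("greater", "less", "two_sided")


@dataclass(frozen=True)
class PollCounts:
    """Undecided counts per framing condition of one poll study."""

    n_selection: int
    n_rejection: int
    undecided_selection: int
    undecided_rejection: int

    def __post_init__(self) -> None:
        if self.n_selection <= 0 or self.n_rejection <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.undecided_selection <= self.n_selection):
            raise ValueError("undecided_selection out of [0, n_selection]")
        if not (0 <= self.undecided_rejection <= self.n_rejection):
            raise ValueError("undecided_rejection out of [0, n_rejection]")

    def swapped(self) -> "PollCounts":
        return PollCounts(
            n_selection=self.n_rejection,
            n_rejection=self.n_selection,
            undecided_selection=self.undecided_rejection,
            undecided_rejection=self.undecided_selection,
        )


@dataclass(frozen=True)
class PollStudy:
    """Published inputs of one survey study: group sizes and undecided rates."""

    name: str
    n_selection: int
    pct_undecided_selection: float
    n_rejection: int
    pct_undecided_rejection: float

    def counts(self) -> PollCounts:
        return PollCounts(
            n_selection=self.n_selection,
            n_rejection=self.n_rejection,
            undecided_selection=reconstruct_counts(
                self.pct_undecided_selection, self.n_selection
            ),
            undecided_rejection=reconstruct_counts(
                self.pct_undecided_rejection, self.n_rejection
            ),
        )


#: May 2024 poll (Biden vs Trump): 32.9% vs 19.9% undecided.
STUDY3 = PollStudy("study3", 484, 32.9, 483, 19.9)
#: September 2024 poll (Harris vs Trump): 22.9% vs 14.6% undecided.
STUDY4 = PollStudy("study4", 489, 22.9, 487, 14.6)


@dataclass(frozen=True)
class PollTestResult:
    z: float
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"z": self.z, "chi2": self.chi2, "df": self.df, "p": self.p}


def reconstruct_counts(percent: float, n: int) -> int:
    """Back out an integer count from a printed percentage and group size.

    Uses round-half-up on ``percent * n / 100`` and warns when the
    back-computed percentage differs from the input by more than 0.05
    points (an ambiguous reconstruction).
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    if n <= 0:
        raise ValueError("n must be positive")
    raw = percent * n / 100.0
    count = int(np.floor(raw + 0.5))
    back = 100.0 * count / n
    if abs(back - percent) > 0.05:
        warnings.warn(
            f"reconstructed count {count}/{n} gives {back:.3f}%, "
            f"{abs(back - percent):.3f} points from the stated {percent}%",
            stacklevel=2,
        )
    return count


def two_proportion_z(
    counts: PollCounts,
    continuity: bool = True,
    alternative: str = "greater",
) -> PollTestResult:
    """Pooled two-proportion z test of undecided rates, selection minus rejection.

    The z statistic is based on ``p_selection - p_rejection``; the default
    alternative "greater" tests whether selection framing yields *more*
    undecided responses.  With ``continuity`` the absolute difference is
    shrunk by ``0.5 * (1/n1 + 1/n2)`` (never past zero) before dividing by
    the pooled standard error.  ``chi2`` is ``z**2`` with 1 df.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n1, n2 = counts.n_selection, counts.n_rejection
    x1, x2 = counts.undecided_selection, counts.undecided_rejection
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError(
            "degenerate table: pooled proportion is 0 or 1, z test undefined"
        )
    inv = 1.0 / n1 + 1.0 / n2
    diff = p1 - p2
    if continuity:
        shrunk = max(abs(diff) - 0.5 * inv, 0.0)
        diff = np.copysign(shrunk, diff) if diff != 0 else 0.0
    se = np.sqrt(pooled * (1.0 - pooled) * inv)
    z = float(diff / se)
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return PollTestResult(z=z, chi2=z * z, df=1, p=p)
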