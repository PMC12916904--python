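"""Participants, candidates, and the candidate-desirability score.

A participant rates 13 political issues on two slider scales, each running
from -3 to +3: a *stance* (where they sit on the issue) and an *importance*
(how much the issue matters to them). A hypothetical candidate holds
positions on exactly two issues. The desirability ``D`` of a candidate to a
participant is an importance-weighted sum of stance alignments,

    D = (10/12) * sum_{k=1,2} w_k * (1 - |stance_cand,k - stance_part,k| / 6)

where the weight ``w_k = importance_raw + 3`` rescales importance to the
range 0..6.  The alignment term is 1 for identical stances and 0 for
maximally opposed stances (difference of 6), so ``D`` spans 0 (two maximally
important, maximally misaligned issues) to 10 (two maximally important,
perfectly aligned issues).

Each ballot shows two candidates side by side; their joint desirability is
summarised by a :class:`DesirabilityPair` holding the *overall* desirability
(mean of the two) and the *relative* desirability (left minus right, kept
both signed and unsigned: side-choice models use the signed difference,
opt-out and decision-time models the unsigned one).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ISSUES = 13
STANCE_MIN = -3.0
STANCE_MAX = 3.0
CONDITIONS = ("selection", "rejection")
LEVELS = ("left", "neutral", "right")

#: Overall 10/12 factor that maps the raw weighted sum (max 2 * 6 = 12) onto 0..10.
DESIRABILITY_SCALE = 10.0 / 12.0

PROFILE_COLUMNS = ["participant_id", "issue_id", "stance", "importance_raw", "condition"]


def _check_range(name: str, value: float) -> None:
    if not (STANCE_MIN <= value <= STANCE_MAX):
        raise ValueError(f"{name} must lie in [{STANCE_MIN}, {STANCE_MAX}], got {value!r}")


def rescale_importance(importance_raw):
    """Map a raw -3..3 importance rating onto the 0..6 weight scale.

    Accepts scalars or arrays; raises ``ValueError`` for out-of-range input.
    """
    x = np.asarray(importance_raw, dtype=float)
    if np.any(x < STANCE_MIN) or np.any(x > STANCE_MAX):
        raise ValueError(
            f"importance_raw must lie in [{STANCE_MIN}, {STANCE_MAX}]"
        )
    out = x + 3.0
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class IssueProfile:
    """One participant's stance and importance rating for a single issue."""

    issue_id: int
    stance: float
    importance_raw: float

    def __post_init__(self) -> None:
        _check_range("stance", self.stance)
        _check_range("importance_raw", self.importance_raw)

    @property
    def importance_scaled(self) -> float:
        return self.importance_raw + 3.0


@dataclass(frozen=True)
class ParticipantProfile:
    """A participant's ratings on all 13 issues plus their assigned goal frame."""

    participant_id: str
    issues: tuple[IssueProfile, ...]
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "issues", tuple(self.issues))
        if len(self.issues) != N_ISSUES:
            raise ValueError(
                f"a profile needs exactly {N_ISSUES} issues, got {len(self.issues)}"
            )
        ids = [ip.issue_id for ip in self.issues]
        if len(set(ids)) != N_ISSUES:
            raise ValueError("issue_ids within a profile must be distinct")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @cached_property
    def _by_id(self) -> dict[int, IssueProfile]:
        return {ip.issue_id: ip for ip in self.issues}

    def issue(self, issue_id: int) -> IssueProfile:
        try:
            return self._by_id[issue_id]
        except KeyError:
            raise LookupError(
                f"issue {issue_id} not rated by participant {self.participant_id}"
            ) from None

    def stance(self, issue_id: int) -> float:
        return self.issue(issue_id).stance

    def importance_raw(self, issue_id: int) -> float:
        return self.issue(issue_id).importance_raw

    def importance_scaled(self, issue_id: int) -> float:
        return self.issue(issue_id).importance_scaled


@dataclass(frozen=True)
class Candidate:
    """A hypothetical candidate defined by stances on two distinct issues.

    ``level_a``/``level_b`` record the nominal design level ("left",
    "neutral", "right") that the (possibly noise-perturbed) stance was
    generated from.
    """

    candidate_id: str
    issue_a: int
    issue_b: int
    stance_a: float
    stance_b: float
    level_a: str
    level_b: str

    def __post_init__(self) -> None:
        if self.issue_a == self.issue_b:
            raise ValueError("a candidate's two issues must be distinct")
        _check_range("stance_a", self.stance_a)
        _check_range("stance_b", self.stance_b)
        for lv in (self.level_a, self.level_b):
            if lv not in LEVELS:
                raise ValueError(f"level must be one of {LEVELS}, got {lv!r}")

    @property
    def issues(self) -> frozenset[int]:
        return frozenset((self.issue_a, self.issue_b))


@dataclass(frozen=True)
class DesirabilityPair:
    """Joint desirability descriptors for the two candidates on a ballot."""

    d_left: float
    d_right: float
    overall: float
    relative_signed: float
    relative_unsigned: float

    def __post_init__(self) -> None:
        for name in ("d_left", "d_right"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 10 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 10], got {v!r}")
        if abs(self.overall - (self.d_left + self.d_right) / 2.0) > 1e-9:
            raise ValueError("overall must equal the mean of d_left and d_right")
        if abs(self.relative_signed - (self.d_left - self.d_right)) > 1e-9:
            raise ValueError("relative_signed must equal d_left - d_right")
        if abs(self.relative_unsigned - abs(self.relative_signed)) > 1e-9:
            raise ValueError("relative_unsigned must equal |relative_signed|")

    @classmethod
    def from_scores(cls, d_left: float, d_right: float) -> "DesirabilityPair":
        signed = d_left - d_right
        return cls(
            d_left=d_left,
            d_right=d_right,
            overall=(d_left + d_right) / 2.0,
            relative_signed=signed,
            relative_unsigned=abs(signed),
        )


def candidate_desirability(participant: ParticipantProfile, candidate: Candidate) -> float:
    """Desirability of ``candidate`` for ``participant`` on the 0..10 scale.

    Raises ``LookupError`` if the candidate references an issue the
    participant has not rated.
    """
    total = 0.0
    for issue_id, cand_stance in (
        (candidate.issue_a, candidate.stance_a),
        (candidate.issue_b, candidate.stance_b),
    ):
        ip = participant.issue(issue_id)
        alignment = 1.0 - abs(cand_stance - ip.stance) / 6.0
        total += ip.importance_scaled * alignment
    return DESIRABILITY_SCALE * total


def ballot_descriptors(
    participant: ParticipantProfile, left: Candidate, right: Candidate
) -> DesirabilityPair:
    """Overall and relative desirability of a (left, right) candidate pair."""
    return DesirabilityPair.from_scores(
        candidate_desirability(participant, left),
        candidate_desirability(participant, right),
    )


# ---------------------------------------------------------------------------
# CSV interchange: one row per (participant, issue).
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for ip in p.issues:
            rows.append(
                (p.participant_id, ip.issue_id, ip.stance, ip.importance_raw, p.condition)
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def frame_to_profiles(frame: pd.DataFrame) -> list[ParticipantProfile]:
    missing = set(PROFILE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"profile table is missing columns: {sorted(missing)}")
    profiles = []
    for pid, g in frame.groupby("participant_id", sort=False):
        conditions = g["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"participant {pid} has inconsistent condition labels")
        issues = tuple(
            IssueProfile(int(r.issue_id), float(r.stance), float(r.importance_raw))
            for r in g.itertuples()
        )
        profiles.append(ParticipantProfile(str(pid), issues, str(conditions[0])))
    return profiles


def save_profiles(profiles: Sequence[ParticipantProfile], path) -> None:
    # %.17g round-trips float64 exactly through text
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")


def load_profiles(path) -> list[ParticipantProfile]:
    return frame_to_profiles(pd.read_csv(path, float_precision="round_trip"))
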