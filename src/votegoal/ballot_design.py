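"""Constrained per-participant ballot generation.

The design tailors every participant's ballots to their own issue ratings:

1. Rank the 13 issues by rated importance (ties broken by ascending
   issue id); the top 8 feed the main task, ranks 9-12 the practice
   ballots, and the least important issue is dropped.
2. Enumerate a table of 252 hypothetical candidates: all 28 unordered
   pairs of the top-8 issues crossed with 3 x 3 stance levels
   (left = -3, neutral = 0, right = +3), each level perturbed by
   zero-mean Gaussian noise and clipped back into [-3, 3].
3. For each ballot, sample a target point uniformly from the feasible
   region of (overall, unsigned relative) desirability -- the convex hull
   of the descriptors realisable by admissible candidate pairs -- and pick
   the admissible pair whose descriptors are closest (Euclidean) to the
   target.  A pair is admissible when its four issues are distinct and
   avoid any forbidden issues.
4. Ballots come in iterations of two: the second ballot's four issues must
   be disjoint from the first's, so each iteration uses all 8 top issues
   exactly once.  Over ``n_ballots/2`` iterations every issue therefore
   appears on exactly ``n_ballots/2`` ballots (50 for the default 100).
5. Counterbalance sides (the more desirable candidate sits on the left on
   exactly half the ballots), counterbalance candidate colors, and shuffle
   the presentation order, all driven by one seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .preferences import (
    DESIRABILITY_SCALE,
    LEVELS,
    Candidate,
    DesirabilityPair,
    ParticipantProfile,
)

N_TOP = 8
N_PRACTICE_ISSUES = 4
N_CANDIDATES = 252
N_ISSUE_PAIRS = 28
N_BALLOTS = 100
N_PRACTICE_BALLOTS = 8
DEFAULT_NOISE_SD = 0.3
MATCH_RETRY_BUDGET = 100

LEVEL_STANCES = np.array([-3.0, 0.0, 3.0])


class BallotDesignError(RuntimeError):
    """Ballot generation failed (constraint infeasibility or retry exhaustion)."""


class MatchInfeasibleError(BallotDesignError):
    """No admissible candidate pair exists under the given constraints."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rank_issues(
    participant: ParticipantProfile,
) -> tuple[list[int], list[int], int]:
    """Split a participant's issues into (top-8, practice 9-12, dropped).

    Issues are ordered by descending importance; ties break by ascending
    issue id so the ranking is deterministic.
    """
    order = sorted(
        participant.issues, key=lambda ip: (-ip.importance_raw, ip.issue_id)
    )
    ids = [ip.issue_id for ip in order]
    return ids[:N_TOP], ids[N_TOP : N_TOP + N_PRACTICE_ISSUES], ids[-1]


@dataclass(frozen=True)
class CandidateTable:
    """The full candidate enumeration for one participant's issue subset."""

    participant_id: str
    issue_ids: tuple[int, ...]  # the issues the table is built on, in rank order
    candidates: tuple[Candidate, ...]
    noise_sd: float
    seed: int | None
    # positions (indices into issue_ids) and stances, as flat arrays
    pos_a: np.ndarray = field(repr=False, compare=False, default=None)
    pos_b: np.ndarray = field(repr=False, compare=False, default=None)
    stance_a: np.ndarray = field(repr=False, compare=False, default=None)
    stance_b: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def top8_issues(self) -> tuple[int, ...]:
        return self.issue_ids

    @property
    def n_issues(self) -> int:
        return len(self.issue_ids)

    def issue_pairs(self) -> set[frozenset[int]]:
        return {c.issues for c in self.candidates}


def _issue_pair_index(n_issues: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(n_issues) for b in range(a + 1, n_issues)]


def _build_table(
    participant: ParticipantProfile,
    issue_ids: Sequence[int],
    noise_sd: float,
    seed,
) -> CandidateTable:
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = _as_rng(seed)
    pairs = _issue_pair_index(len(issue_ids))
    n_cand = len(pairs) * 9
    pos_a = np.empty(n_cand, dtype=np.intp)
    pos_b = np.empty(n_cand, dtype=np.intp)
    lev_a = np.empty(n_cand, dtype=np.intp)
    lev_b = np.empty(n_cand, dtype=np.intp)
    for p, (a, b) in enumerate(pairs):
        for la in range(3):
            for lb in range(3):
                idx = p * 9 + la * 3 + lb
                pos_a[idx], pos_b[idx] = a, b
                lev_a[idx], lev_b[idx] = la, lb
    base_a = LEVEL_STANCES[lev_a]
    base_b = LEVEL_STANCES[lev_b]
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n_cand, 2))
    else:
        noise = np.zeros((n_cand, 2))
    stance_a = np.clip(base_a + noise[:, 0], -3.0, 3.0)
    stance_b = np.clip(base_b + noise[:, 1], -3.0, 3.0)
    issue_ids = tuple(int(i) for i in issue_ids)
    candidates = tuple(
        Candidate(
            candidate_id=f"C{i + 1:03d}",
            issue_a=issue_ids[pos_a[i]],
            issue_b=issue_ids[pos_b[i]],
            stance_a=float(stance_a[i]),
            stance_b=float(stance_b[i]),
            level_a=LEVELS[lev_a[i]],
            level_b=LEVELS[lev_b[i]],
        )
        for i in range(n_cand)
    )
    return CandidateTable(
        participant_id=participant.participant_id,
        issue_ids=issue_ids,
        candidates=candidates,
        noise_sd=noise_sd,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        pos_a=pos_a,
        pos_b=pos_b,
        stance_a=stance_a,
        stance_b=stance_b,
    )


def build_candidate_table(
    participant: ParticipantProfile,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed=0,
) -> CandidateTable:
    """Enumerate the 252-candidate table on the participant's top-8 issues."""
    top8, _, _ = rank_issues(participant)
    return _build_table(participant, top8, noise_sd, seed)


def table_desirability(
    participant: ParticipantProfile, table: CandidateTable
) -> np.ndarray:
    """Desirability of every table candidate for ``participant`` (vectorised)."""
    ps = np.array([participant.stance(i) for i in table.issue_ids])
    w = np.array([participant.importance_scaled(i) for i in table.issue_ids])
    term_a = w[table.pos_a] * (1.0 - np.abs(table.stance_a - ps[table.pos_a]) / 6.0)
    term_b = w[table.pos_b] * (1.0 - np.abs(table.stance_b - ps[table.pos_b]) / 6.0)
    return DESIRABILITY_SCALE * (term_a + term_b)


# ---------------------------------------------------------------------------
# Admissible-pair catalog: all unordered candidate pairs whose four issues are
# distinct.  The index structure depends only on the table layout (issue-pair
# x level grid), so it is computed once per issue count and shared.
# ---------------------------------------------------------------------------


class _PairCatalog:
    def __init__(self, n_issues: int):
        pairs = _issue_pair_index(n_issues)
        i1, i2, masks = [], [], []
        for p1, p2 in itertools.combinations(range(len(pairs)), 2):
            a1, b1 = pairs[p1]
            a2, b2 = pairs[p2]
            if {a1, b1} & {a2, b2}:
                continue
            m = (1 << a1) | (1 << b1) | (1 << a2) | (1 << b2)
            for l1 in range(9):
                c1 = p1 * 9 + l1
                for l2 in range(9):
                    i1.append(c1)
                    i2.append(p2 * 9 + l2)
                    masks.append(m)
        self.i1 = np.asarray(i1, dtype=np.intp)
        self.i2 = np.asarray(i2, dtype=np.intp)
        self.mask = np.asarray(masks, dtype=np.int64)
        # sort rows lexicographically by (i1, i2) so np.argmin's first-minimum
        # rule implements the lexicographic candidate-id tie-break
        order = np.lexsort((self.i2, self.i1))
        self.i1, self.i2, self.mask = self.i1[order], self.i2[order], self.mask[order]
        self.full_mask = (1 << n_issues) - 1
        self.groups = {
            int(m): np.nonzero(self.mask == m)[0] for m in np.unique(self.mask)
        }


_CATALOGS: dict[int, _PairCatalog] = {}


def _catalog(n_issues: int) -> _PairCatalog:
    if n_issues not in _CATALOGS:
        _CATALOGS[n_issues] = _PairCatalog(n_issues)
    return _CATALOGS[n_issues]


class _PolygonSampler:
    """Uniform sampling over the convex hull of a 2-D point cloud.

    The hull polygon is fan-triangulated; a triangle is drawn with
    probability proportional to its area and a point placed uniformly
    inside it.  Degenerate clouds (a single point, or collinear points for
    which qhull cannot build a 2-D hull) fall back to resampling the
    realised points themselves.
    """

    def __init__(self, points: np.ndarray):
        self.points = points
        self.degenerate = False
        span = points.max(axis=0) - points.min(axis=0)
        if np.all(span < 1e-12):
            self.degenerate = True
            return
        try:
            hull = ConvexHull(points)
        except QhullError:
            self.degenerate = True
            return
        verts = points[hull.vertices]
        a = verts[0]
        b = verts[1:-1]
        c = verts[2:]
        cross = (b[:, 0] - a[0]) * (c[:, 1] - a[1]) - (b[:, 1] - a[1]) * (c[:, 0] - a[0])
        areas = 0.5 * np.abs(cross)
        total = areas.sum()
        if total <= 0:
            self.degenerate = True
            return
        self.hull = hull
        self._a, self._b, self._c = a, b, c
        self._probs = areas / total

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.degenerate:
            idx = rng.integers(len(self.points), size=size)
            return self.points[idx]
        tri = rng.choice(len(self._probs), size=size, p=self._probs)
        uv = rng.random((size, 2))
        flip = uv.sum(axis=1) > 1.0
        uv[flip] = 1.0 - uv[flip]
        b = self._b[tri]
        c = self._c[tri]
        return (
            self._a
            + uv[:, :1] * (b - self._a)
            + uv[:, 1:] * (c - self._a)
        )

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        if self.degenerate:
            ref = self.points
            d = np.abs(points[:, None, :] - ref[None, :, :]).sum(axis=2)
            return d.min(axis=1) <= 1e-6
        eq = self.hull.equations
        vals = points @ eq[:, :2].T + eq[:, 2]
        return np.all(vals <= tol, axis=1)


class DesirabilitySpace:
    """Cached view of the (overall, unsigned relative) descriptor space.

    Binds a participant to a candidate table: holds the per-candidate
    desirabilities, the descriptors of every admissible pair, and a
    uniform sampler over their convex hull.
    """

    def __init__(self, participant: ParticipantProfile, table: CandidateTable):
        self.participant = participant
        self.table = table
        self.catalog = _catalog(table.n_issues)
        self.d = table_desirability(participant, table)
        cat = self.catalog
        self.overall = (self.d[cat.i1] + self.d[cat.i2]) / 2.0
        self.rel_unsigned = np.abs(self.d[cat.i1] - self.d[cat.i2])
        self._sampler: _PolygonSampler | None = None

    @property
    def feasible_points(self) -> np.ndarray:
        return np.column_stack([self.overall, self.rel_unsigned])

    @property
    def sampler(self) -> _PolygonSampler:
        if self._sampler is None:
            self._sampler = _PolygonSampler(self.feasible_points)
        return self._sampler

    def sample_targets(self, rng, size: int | None = None) -> np.ndarray:
        """Draw target (overall, unsigned relative) points uniformly over the
        feasible region."""
        rng = _as_rng(rng)
        n = 1 if size is None else size
        out = self.sampler.sample(rng, n)
        return out[0] if size is None else out

    def _forbidden_mask(self, forbidden_issues: Iterable[int]) -> int:
        mask = 0
        lookup = {iid: pos for pos, iid in enumerate(self.table.issue_ids)}
        for iid in forbidden_issues:
            if iid in lookup:
                mask |= 1 << lookup[iid]
        return mask

    def match_index(self, target, forbidden_mask: int = 0) -> int:
        """Row index (into the catalog) of the admissible pair closest to
        ``target``; ties resolve to the lexicographically first pair."""
        cat = self.catalog
        if forbidden_mask == 0:
            dist = (self.overall - target[0]) ** 2 + (self.rel_unsigned - target[1]) ** 2
            return int(np.argmin(dist))
        rows = np.nonzero((cat.mask & forbidden_mask) == 0)[0]
        if rows.size == 0:
            raise MatchInfeasibleError(
                "no admissible candidate pair avoids the forbidden issues"
            )
        dist = (self.overall[rows] - target[0]) ** 2 + (
            self.rel_unsigned[rows] - target[1]
        ) ** 2
        return int(rows[np.argmin(dist)])

    def match(
        self, target, forbidden_issues: Iterable[int] = ()
    ) -> tuple[Candidate, Candidate]:
        k = self.match_index(np.asarray(target, dtype=float),
                             self._forbidden_mask(forbidden_issues))
        cat = self.catalog
        return self.table.candidates[cat.i1[k]], self.table.candidates[cat.i2[k]]


def sample_desirability_targets(
    participant: ParticipantProfile,
    table: CandidateTable,
    seed=None,
    size: int | None = None,
):
    """Sample (overall, unsigned relative) desirability targets for ballots."""
    return DesirabilitySpace(participant, table).sample_targets(seed, size)


def match_candidate_pair(
    participant: ParticipantProfile,
    table: CandidateTable,
    targets,
    forbidden_issues: Iterable[int] = (),
) -> tuple[Candidate, Candidate]:
    """The admissible candidate pair whose descriptors are closest to
    ``targets = (overall, unsigned relative)``."""
    return DesirabilitySpace(participant, table).match(targets, forbidden_issues)


# ---------------------------------------------------------------------------
# Ballot assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ballot:
    ballot_index: int
    left: Candidate
    right: Candidate
    descriptors: DesirabilityPair
    color_left: str

    def __post_init__(self) -> None:
        if len(self.left.issues | self.right.issues) != 4:
            raise ValueError("the four issues on a ballot must be distinct")
        if self.color_left not in ("yellow", "green"):
            raise ValueError("color_left must be 'yellow' or 'green'")

    @property
    def issues(self) -> frozenset[int]:
        return self.left.issues | self.right.issues


@dataclass(frozen=True)
class BallotSet:
    participant_id: str
    ballots: tuple[Ballot, ...]
    rng_seed: int | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ballots", tuple(self.ballots))

    def __len__(self) -> int:
        return len(self.ballots)


def generate_ballot_set(
    participant: ParticipantProfile,
    table: CandidateTable,
    seed,
    n_ballots: int = N_BALLOTS,
) -> BallotSet:
    """Generate a counterbalanced, issue-balanced ballot set.

    ``n_ballots`` must be even; each of the ``n_ballots/2`` iterations
    produces two ballots that jointly use all 8 top issues once, so every
    issue occurs on exactly ``n_ballots/2`` ballots.
    """
    if n_ballots % 2 != 0 or n_ballots <= 0:
        raise ValueError("n_ballots must be a positive even number")
    rng = _as_rng(seed)
    space = DesirabilitySpace(participant, table)
    cat = space.catalog
    n_iter = n_ballots // 2
    targets = space.sample_targets(rng, size=n_ballots)

    # first ballot of every iteration: unconstrained, matched in one batch
    t_first = targets[0::2]
    dist = (space.overall[:, None] - t_first[None, :, 0]) ** 2 + (
        space.rel_unsigned[:, None] - t_first[None, :, 1]
    ) ** 2
    k_first = np.argmin(dist, axis=0)

    rows: list[int] = []
    for it in range(n_iter):
        ka = int(k_first[it])
        comp = cat.full_mask ^ int(cat.mask[ka])
        group = cat.groups.get(comp)
        if group is None or group.size == 0:
            raise BallotDesignError(
                "no admissible complementary pair exists for an iteration"
            )
        t = targets[2 * it + 1]
        dd = (space.overall[group] - t[0]) ** 2 + (space.rel_unsigned[group] - t[1]) ** 2
        kb = int(group[np.argmin(dd)])
        rows.extend((ka, kb))

    rows_arr = np.asarray(rows)
    ci = cat.i1[rows_arr]
    cj = cat.i2[rows_arr]
    d_i = space.d[ci]
    d_j = space.d[cj]
    hi = np.where(d_i >= d_j, ci, cj)
    lo = np.where(d_i >= d_j, cj, ci)

    left_higher = np.zeros(n_ballots, dtype=bool)
    left_higher[rng.permutation(n_ballots)[: n_ballots // 2]] = True
    left_idx = np.where(left_higher, hi, lo)
    right_idx = np.where(left_higher, lo, hi)

    colors = np.array(["yellow"] * (n_ballots // 2) + ["green"] * (n_ballots - n_ballots // 2))
    rng.shuffle(colors)
    order = rng.permutation(n_ballots)

    ballots = []
    for rank, m in enumerate(order):
        li, ri = int(left_idx[m]), int(right_idx[m])
        ballots.append(
            Ballot(
                ballot_index=rank + 1,
                left=table.candidates[li],
                right=table.candidates[ri],
                descriptors=DesirabilityPair.from_scores(
                    float(space.d[li]), float(space.d[ri])
                ),
                color_left=str(colors[m]),
            )
        )
    return BallotSet(
        participant_id=participant.participant_id,
        ballots=tuple(ballots),
        rng_seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def generate_practice_ballots(
    participant: ParticipantProfile,
    seed,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_ballots: int = N_PRACTICE_BALLOTS,
) -> list[Ballot]:
    """Practice ballots drawn from the 9th-12th ranked issues.

    Uses the same target-and-match machinery as the main task but on the
    4-issue practice table; practice ballots are exempt from the issue
    balance and counterbalancing constraints.
    """
    rng = _as_rng(seed)
    _, practice, _ = rank_issues(participant)
    table = _build_table(participant, practice, noise_sd, rng)
    space = DesirabilitySpace(participant, table)
    targets = space.sample_targets(rng, size=n_ballots)
    ballots = []
    for i in range(n_ballots):
        k = space.match_index(targets[i])
        ci, cj = space.catalog.i1[k], space.catalog.i2[k]
        if rng.random() < 0.5:
            ci, cj = cj, ci
        ballots.append(
            Ballot(
                ballot_index=i + 1,
                left=table.candidates[ci],
                right=table.candidates[cj],
                descriptors=DesirabilityPair.from_scores(
                    float(space.d[ci]), float(space.d[cj])
                ),
                color_left="yellow" if rng.random() < 0.5 else "green",
            )
        )
    return ballots


def audit_ballot_set(ballot_set: BallotSet) -> dict:
    """Invariant audit: issue occurrence tally, side counterbalance, issue
    distinctness.  Used by tests and the acceptance harness."""
    issue_counts: dict[int, int] = {}
    left_higher = 0
    distinct_ok = True
    for b in ballot_set.ballots:
        if len(b.issues) != 4:
            distinct_ok = False
        for iid in b.issues:
            issue_counts[iid] = issue_counts.get(iid, 0) + 1
        if b.descriptors.d_left > b.descriptors.d_right:
            left_higher += 1
    return {
        "n_ballots": len(ballot_set),
        "issue_counts": dict(sorted(issue_counts.items())),
        "left_higher_count": left_higher,
        "four_distinct_issues": distinct_ok,
    }


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

BALLOT_COLUMNS = [
    "participant_id",
    "ballot_index",
    "left_candidate_id",
    "right_candidate_id",
    "left_issue_a",
    "left_stance_a",
    "left_issue_b",
    "left_stance_b",
    "right_issue_a",
    "right_stance_a",
    "right_issue_b",
    "right_stance_b",
    "d_left",
    "d_right",
    "overall",
    "relative_signed",
    "relative_unsigned",
    "color_left",
]


def ballots_to_frame(ballot_set: BallotSet) -> pd.DataFrame:
    rows = []
    for b in ballot_set.ballots:
        rows.append(
            (
                ballot_set.participant_id,
                b.ballot_index,
                b.left.candidate_id,
                b.right.candidate_id,
                b.left.issue_a,
                b.left.stance_a,
                b.left.issue_b,
                b.left.stance_b,
                b.right.issue_a,
                b.right.stance_a,
                b.right.issue_b,
                b.right.stance_b,
                b.descriptors.d_left,
                b.descriptors.d_right,
                b.descriptors.overall,
                b.descriptors.relative_signed,
                b.descriptors.relative_unsigned,
                b.color_left,
            )
        )
    return pd.DataFrame(rows, columns=BALLOT_COLUMNS)


def save_ballots(ballot_sets: Iterable[BallotSet], path) -> None:
    frames = [ballots_to_frame(bs) for bs in ballot_sets]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_ballots(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(BALLOT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"ballot table is missing columns: {sorted(missing)}")
    return frame
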