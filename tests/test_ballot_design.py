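"""Ballot design: combinatorics, matching optimality, balance, determinism."""

import itertools

import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.stats import chi2_contingency

from votegoal import ballot_design as bd
from votegoal import behavior_sim
from votegoal.ballot_design import (
    DesirabilitySpace,
    MatchInfeasibleError,
    audit_ballot_set,
    build_candidate_table,
    generate_ballot_set,
    generate_practice_ballots,
    rank_issues,
    sample_desirability_targets,
)

from conftest import make_profile


@pytest.fixture(scope="module")
def profile():
    return behavior_sim.generate_profiles(1, "selection", seed=3)[0]


@pytest.fixture(scope="module")
def table(profile):
    return build_candidate_table(profile, seed=4)


# ---------------------------------------------------------------------------
# issue ranking
# ---------------------------------------------------------------------------


def test_rank_issues_identity_when_sorted(ranked_profile):
    top8, practice, dropped = rank_issues(ranked_profile)
    assert top8 == list(range(1, 9))
    assert practice == list(range(9, 13))
    assert dropped == 13


def test_rank_issues_tie_break_by_issue_id():
    profile = make_profile([0.0] * 13, [1.0] * 13)
    top8, practice, dropped = rank_issues(profile)
    assert top8 == list(range(1, 9))
    assert dropped == 13


def test_rank_issues_matches_sort_oracle():
    rng = np.random.default_rng(9)
    importances = rng.uniform(-3, 3, 13)
    profile = make_profile(rng.uniform(-3, 3, 13), importances)
    top8, practice, dropped = rank_issues(profile)
    expected = [
        iid for _, iid in sorted(
            ((-importances[i], i + 1) for i in range(13))
        )
    ]
    assert top8 + practice + [dropped] == expected


# ---------------------------------------------------------------------------
# candidate table
# ---------------------------------------------------------------------------


def test_table_has_252_candidates_over_28_pairs(table):
    assert len(table.candidates) == 252
    assert len(table.issue_pairs()) == 28
    ids = [c.candidate_id for c in table.candidates]
    assert len(set(ids)) == 252


def test_table_noise_free_stances_are_exact_levels(profile):
    t = build_candidate_table(profile, noise_sd=0.0, seed=0)
    stances = np.concatenate([t.stance_a, t.stance_b])
    assert set(np.unique(stances)) <= {-3.0, 0.0, 3.0}
    # all 3x3 level combinations present for every pair
    combos = {(c.issues, c.level_a, c.level_b) for c in t.candidates}
    assert len(combos) == 252


def test_table_rejects_negative_noise(profile):
    with pytest.raises(ValueError):
        build_candidate_table(profile, noise_sd=-0.1)


def test_table_stances_stay_in_bounds(profile):
    t = build_candidate_table(profile, noise_sd=2.0, seed=1)
    assert np.all(t.stance_a >= -3) and np.all(t.stance_a <= 3)
    assert np.all(t.stance_b >= -3) and np.all(t.stance_b <= 3)


# ---------------------------------------------------------------------------
# target sampling
# ---------------------------------------------------------------------------


def test_targets_fall_inside_feasible_region(profile, table):
    space = DesirabilitySpace(profile, table)
    draws = space.sample_targets(np.random.default_rng(0), size=10_000)
    hull = space.sampler.hull
    vals = draws @ hull.equations[:, :2].T + hull.equations[:, 2]
    assert np.all(vals <= 1e-9)


def test_degenerate_region_returns_single_point():
    # importance all at the floor -> every candidate scores exactly 0
    profile = make_profile([0.0] * 13, [-3.0] * 13)
    t = build_candidate_table(profile, noise_sd=0.0, seed=0)
    draws = sample_desirability_targets(profile, t, seed=1, size=50)
    assert np.allclose(draws, 0.0)


def test_target_sampling_uniform_over_region(profile, table):
    """Compare the triangulation sampler against an independent
    rejection-sampling oracle on a coarse grid (two-sample chi-square)."""
    space = DesirabilitySpace(profile, table)
    rng = np.random.default_rng(12)
    n = 4000
    mine = space.sample_targets(rng, size=n)

    pts = space.feasible_points
    tri = Delaunay(pts[space.sampler.hull.vertices])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    oracle = []
    while len(oracle) < n:
        cand = rng.uniform(lo, hi, size=(4 * n, 2))
        inside = tri.find_simplex(cand) >= 0
        oracle.extend(cand[inside][: n - len(oracle)])
    oracle = np.asarray(oracle)

    def grid_counts(points):
        ix = np.clip(((points[:, 0] - lo[0]) / (hi[0] - lo[0]) * 4).astype(int), 0, 3)
        iy = np.clip(((points[:, 1] - lo[1]) / (hi[1] - lo[1]) * 4).astype(int), 0, 3)
        counts = np.zeros(16)
        np.add.at(counts, ix * 4 + iy, 1)
        return counts

    c1, c2 = grid_counts(mine), grid_counts(oracle)
    keep = (c1 + c2) > 0
    _, p, _, _ = chi2_contingency(np.vstack([c1[keep], c2[keep]]))
    assert p > 0.01


# ---------------------------------------------------------------------------
# pair matching
# ---------------------------------------------------------------------------


def brute_force_best(space, target, forbidden=frozenset()):
    """Exhaustive scan over all candidate pairs with 4 distinct issues."""
    best, best_d = None, np.inf
    cands = space.table.candidates
    for i, j in itertools.combinations(range(len(cands)), 2):
        issues = cands[i].issues | cands[j].issues
        if len(issues) != 4 or issues & forbidden:
            continue
        ov = (space.d[i] + space.d[j]) / 2
        ru = abs(space.d[i] - space.d[j])
        dist = (ov - target[0]) ** 2 + (ru - target[1]) ** 2
        if dist < best_d - 1e-15:
            best, best_d = (i, j), dist
    return best, best_d


def test_match_is_global_minimizer(profile, table):
    space = DesirabilitySpace(profile, table)
    rng = np.random.default_rng(21)
    for target in space.sample_targets(rng, size=3):
        left, right = space.match(target)
        i = table.candidates.index(left)
        j = table.candidates.index(right)
        got = ((space.d[i] + space.d[j]) / 2 - target[0]) ** 2 + (
            abs(space.d[i] - space.d[j]) - target[1]
        ) ** 2
        _, best_d = brute_force_best(space, target)
        assert got == pytest.approx(best_d, abs=1e-12)


def test_match_exact_target_returns_that_pair(profile, table):
    space = DesirabilitySpace(profile, table)
    k = 1234  # arbitrary catalog row
    target = (space.overall[k], space.rel_unsigned[k])
    left, right = space.match(target)
    ov = (space.d[table.candidates.index(left)]
          + space.d[table.candidates.index(right)]) / 2
    ru = abs(space.d[table.candidates.index(left)]
             - space.d[table.candidates.index(right)])
    assert ov == pytest.approx(target[0], abs=1e-12)
    assert ru == pytest.approx(target[1], abs=1e-12)


def test_match_respects_forbidden_issues(profile, table):
    space = DesirabilitySpace(profile, table)
    forbidden = set(table.issue_ids[:4])
    left, right = space.match((5.0, 1.0), forbidden_issues=forbidden)
    assert not (left.issues | right.issues) & forbidden
    # forbidding 6 of 8 issues leaves only 2 -> no admissible pair
    with pytest.raises(MatchInfeasibleError):
        space.match((5.0, 1.0), forbidden_issues=set(table.issue_ids[:6]))


# ---------------------------------------------------------------------------
# ballot sets
# ---------------------------------------------------------------------------


def test_ballot_set_invariants(profile, table):
    bs = generate_ballot_set(profile, table, seed=7)
    audit = audit_ballot_set(bs)
    assert audit["n_ballots"] == 100
    assert audit["four_distinct_issues"]
    assert set(audit["issue_counts"]) == set(table.issue_ids)
    assert all(v == 50 for v in audit["issue_counts"].values())
    assert audit["left_higher_count"] == 50
    assert [b.ballot_index for b in bs.ballots] == list(range(1, 101))


def test_single_iteration_issues_partition(profile, table):
    """With one iteration the two ballots' issues are disjoint and jointly
    cover all 8 top issues."""
    bs = generate_ballot_set(profile, table, seed=2, n_ballots=2)
    b1, b2 = bs.ballots[0], bs.ballots[1]
    assert not b1.issues & b2.issues
    assert b1.issues | b2.issues == set(table.issue_ids)


def test_ballot_set_deterministic_under_seed(profile, table, tmp_path):
    bs1 = generate_ballot_set(profile, table, seed=42)
    bs2 = generate_ballot_set(profile, table, seed=42)
    assert bs1 == bs2
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    bd.save_ballots([bs1], p1)
    bd.save_ballots([bs2], p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert not bd.ballots_to_frame(
        generate_ballot_set(profile, table, seed=43)
    ).equals(bd.ballots_to_frame(bs1))


def test_ballot_csv_round_trip(profile, table, tmp_path):
    bs = generate_ballot_set(profile, table, seed=5)
    path = tmp_path / "ballots.csv"
    bd.save_ballots([bs], path)
    frame = bd.load_ballots(path)
    assert len(frame) == 100
    orig = bd.ballots_to_frame(bs)
    assert np.allclose(frame["overall"], orig["overall"])
    assert list(frame["left_candidate_id"]) == list(orig["left_candidate_id"])


def test_ballot_set_rejects_odd_count(profile, table):
    with pytest.raises(ValueError):
        generate_ballot_set(profile, table, seed=0, n_ballots=99)


def test_practice_ballots_use_practice_issues(profile):
    _, practice, _ = rank_issues(profile)
    ballots = generate_practice_ballots(profile, seed=6)
    assert len(ballots) == 8
    for b in ballots:
        assert b.issues <= set(practice)
        assert len(b.issues) == 4
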