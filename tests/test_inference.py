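"""Exclusions, standardization, logistic fits, and quartile summaries."""

import numpy as np
import pandas as pd
import pytest

from votegoal import inference as inf
from votegoal.preprocessing import (
    DegenerateInputError,
    standardize,
    standardize_within_participant,
    unstandardize,
)


def make_trials(pid, condition, opted_out, chose_left, relative_signed,
                overall=None, censored=None):
    n = len(opted_out)
    overall = overall if overall is not None else np.linspace(1, 9, n)
    censored = censored if censored is not None else [False] * n
    rel = np.asarray(relative_signed, dtype=float)
    frame = pd.DataFrame({
        "participant_id": pid,
        "condition": condition,
        "ballot_index": np.arange(1, n + 1),
        "trial_order": np.arange(1, n + 1, dtype=float),
        "overall": overall,
        "relative_signed": rel,
        "relative_unsigned": np.abs(rel),
        "opted_out": list(opted_out),
        "chose_left": pd.array(chose_left, dtype="boolean"),
        "rt_log10": 0.3,
        "deadline_censored": list(censored),
    })
    return standardize_within_participant(frame)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------


def test_exclusion_no_optout():
    rng = np.random.default_rng(0)
    rel = rng.normal(size=20)
    t = make_trials("A", "selection", [False] * 20, list(rel > 0), rel)
    retained, log = inf.apply_exclusions(t)
    assert len(retained) == 0
    assert log.to_dict("records") == [
        {"participant_id": "A", "reason": "no_optout"}
    ]


def test_exclusion_goal_inconsistent_rejection():
    """A rejection participant naming the best candidate on 60% of voted
    ballots is excluded."""
    rel = np.concatenate([np.linspace(0.5, 1.5, 10), -np.linspace(0.6, 1.6, 10)])
    # chose_left=True with rel>0 -> picked the strictly better candidate
    chose = [True] * 6 + [None] * 4 + [True] * 4 + [None] * 6
    opted = [c is None for c in chose]
    t = make_trials("B", "rejection", opted, chose, rel)
    retained, log = inf.apply_exclusions(t)
    assert list(log["reason"]) == ["goal_inconsistent"]
    # the same behavior under a selection goal is consistent -> retained
    t2 = make_trials("B", "selection", opted, chose, rel)
    retained2, log2 = inf.apply_exclusions(t2)
    assert len(log2) == 0
    assert retained2["participant_id"].nunique() == 1


def test_exclusions_retain_and_idempotent():
    rel = np.linspace(-2, 2, 21)
    chose = [None] + [r > 0 for r in rel[1:]]
    opted = [True] + [False] * 20
    t = make_trials("C", "selection", opted, chose, rel)
    retained, log = inf.apply_exclusions(t)
    assert len(log) == 0 and len(retained) == 21
    again, log2 = inf.apply_exclusions(retained)
    pd.testing.assert_frame_equal(again, retained)
    assert len(log2) == 0
    with pytest.raises(ValueError):
        inf.apply_exclusions(t.iloc[0:0])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_standardize_definition_and_round_trip():
    rng = np.random.default_rng(1)
    x = rng.normal(5, 2, size=200)
    z = standardize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(unstandardize(z, x.mean(), x.std(ddof=1)), x)
    with pytest.raises(DegenerateInputError):
        standardize(np.ones(10))


def test_standardize_within_participant_is_per_group():
    frames = [
        make_trials(pid, "selection", [True] * 10 + [False] * 10,
                    [None] * 10 + [True] * 10,
                    np.random.default_rng(i).normal(size=20))
        for i, pid in enumerate(["P1", "P2"])
    ]
    merged = pd.concat(frames, ignore_index=True)
    for _, g in merged.groupby("participant_id"):
        for col in ("overall_std", "relative_signed_std", "trial_order_std"):
            assert g[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert g[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------


def test_logistic_recovers_2x2_log_odds_ratio_exactly():
    a, b_, c, d = 30, 10, 15, 45  # exposed yes/no, unexposed yes/no
    y = np.concatenate([np.ones(a), np.zeros(b_), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b_), np.zeros(c + d)])
    X = np.column_stack([np.ones_like(x), x])
    res = inf.fit_logistic(y, X, ["intercept", "x"])
    assert res.converged
    assert res.coefficients["x"] == pytest.approx(np.log(a * d / (b_ * c)),
                                                  abs=1e-8)
    assert res.coefficients["intercept"] == pytest.approx(np.log(c / d),
                                                          abs=1e-8)


def test_logistic_null_recovery():
    rng = np.random.default_rng(7)
    n = 10_000
    x = rng.normal(size=n)
    y = (rng.random(n) < 0.4).astype(float)
    res = inf.fit_logistic(y, np.column_stack([np.ones(n), x]),
                           ["intercept", "x"])
    assert abs(res.z_values["x"]) < 3


def grid_search_mle(y, X, lo=-3.0, hi=3.0):
    """Brute-force likelihood maximization on a shrinking 2-D grid."""
    c0 = np.array([(lo + hi) / 2, (lo + hi) / 2])
    half = (hi - lo) / 2
    for _ in range(8):
        g0 = np.linspace(c0[0] - half, c0[0] + half, 41)
        g1 = np.linspace(c0[1] - half, c0[1] + half, 41)
        B0, B1 = np.meshgrid(g0, g1, indexing="ij")
        lp = X[:, 0][:, None, None] * B0 + X[:, 1][:, None, None] * B1
        ll = np.sum(y[:, None, None] * lp - np.log1p(np.exp(lp)), axis=0)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0 = np.array([g0[i], g1[j]])
        half /= 10
    return c0


def test_logistic_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(13)
    n = 200
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
    y = (rng.random(n) < p).astype(float)
    X = np.column_stack([np.ones(n), x])
    res = inf.fit_logistic(y, X, ["intercept", "x"])
    b = grid_search_mle(y, X)
    assert res.coefficients["intercept"] == pytest.approx(b[0], abs=1e-4)
    assert res.coefficients["x"] == pytest.approx(b[1], abs=1e-4)


def test_logistic_input_validation_and_separation():
    y = np.array([0, 0, 1, 1], dtype=float)
    X = np.column_stack([np.ones(4), np.array([1.0, 2.0, 3.0, 4.0])])
    with pytest.raises(ValueError):
        inf.fit_logistic(np.zeros(4), X, ["intercept", "x"])  # one class
    with pytest.raises(ValueError):
        inf.fit_logistic(y, np.column_stack([X, X[:, 1]]),
                         ["intercept", "x", "x2"])  # rank deficient
    res = inf.fit_logistic(y, X, ["intercept", "x"])  # perfectly separated
    assert not res.converged


def test_fit_result_reporting():
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1], dtype=float)
    x = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 0], dtype=float)
    res = inf.fit_logistic(y, np.column_stack([np.ones(10), x]),
                           ["intercept", "x"])
    lo, hi = res.ci95["x"]
    est, se = res.coefficients["x"], res.standard_errors["x"]
    assert lo == pytest.approx(est - 1.96 * se)
    assert hi == pytest.approx(est + 1.96 * se)
    assert "intercept" in res.summary()
    assert res.to_dict()["n_obs"] == 10


# ---------------------------------------------------------------------------
# condition interaction
# ---------------------------------------------------------------------------


def _two_condition_trials(seed=0, flip=False):
    rng = np.random.default_rng(seed)
    frames = []
    for pid, cond in [("S1", "selection"), ("S2", "selection"),
                      ("R1", "rejection"), ("R2", "rejection")]:
        if flip:
            cond = {"selection": "rejection", "rejection": "selection"}[cond]
        rel = rng.normal(size=60)
        opted = list(rng.random(60) < 0.4)
        chose = [None if o else bool(rng.random() < 0.7) for o in opted]
        frames.append(
            make_trials(pid, cond, opted, chose, rel,
                        overall=rng.uniform(1, 9, size=60))
        )
    return pd.concat(frames, ignore_index=True)


def test_condition_relabel_flips_interaction_sign_exactly():
    a = inf.fit_condition_interaction(_two_condition_trials(seed=3))
    b = inf.fit_condition_interaction(_two_condition_trials(seed=3, flip=True))
    for name in a.coefficients:
        expected = a.coefficients[name]
        if name.startswith("condition"):
            expected = -expected
        assert b.coefficients[name] == pytest.approx(expected, abs=1e-6)


def test_combined_model_requires_both_conditions():
    t = _two_condition_trials()
    sel_only = t[t["condition"] == "selection"]
    with pytest.raises(ValueError):
        inf.fit_condition_interaction(sel_only)
    with pytest.raises(ValueError):
        inf.OptOutModel(t)  # mixed conditions need combined=True


def test_identical_agents_in_both_conditions_no_interaction(sim_trials):
    """When both groups behave identically, the condition terms vanish."""
    sub = sim_trials.copy()
    # relabel half of the selection participants as rejection: same generative
    # process, different labels
    sel = sub[sub["condition"] == "selection"]
    pids = sorted(sel["participant_id"].unique())
    relabel = set(pids[: len(pids) // 2])
    sub = sel.copy()
    sub.loc[sub["participant_id"].isin(relabel), "condition"] = "rejection"
    res = inf.fit_condition_interaction(sub)
    assert abs(res.z_values["condition:overall_std"]) < 3


# ---------------------------------------------------------------------------
# quartile summary
# ---------------------------------------------------------------------------


def test_quartile_all_opted_out():
    frames = [
        make_trials(pid, "selection", [True] * 20, [None] * 20,
                    np.random.default_rng(i).normal(size=20))
        for i, pid in enumerate(["P1", "P2"])
    ]
    q = inf.quartile_optout_summary(pd.concat(frames, ignore_index=True))
    assert np.allclose(q["optout_rate"], 1.0)
    assert np.allclose(q["ci_hi"] - q["ci_lo"], 0.0)


def test_quartile_bins_are_equal_count(sim_trials):
    sel = sim_trials[sim_trials["condition"] == "selection"]
    q = inf.quartile_optout_summary(sel)
    n_participants = sel["participant_id"].nunique()
    assert list(q["n_trials"]) == [25 * n_participants] * 4
    assert list(q["quartile"]) == [1, 2, 3, 4]


def test_quartile_selection_bottom_exceeds_top(sim_trials):
    sel = sim_trials[sim_trials["condition"] == "selection"]
    q = inf.quartile_optout_summary(sel)
    assert q["optout_rate"].iloc[0] > q["optout_rate"].iloc[3]
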