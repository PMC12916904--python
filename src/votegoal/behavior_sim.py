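"""Generative voting agents: opt-out decisions, candidate choices, decision times.

An agent is parameterised by three linear models over standardized
ballot-level predictors, mirroring the fitting direction in
:mod:`votegoal.inference`:

* **opt-out** -- logistic model of declining to vote.  Predictors: overall
  desirability, unsigned relative desirability, trial order.
* **choice** -- logistic model of picking the *left* candidate (in the
  rejection frame, "picking" a candidate means naming it as the one voted
  against).  Predictors: signed relative desirability (left minus right),
  overall desirability, trial order.
* **decision time** -- linear model of log10 choice time in seconds, with
  Gaussian noise, for trials on which a vote was cast.

Default coefficients are documented study estimates (fixed effects):
selection agents opt out much more as overall desirability falls
(b_overall = -2.72) and as the candidates grow similar (b_rel = -0.92);
rejection agents show a weak opposite overall trend (b_overall = +0.71);
selection agents choose the more desirable candidate (b_rel = +2.75) while
rejection agents name the less desirable one (b_rel = -1.67).  Intercepts
are set to the logit of the observed marginal opt-out rates (40.3%
selection, 33.3% rejection).  The implied goal-by-overall-desirability
interaction on a -1/+1 goal coding is (0.71 + 2.72)/2 = 1.715.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .ballot_design import BallotSet, ballots_to_frame
from .preferences import (
    CONDITIONS,
    N_ISSUES,
    IssueProfile,
    ParticipantProfile,
)
from .preprocessing import standardize_within_participant

DEFAULT_DEADLINE_RATE = 0.001  # per-trial implicit-deadline censoring probability

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "ballot_index",
    "trial_order",
    "overall",
    "relative_signed",
    "relative_unsigned",
    "overall_std",
    "relative_signed_std",
    "relative_unsigned_std",
    "trial_order_std",
    "opted_out",
    "chose_left",
    "rt_log10",
    "deadline_censored",
]


@dataclass(frozen=True)
class AgentParams:
    """Coefficients of one goal frame's generative models (log-odds scale for
    the two logistic models, log10-seconds for decision time)."""

    goal: str
    optout_coefs: Mapping[str, float]
    choice_coefs: Mapping[str, float]
    rt_coefs: Mapping[str, float]
    rt_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.goal not in CONDITIONS:
            raise ValueError(f"goal must be one of {CONDITIONS}")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")
        object.__setattr__(self, "optout_coefs", dict(self.optout_coefs))
        object.__setattr__(self, "choice_coefs", dict(self.choice_coefs))
        object.__setattr__(self, "rt_coefs", dict(self.rt_coefs))


SELECTION_PARAMS = AgentParams(
    goal="selection",
    optout_coefs={
        "intercept": -0.393,  # logit of the 40.3% marginal opt-out rate
        "b_overall": -2.72,
        "b_relative_unsigned": -0.92,
        "b_trial_order": 0.0,
    },
    choice_coefs={
        "intercept": 0.0,
        "b_relative_signed": 2.75,
        "b_overall": 0.0,
        "b_trial_order": 0.0,
    },
    rt_coefs={"intercept": 0.30, "b_relative_unsigned": -0.04, "b_overall": -0.04},
    rt_noise_sd=0.15,
)

REJECTION_PARAMS = AgentParams(
    goal="rejection",
    optout_coefs={
        "intercept": -0.695,  # logit of the 33.3% marginal opt-out rate
        "b_overall": 0.71,
        "b_relative_unsigned": -0.92,
        "b_trial_order": 0.0,
    },
    choice_coefs={
        "intercept": 0.0,
        "b_relative_signed": -1.67,
        "b_overall": 0.0,
        "b_trial_order": 0.0,
    },
    rt_coefs={"intercept": 0.30, "b_relative_unsigned": -0.02, "b_overall": 0.02},
    rt_noise_sd=0.15,
)


def default_params(goal: str) -> AgentParams:
    if goal == "selection":
        return SELECTION_PARAMS
    if goal == "rejection":
        return REJECTION_PARAMS
    raise ValueError(f"goal must be one of {CONDITIONS}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def p_opt_out(
    params: AgentParams,
    overall_std,
    relative_unsigned_std,
    trial_order_std=0.0,
):
    """Probability of opting out of a ballot given standardized predictors."""
    c = params.optout_coefs
    lp = (
        c["intercept"]
        + c["b_overall"] * np.asarray(overall_std, dtype=float)
        + c["b_relative_unsigned"] * np.asarray(relative_unsigned_std, dtype=float)
        + c.get("b_trial_order", 0.0) * np.asarray(trial_order_std, dtype=float)
    )
    return expit(lp)


def p_choose_left(
    params: AgentParams,
    relative_signed_std,
    overall_std=0.0,
    trial_order_std=0.0,
):
    """Probability of picking the left candidate given standardized predictors.

    Under selection, "picking" is voting for; under rejection, it is naming
    the candidate voted against.
    """
    c = params.choice_coefs
    lp = (
        c["intercept"]
        + c["b_relative_signed"] * np.asarray(relative_signed_std, dtype=float)
        + c.get("b_overall", 0.0) * np.asarray(overall_std, dtype=float)
        + c.get("b_trial_order", 0.0) * np.asarray(trial_order_std, dtype=float)
    )
    return expit(lp)


def generate_profiles(
    n: int,
    condition: str,
    seed,
    id_prefix: str | None = None,
) -> list[ParticipantProfile]:
    """Synthetic participant profiles: stances and importances drawn uniformly
    over the continuous -3..3 slider range."""
    rng = _as_rng(seed)
    if id_prefix is None:
        id_prefix = {"selection": "S", "rejection": "R"}.get(condition, "P")
    profiles = []
    for i in range(n):
        stances = rng.uniform(-3.0, 3.0, size=N_ISSUES)
        importances = rng.uniform(-3.0, 3.0, size=N_ISSUES)
        issues = tuple(
            IssueProfile(issue_id=k + 1, stance=float(stances[k]),
                         importance_raw=float(importances[k]))
            for k in range(N_ISSUES)
        )
        profiles.append(
            ParticipantProfile(f"{id_prefix}{i + 1:03d}", issues, condition)
        )
    return profiles


def _simulate_one(
    frame: pd.DataFrame,
    params: AgentParams,
    design: str,
    rng: np.random.Generator,
    deadline_rate: float,
) -> pd.DataFrame:
    n = len(frame)
    po = p_opt_out(
        params,
        frame["overall_std"].to_numpy(),
        frame["relative_unsigned_std"].to_numpy(),
        frame["trial_order_std"].to_numpy(),
    )
    pl = p_choose_left(
        params,
        frame["relative_signed_std"].to_numpy(),
        frame["overall_std"].to_numpy(),
        frame["trial_order_std"].to_numpy(),
    )
    censored = rng.random(n) < deadline_rate
    if design == "two_stage":
        opted_out = rng.random(n) < po
        chose_left = rng.random(n) < pl
    elif design == "trinary":
        u = rng.random(n)
        opted_out = u < po
        chose_left = (u >= po) & (u < po + (1.0 - po) * pl)
    else:
        raise ValueError("design must be 'two_stage' or 'trinary'")
    opted_out = np.where(censored, False, opted_out)
    voted = ~opted_out & ~censored
    rt = np.full(n, np.nan)
    c = params.rt_coefs
    lp_rt = (
        c["intercept"]
        + c["b_relative_unsigned"] * frame["relative_unsigned_std"].to_numpy()
        + c["b_overall"] * frame["overall_std"].to_numpy()
    )
    noise = rng.normal(0.0, params.rt_noise_sd, size=n)
    rt[voted] = lp_rt[voted] + noise[voted]

    out = frame.copy()
    out["opted_out"] = opted_out
    chose = pd.array(chose_left, dtype="boolean")
    chose[~voted] = pd.NA
    out["chose_left"] = chose
    out["rt_log10"] = rt
    out["deadline_censored"] = censored
    return out


def simulate_dataset(
    profiles: Sequence[ParticipantProfile],
    ballot_sets: Sequence[BallotSet],
    params_by_condition: Mapping[str, AgentParams] | None = None,
    design: str = "two_stage",
    seed=0,
    deadline_rate: float = DEFAULT_DEADLINE_RATE,
    params_by_participant: Mapping[str, AgentParams] | None = None,
) -> pd.DataFrame:
    """Simulate trial records for every (profile, ballot set) pair.

    ``design="two_stage"`` draws the opt-out decision first and, on voted
    trials, the candidate pick; ``design="trinary"`` draws a single
    three-way outcome with masses {p_opt, (1-p_opt)p_left, (1-p_opt)(1-p_left)}.
    The two are distributionally identical.  ``params_by_participant``
    overrides the per-condition parameters for heterogeneous populations.
    """
    if len(profiles) != len(ballot_sets):
        raise ValueError("need exactly one ballot set per profile")
    if params_by_condition is None:
        params_by_condition = {c: default_params(c) for c in CONDITIONS}
    rng = _as_rng(seed)
    chunks = []
    for profile, bs in zip(profiles, ballot_sets):
        if profile.participant_id != bs.participant_id:
            raise ValueError(
                f"profile/ballot-set mismatch: {profile.participant_id} vs "
                f"{bs.participant_id}"
            )
        frame = ballots_to_frame(bs)[
            ["participant_id", "ballot_index", "overall",
             "relative_signed", "relative_unsigned"]
        ].copy()
        frame["condition"] = profile.condition
        frame["trial_order"] = frame["ballot_index"].astype(float)
        frame = standardize_within_participant(frame)
        if params_by_participant and profile.participant_id in params_by_participant:
            params = params_by_participant[profile.participant_id]
        else:
            params = params_by_condition[profile.condition]
        chunks.append(_simulate_one(frame, params, design, rng, deadline_rate))
    out = pd.concat(chunks, ignore_index=True)
    return out[TRIAL_COLUMNS]


def heterogeneity(
    params: AgentParams,
    sd_vector: Mapping[str, Mapping[str, float]],
    n_agents: int,
    seed,
) -> list[AgentParams]:
    """Draw agent-level coefficient sets Gaussian around ``params``.

    ``sd_vector`` mirrors the coefficient dictionaries, e.g.
    ``{"optout": {"b_overall": 0.5}}``; omitted entries have sd 0.  With an
    all-zero vector every agent equals the population parameters exactly.
    """
    rng = _as_rng(seed)
    blocks = {"optout": "optout_coefs", "choice": "choice_coefs", "rt": "rt_coefs"}
    for block, coefs in sd_vector.items():
        if block not in blocks:
            raise ValueError(f"unknown coefficient block {block!r}")
        for name, sd in coefs.items():
            if sd < 0:
                raise ValueError(f"negative sd for {block}.{name}")
    agents = []
    for _ in range(n_agents):
        new = {attr: dict(getattr(params, attr)) for attr in blocks.values()}
        for block, coefs in sd_vector.items():
            attr = blocks[block]
            for name, sd in coefs.items():
                if name not in new[attr]:
                    raise KeyError(f"{block} has no coefficient {name!r}")
                if sd > 0:
                    new[attr][name] += rng.normal(0.0, sd)
        agents.append(
            AgentParams(
                goal=params.goal,
                optout_coefs=new["optout_coefs"],
                choice_coefs=new["choice_coefs"],
                rt_coefs=new["rt_coefs"],
                rt_noise_sd=params.rt_noise_sd,
            )
        )
    return agents


# ---------------------------------------------------------------------------
# Parameter / trial-table I/O
# ---------------------------------------------------------------------------


def params_to_dict(params: AgentParams) -> dict:
    return {
        "goal": params.goal,
        "optout_coefs": dict(params.optout_coefs),
        "choice_coefs": dict(params.choice_coefs),
        "rt_coefs": dict(params.rt_coefs),
        "rt_noise_sd": params.rt_noise_sd,
    }


def params_from_dict(d: Mapping) -> AgentParams:
    return AgentParams(
        goal=d["goal"],
        optout_coefs=d["optout_coefs"],
        choice_coefs=d["choice_coefs"],
        rt_coefs=d["rt_coefs"],
        rt_noise_sd=float(d.get("rt_noise_sd", 0.15)),
    )


def save_params(params_by_condition: Mapping[str, AgentParams], path) -> None:
    data = {cond: params_to_dict(p) for cond, p in params_by_condition.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_params(path) -> dict[str, AgentParams]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {cond: params_from_dict(d) for cond, d in data.items()}


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, float_format="%.17g")


def load_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    frame["chose_left"] = frame["chose_left"].astype("boolean")
    frame["opted_out"] = frame["opted_out"].astype(bool)
    frame["deadline_censored"] = frame["deadline_censored"].astype(bool)
    return frame
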