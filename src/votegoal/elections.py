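"""Deterministic expected-vote elections from fixed-effects voting agents.

A voting agent is the fixed-effects opt-out + choice model pair for one
goal frame, evaluated on candidate pairs described by two desirability
numbers: ``D_blue`` and ``D_red``, each on the 0..10 candidate-desirability
scale.  The reporting surface is the 9 x 9 grid with desirabilities 1..9
for each candidate (81 cells); off-grid desirabilities are handled by
evaluating the same models directly, since a logistic model is defined
everywhere.

Predictors are standardized with population-level centers and scales
(means and sds of the ballot descriptors averaged across participants of
the ballot-design generator's population by default), and trial order is
fixed at the standardized value of ballot 1 -- the agent faces a single
ballot.

An election scenario is a set of voter groups, each holding fixed
``(d_blue, d_red)`` perceptions and a head count.  Expected votes are
computed without sampling:

* selection frame: ``votes_blue += count * p_not_opt_out * p_select_blue``
* rejection frame: a vote naming Blue as the rejected candidate counts for
  Red, so ``votes_blue += count * p_not_opt_out * p_reject_red``.

The default scenario grid follows the two archetypes -- Blue Voters rate
(Blue, Red) = (4, 1); Red Voters rate (3, 6); equal 3-point preference
margins, different overall desirability -- crossed with four population
mixes of 10,000 voters, plus a full-turnout variant with the opt-out
pathway disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ballot_design, behavior_sim
from .behavior_sim import AgentParams, default_params, p_choose_left, p_opt_out
from .preferences import CONDITIONS

GRID_VALUES = np.arange(1.0, 10.0)  # 1..9 out of 10 desirability points
DEFAULT_MIXES = ((500, 9500), (3500, 6500), (6500, 3500), (9500, 500))
BLUE_ARCHETYPE = (4.0, 1.0)  # (d_blue, d_red) as seen by a Blue Voter
RED_ARCHETYPE = (3.0, 6.0)  # as seen by a Red Voter

_TRIAL_ORDERS = np.arange(1, 101, dtype=float)


@dataclass(frozen=True)
class Standardization:
    """Population centers and scales used to standardize agent predictors."""

    center_overall: float
    scale_overall: float
    center_relative_signed: float
    scale_relative_signed: float
    center_relative_unsigned: float
    scale_relative_unsigned: float
    center_trial_order: float = float(_TRIAL_ORDERS.mean())
    scale_trial_order: float = float(_TRIAL_ORDERS.std(ddof=1))

    def __post_init__(self) -> None:
        for name in (
            "scale_overall",
            "scale_relative_signed",
            "scale_relative_unsigned",
            "scale_trial_order",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def trial_order_1_std(self) -> float:
        return (1.0 - self.center_trial_order) / self.scale_trial_order


def population_standardization(
    n_participants: int = 24,
    noise_sd: float = ballot_design.DEFAULT_NOISE_SD,
    seed: int = 0,
    n_ballots: int = 100,
) -> Standardization:
    """Centers/scales from a synthetic ballot-design population.

    Generates ``n_participants`` profiles and ballot sets, computes each
    participant's mean and sample sd of the overall / relative descriptors,
    and averages them across participants.
    """
    rng = np.random.default_rng(seed)
    profiles = behavior_sim.generate_profiles(n_participants, "selection", rng, "P")
    means = {"overall": [], "relative_signed": [], "relative_unsigned": []}
    sds = {k: [] for k in means}
    for p in profiles:
        table = ballot_design.build_candidate_table(p, noise_sd, rng)
        bs = ballot_design.generate_ballot_set(p, table, rng, n_ballots)
        frame = ballot_design.ballots_to_frame(bs)
        for col in means:
            vals = frame[col].to_numpy(dtype=float)
            means[col].append(vals.mean())
            sds[col].append(vals.std(ddof=1))
    return Standardization(
        center_overall=float(np.mean(means["overall"])),
        scale_overall=float(np.mean(sds["overall"])),
        center_relative_signed=float(np.mean(means["relative_signed"])),
        scale_relative_signed=float(np.mean(sds["relative_signed"])),
        center_relative_unsigned=float(np.mean(means["relative_unsigned"])),
        scale_relative_unsigned=float(np.mean(sds["relative_unsigned"])),
    )


@dataclass(frozen=True)
class ProbabilitySurface:
    """Model-implied probabilities over the (D_blue, D_red) grid.

    ``p_not_opt_out[i, j]`` and ``p_vote_blue_given_vote[i, j]`` correspond
    to ``d_values[i]`` for the Blue and ``d_values[j]`` for the Red
    candidate.  ``p_vote_blue_given_vote`` is the probability that the Blue
    candidate *receives* the vote: under rejection, naming Red as the
    rejected candidate.
    """

    goal: str
    d_values: np.ndarray
    p_not_opt_out: np.ndarray
    p_vote_blue_given_vote: np.ndarray
    params: AgentParams
    standardization: Standardization

    def __post_init__(self) -> None:
        if self.p_not_opt_out.shape != (len(self.d_values), len(self.d_values)):
            raise ValueError("grid shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.p_not_opt_out.size

    def evaluate(self, d_blue, d_red) -> tuple[np.ndarray, np.ndarray]:
        """(p_not_opt_out, p_vote_blue_given_vote) at arbitrary desirabilities."""
        return _evaluate(self.params, self.standardization, self.goal, d_blue, d_red)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, db in enumerate(self.d_values):
            for j, dr in enumerate(self.d_values):
                rows.append(
                    (db, dr, self.goal, self.p_not_opt_out[i, j],
                     self.p_vote_blue_given_vote[i, j])
                )
        return pd.DataFrame(
            rows,
            columns=["d_blue", "d_red", "goal", "p_not_opt_out", "p_vote_blue"],
        )


def _evaluate(params, std: Standardization, goal, d_blue, d_red):
    d_blue = np.asarray(d_blue, dtype=float)
    d_red = np.asarray(d_red, dtype=float)
    overall = (d_blue + d_red) / 2.0
    rel_signed = d_blue - d_red
    rel_unsigned = np.abs(rel_signed)
    ov = (overall - std.center_overall) / std.scale_overall
    rs = (rel_signed - std.center_relative_signed) / std.scale_relative_signed
    ru = (rel_unsigned - std.center_relative_unsigned) / std.scale_relative_unsigned
    t1 = std.trial_order_1_std
    p_out = p_opt_out(params, ov, ru, t1)
    p_blue_chosen = p_choose_left(params, rs, ov, t1)
    if goal == "selection":
        p_vote_blue = p_blue_chosen
    else:  # naming Blue as the rejected candidate sends the vote to Red
        p_vote_blue = 1.0 - p_blue_chosen
    return 1.0 - p_out, p_vote_blue


def probability_surface(
    params: AgentParams,
    standardization: Standardization,
    goal: str | None = None,
) -> ProbabilitySurface:
    """Evaluate the voting agent on the 81-cell (D_blue, D_red) grid."""
    goal = params.goal if goal is None else goal
    if goal not in CONDITIONS:
        raise ValueError(f"goal must be one of {CONDITIONS}")
    db, dr = np.meshgrid(GRID_VALUES, GRID_VALUES, indexing="ij")
    p_not, p_blue = _evaluate(params, standardization, goal, db, dr)
    return ProbabilitySurface(
        goal=goal,
        d_values=GRID_VALUES.copy(),
        p_not_opt_out=p_not,
        p_vote_blue_given_vote=p_blue,
        params=params,
        standardization=standardization,
    )


@dataclass(frozen=True)
class VoterGroup:
    """A block of voters sharing candidate perceptions."""

    d_blue: float
    d_red: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class ElectionResult:
    votes_blue: float
    votes_red: float
    abstentions: float

    def __post_init__(self) -> None:
        for name in ("votes_blue", "votes_red", "abstentions"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.votes_blue + self.votes_red + self.abstentions

    @property
    def margin_blue(self) -> float:
        return self.votes_blue - self.votes_red

    @property
    def winner(self) -> str:
        if abs(self.margin_blue) <= 1e-9:
            return "tie"
        return "blue" if self.margin_blue > 0 else "red"


def expected_votes(
    surface: ProbabilitySurface,
    groups: Iterable[VoterGroup],
    full_turnout: bool = False,
) -> ElectionResult:
    """Deterministic expected vote tally over voter groups.

    ``full_turnout=True`` disables the opt-out pathway (every voter casts a
    ballot).  Vote conservation holds exactly: blue + red + abstentions
    equals the population size.
    """
    votes_blue = votes_red = abstain = 0.0
    for g in groups:
        p_not, p_blue = surface.evaluate(g.d_blue, g.d_red)
        p_not = 1.0 if full_turnout else float(p_not)
        p_blue = float(p_blue)
        votes_blue += g.count * p_not * p_blue
        votes_red += g.count * p_not * (1.0 - p_blue)
        abstain += g.count * (1.0 - p_not)
    return ElectionResult(votes_blue, votes_red, abstain)


def sample_election(
    surface: ProbabilitySurface,
    groups: Iterable[VoterGroup],
    seed,
) -> ElectionResult:
    """Optional stochastic variant: multinomial draws per group (for
    uncertainty bands; the deterministic expectation is the primary output)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    votes_blue = votes_red = abstain = 0.0
    for g in groups:
        p_not, p_blue = surface.evaluate(g.d_blue, g.d_red)
        p = [float(p_not * p_blue), float(p_not * (1 - p_blue)), float(1 - p_not)]
        draw = rng.multinomial(g.count, p)
        votes_blue += draw[0]
        votes_red += draw[1]
        abstain += draw[2]
    return ElectionResult(votes_blue, votes_red, abstain)


def run_scenarios(
    params_by_goal: Mapping[str, AgentParams] | None = None,
    mixes: Sequence[tuple[int, int]] = DEFAULT_MIXES,
    blue_archetype: tuple[float, float] = BLUE_ARCHETYPE,
    red_archetype: tuple[float, float] = RED_ARCHETYPE,
    standardization: Standardization | None = None,
    include_full_turnout: bool = True,
) -> pd.DataFrame:
    """Expected-vote elections for every (goal, mix) combination.

    Returns one row per scenario with vote totals, the Blue margin, and the
    winner; with ``include_full_turnout`` a second block repeats every
    scenario with opt-outs disabled.
    """
    if params_by_goal is None:
        params_by_goal = {c: default_params(c) for c in CONDITIONS}
    if standardization is None:
        standardization = population_standardization()
    rows = []
    turnout_modes = [False, True] if include_full_turnout else [False]
    for goal in CONDITIONS:
        if goal not in params_by_goal:
            continue
        surface = probability_surface(params_by_goal[goal], standardization, goal)
        for n_blue, n_red in mixes:
            groups = [
                VoterGroup(blue_archetype[0], blue_archetype[1], n_blue),
                VoterGroup(red_archetype[0], red_archetype[1], n_red),
            ]
            for full in turnout_modes:
                res = expected_votes(surface, groups, full_turnout=full)
                rows.append(
                    (
                        goal,
                        "full" if full else "free",
                        n_blue,
                        n_red,
                        res.votes_blue,
                        res.votes_red,
                        res.abstentions,
                        res.margin_blue,
                        res.winner,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "goal", "turnout", "n_blue_voters", "n_red_voters",
            "votes_blue", "votes_red", "abstentions", "margin_blue", "winner",
        ],
    )


def plot_surface(surface: ProbabilitySurface, kind: str = "optout", ax=None):
    """Heatmap of a probability surface (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if kind == "optout":
        grid = 1.0 - surface.p_not_opt_out
        title = f"P(opt out), {surface.goal}"
    elif kind == "vote":
        grid = surface.p_vote_blue_given_vote
        title = f"P(vote Blue | vote), {surface.goal}"
    else:
        raise ValueError("kind must be 'optout' or 'vote'")
    im = ax.imshow(
        grid.T, origin="lower", vmin=0, vmax=1,
        extent=(0.5, 9.5, 0.5, 9.5), cmap="viridis",
    )
    ax.set_xlabel("Blue candidate desirability")
    ax.set_ylabel("Red candidate desirability")
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax)
    return ax
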