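"""Fixed-effects regression models for trial data, exclusions, and recovery.

The fitting direction mirrors :mod:`votegoal.behavior_sim`'s generative
direction.  Three model classes follow the familiar model/results idiom:
construct from a trial table, call :meth:`fit`, receive a
:class:`FitResult` carrying estimates, Wald standard errors and 95%
confidence intervals, and a :meth:`FitResult.summary` table.

* :class:`OptOutModel` -- logistic regression of opting out on overall
  desirability, unsigned relative desirability and trial order (all
  standardized within participant).
* :class:`ChoiceModel` -- logistic regression of picking the left candidate
  on signed relative desirability, overall desirability and trial order,
  restricted to voted, uncensored trials.
* :class:`DecisionTimeModel` -- OLS of log10 decision time on unsigned
  relative and overall desirability for voted trials.

Each accepts ``combined=True`` to pool both goal frames with a -1/+1
condition code (selection -1, rejection +1) plus condition-by-desirability
interaction terms.  Random-slope mixed-effects structure is deliberately
reduced to fixed effects: the election simulator consumes exactly these
fixed-effects models, and the parameter-recovery harness validates them.
A ``glmm_hook`` attribute allows delegating to an external mixed-model
fitter without changing this surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

try:  # raised (older statsmodels) vs warned (newer)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

from . import ballot_design, behavior_sim
from .behavior_sim import AgentParams
from .preprocessing import (
    DegenerateInputError,
    standardize,
    standardize_within_participant,
    unstandardize,
)

__all__ = [
    "FitResult",
    "OptOutModel",
    "ChoiceModel",
    "DecisionTimeModel",
    "apply_exclusions",
    "standardize_within_participant",
    "fit_logistic",
    "fit_ols",
    "fit_condition_interaction",
    "quartile_optout_summary",
    "recovery_experiment",
]

Z_95 = 1.96

OPTOUT_PREDICTORS = ("overall_std", "relative_unsigned_std", "trial_order_std")
CHOICE_PREDICTORS = ("relative_signed_std", "overall_std", "trial_order_std")
RT_PREDICTORS = ("relative_unsigned_std", "overall_std")
#: desirability predictors that get condition interactions in combined models
_INTERACTED = ("overall_std", "relative_unsigned_std", "relative_signed_std")


@dataclass(frozen=True)
class FitResult:
    """Estimates and Wald inference for one fitted fixed-effects model."""

    model_name: str
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    z_values: Mapping[str, float]
    ci95: Mapping[str, tuple[float, float]]
    converged: bool
    n_obs: int
    log_likelihood: float | None = None

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for name in self.coefficients:
            lo, hi = self.ci95[name]
            rows.append(
                (name, self.coefficients[name], self.standard_errors[name],
                 self.z_values[name], lo, hi)
            )
        return pd.DataFrame(
            rows, columns=["coefficient", "estimate", "se", "z", "ci_lo", "ci_hi"]
        )

    def summary(self) -> str:
        table = self.coef_table().to_string(index=False, float_format="%.4f")
        head = (
            f"{self.model_name}  (n_obs={self.n_obs}, "
            f"converged={self.converged})"
        )
        return head + "\n" + table

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "z_values": dict(self.z_values),
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "converged": self.converged,
            "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood,
        }


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("design matrix / name length mismatch")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def _package(model_name, names, params, bse, converged, n_obs, llf=None) -> FitResult:
    coefs = {n: float(p) for n, p in zip(names, params)}
    ses = {n: float(s) for n, s in zip(names, bse)}
    zs = {
        n: (coefs[n] / ses[n]) if ses[n] > 0 else float("nan") for n in coefs
    }
    cis = {n: (coefs[n] - Z_95 * ses[n], coefs[n] + Z_95 * ses[n]) for n in coefs}
    return FitResult(
        model_name=model_name,
        coefficients=coefs,
        standard_errors=ses,
        z_values=zs,
        ci95=cis,
        converged=converged,
        n_obs=n_obs,
        log_likelihood=llf,
    )


def fit_logistic(
    y, X, names: Sequence[str], model_name: str = "logistic"
) -> FitResult:
    """Maximum-likelihood logistic regression with Wald inference.

    Perfect separation is flagged (``converged=False``) rather than raised;
    rank-deficient designs and single-class responses raise ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("response must be binary (0/1)")
    if classes.size < 2:
        raise ValueError("response must contain both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError):
            nan = [float("nan")] * len(names)
            return _package(model_name, names, nan, nan, False, len(y))
    converged = bool(res.mle_retvals.get("converged", False))
    return _package(
        model_name, names, res.params, res.bse, converged, int(res.nobs),
        float(res.llf),
    )


def fit_ols(y, X, names: Sequence[str], model_name: str = "ols") -> FitResult:
    """Ordinary least squares with the same result container (t statistics
    are reported in the ``z_values`` slot)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    res = sm.OLS(y, X).fit()
    return _package(
        model_name, names, res.params, res.bse, True, int(res.nobs),
        float(res.llf),
    )


def _build_design(
    frame: pd.DataFrame, predictors: Sequence[str], combined: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for p in predictors:
        cols.append(frame[p].to_numpy(dtype=float))
        names.append(p)
    if combined:
        cond = np.where(frame["condition"].to_numpy() == "rejection", 1.0, -1.0)
        cols.append(cond)
        names.append("condition")
        for p in predictors:
            if p in _INTERACTED:
                cols.append(cond * frame[p].to_numpy(dtype=float))
                names.append(f"condition:{p}")
    return np.column_stack(cols), names


class _TrialModel:
    """Shared scaffolding: filter trials, build the design, fit."""

    response: str
    predictors: tuple[str, ...]
    name: str
    #: optional delegate, e.g. to an external mixed-model fitter; receives
    #: (y, X, names) and must return a FitResult
    glmm_hook: Callable | None = None

    def __init__(self, trials: pd.DataFrame, combined: bool = False):
        if len(trials) == 0:
            raise ValueError("empty trial table")
        conditions = trials["condition"].unique()
        if combined and len(conditions) < 2:
            raise ValueError("combined models need trials from both conditions")
        if not combined and len(conditions) > 1:
            raise ValueError(
                "single-condition model got trials from several conditions; "
                "filter first or use combined=True"
            )
        self.trials = self._filter(trials)
        self.combined = combined
        self.exog, self.exog_names = _build_design(
            self.trials, self.predictors, combined
        )
        self.endog = self._response_vector(self.trials)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, combined: bool = False):
        return cls(trials, combined=combined)

    def _filter(self, trials: pd.DataFrame) -> pd.DataFrame:
        return trials

    def _response_vector(self, trials: pd.DataFrame) -> np.ndarray:
        return trials[self.response].to_numpy(dtype=float)

    def fit(self) -> FitResult:
        if self.glmm_hook is not None:
            return self.glmm_hook(self.endog, self.exog, self.exog_names)
        return fit_logistic(
            self.endog, self.exog, self.exog_names, model_name=self.name
        )


class OptOutModel(_TrialModel):
    """Logistic model of opting out.  Deadline-censored trials count as
    not abstaining and are retained."""

    response = "opted_out"
    predictors = OPTOUT_PREDICTORS
    name = "optout"


class ChoiceModel(_TrialModel):
    """Logistic model of picking the left candidate, on voted trials only."""

    response = "chose_left"
    predictors = CHOICE_PREDICTORS
    name = "choice"

    def _filter(self, trials: pd.DataFrame) -> pd.DataFrame:
        voted = (~trials["opted_out"]) & (~trials["deadline_censored"])
        out = trials[voted]
        if len(out) == 0:
            raise ValueError("no voted trials to fit a choice model on")
        return out

    def _response_vector(self, trials: pd.DataFrame) -> np.ndarray:
        return trials["chose_left"].astype("boolean").to_numpy(dtype=float)


class DecisionTimeModel(_TrialModel):
    """OLS of log10 decision time on voted trials."""

    response = "rt_log10"
    predictors = RT_PREDICTORS
    name = "decision_time"

    def _filter(self, trials: pd.DataFrame) -> pd.DataFrame:
        voted = (
            (~trials["opted_out"])
            & (~trials["deadline_censored"])
            & trials["rt_log10"].notna()
        )
        out = trials[voted]
        if len(out) == 0:
            raise ValueError("no timed voted trials to fit")
        return out

    def fit(self) -> FitResult:
        return fit_ols(self.endog, self.exog, self.exog_names, model_name=self.name)


def fit_condition_interaction(
    trials: pd.DataFrame, model: str = "optout"
) -> FitResult:
    """Pooled two-condition fit with -1/+1 condition coding and
    condition-by-desirability interactions."""
    cls = {"optout": OptOutModel, "choice": ChoiceModel, "rt": DecisionTimeModel}[
        model
    ]
    return cls(trials, combined=True).fit()


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level exclusions before analysis.

    Drops (1) participants who never opted out, and (2) participants who, on
    half or more of their voted ballots, picked the candidate inconsistent
    with their goal (selection: picked the strictly less desirable;
    rejection: named the strictly more desirable as the rejected one).
    Returns (retained trials, exclusion log).  Idempotent.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    keep = []
    log_rows = []
    for pid, g in trials.groupby("participant_id", sort=False):
        if int(g["opted_out"].sum()) == 0:
            log_rows.append((pid, "no_optout"))
            continue
        voted = g[(~g["opted_out"]) & (~g["deadline_censored"])]
        if len(voted) > 0:
            rel = voted["relative_signed"].to_numpy(dtype=float)
            chose_left = voted["chose_left"].astype("boolean").to_numpy(dtype=bool)
            picked_higher = np.where(chose_left, rel > 0, rel < 0)
            picked_lower = np.where(chose_left, rel < 0, rel > 0)
            condition = g["condition"].iloc[0]
            inconsistent = picked_lower if condition == "selection" else picked_higher
            if inconsistent.mean() >= 0.5:
                log_rows.append((pid, "goal_inconsistent"))
                continue
        keep.append(g)
    retained = (
        pd.concat(keep, ignore_index=True) if keep else trials.iloc[0:0].copy()
    )
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# Quartile summary
# ---------------------------------------------------------------------------


def _quartile_bins(x: np.ndarray) -> np.ndarray:
    """Equal-count quartile labels 1..4 (1 = lowest values); stable under ties."""
    ranks = rankdata(x, method="ordinal") - 1
    return (ranks * 4 // len(x)).astype(int) + 1


def quartile_optout_summary(
    trials: pd.DataFrame, within_participant: bool = True
) -> pd.DataFrame:
    """Opt-out rate per overall-desirability quartile with a 95% CI.

    Quartiles are equal-count bins of the raw overall desirability, computed
    within each participant by default (``within_participant=False`` pools
    all trials before binning).  The rate is pooled opt-outs/trials; the CI
    is a normal approximation on the distribution of participant means.
    """
    if trials["overall"].nunique() < 4:
        raise ValueError("need at least 4 distinct overall-desirability values")
    df = trials.copy()
    if within_participant:
        df["quartile"] = 0
        for _, idx in df.groupby("participant_id", sort=False).indices.items():
            vals = df["overall"].to_numpy(dtype=float)[idx]
            df.iloc[idx, df.columns.get_loc("quartile")] = _quartile_bins(vals)
    else:
        df["quartile"] = _quartile_bins(df["overall"].to_numpy(dtype=float))
    rows = []
    for q in (1, 2, 3, 4):
        sub = df[df["quartile"] == q]
        pmeans = sub.groupby("participant_id", sort=False)["opted_out"].mean()
        if len(pmeans) < 2:
            raise ValueError(f"quartile {q} has fewer than 2 participants")
        rate = float(sub["opted_out"].mean())
        se = float(pmeans.std(ddof=1) / np.sqrt(len(pmeans)))
        m = float(pmeans.mean())
        rows.append((q, len(sub), rate, m - Z_95 * se, m + Z_95 * se))
    return pd.DataFrame(
        rows, columns=["quartile", "n_trials", "optout_rate", "ci_lo", "ci_hi"]
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def _optout_truth(coefs: Mapping[str, float]) -> dict[str, float]:
    return {
        "intercept": coefs["intercept"],
        "overall_std": coefs["b_overall"],
        "relative_unsigned_std": coefs["b_relative_unsigned"],
        "trial_order_std": coefs.get("b_trial_order", 0.0),
    }


def _choice_truth(coefs: Mapping[str, float]) -> dict[str, float]:
    return {
        "intercept": coefs["intercept"],
        "relative_signed_std": coefs["b_relative_signed"],
        "overall_std": coefs.get("b_overall", 0.0),
        "trial_order_std": coefs.get("b_trial_order", 0.0),
    }


def _combined_optout_truth(
    sel: Mapping[str, float], rej: Mapping[str, float]
) -> dict[str, float]:
    # selection coded -1, rejection +1: main effect = mean, interaction = half-difference
    return {
        "intercept": (sel["intercept"] + rej["intercept"]) / 2.0,
        "overall_std": (sel["b_overall"] + rej["b_overall"]) / 2.0,
        "relative_unsigned_std": (
            sel["b_relative_unsigned"] + rej["b_relative_unsigned"]
        ) / 2.0,
        "trial_order_std": (
            sel.get("b_trial_order", 0.0) + rej.get("b_trial_order", 0.0)
        ) / 2.0,
        "condition": (rej["intercept"] - sel["intercept"]) / 2.0,
        "condition:overall_std": (rej["b_overall"] - sel["b_overall"]) / 2.0,
        "condition:relative_unsigned_std": (
            rej["b_relative_unsigned"] - sel["b_relative_unsigned"]
        ) / 2.0,
    }


def simulate_study(
    params_by_condition: Mapping[str, AgentParams],
    n_agents: Mapping[str, int],
    n_ballots: int,
    seed,
    noise_sd: float = ballot_design.DEFAULT_NOISE_SD,
    design: str = "two_stage",
    deadline_rate: float = behavior_sim.DEFAULT_DEADLINE_RATE,
) -> pd.DataFrame:
    """One synthetic study: profiles -> ballots -> simulated trials."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    # fixed stream layout: [selection profiles/design, rejection ..., simulation]
    streams = {name: s for name, s in zip(
        ("selection", "rejection", "simulate"), seed.spawn(3)
    )}
    profiles = []
    ballot_sets = []
    for cond in ("selection", "rejection"):
        n = n_agents.get(cond, 0)
        if n <= 0:
            continue
        rng = np.random.default_rng(streams[cond])
        profs = behavior_sim.generate_profiles(n, cond, rng)
        for p in profs:
            table = ballot_design.build_candidate_table(p, noise_sd, rng)
            ballot_sets.append(
                ballot_design.generate_ballot_set(p, table, rng, n_ballots)
            )
        profiles.extend(profs)
    return behavior_sim.simulate_dataset(
        profiles,
        ballot_sets,
        params_by_condition,
        design=design,
        seed=np.random.default_rng(streams["simulate"]),
        deadline_rate=deadline_rate,
    )


def recovery_experiment(
    params_by_condition: Mapping[str, AgentParams],
    n_agents: Mapping[str, int] | int,
    n_ballots: int = 100,
    n_reps: int = 50,
    seed: int = 0,
    noise_sd: float = ballot_design.DEFAULT_NOISE_SD,
    design: str = "two_stage",
    models: Sequence[str] = ("optout", "choice", "combined"),
) -> pd.DataFrame:
    """Simulate -> exclude -> standardize -> fit, repeatedly; report recovery.

    For every requested model and coefficient, reports the generating truth,
    the mean estimate across replicates, bias, RMSE, and the fraction of 95%
    Wald intervals covering the truth.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if isinstance(n_agents, int):
        n_agents = {cond: n_agents for cond in params_by_condition}
    conditions = [c for c in sorted(params_by_condition) if n_agents.get(c, 0) > 0]

    # (model, condition, coefficient) -> truth
    truths: dict[tuple[str, str, str], float] = {}
    if "optout" in models:
        for c in conditions:
            for k, v in _optout_truth(params_by_condition[c].optout_coefs).items():
                truths[("optout", c, k)] = v
    if "choice" in models:
        for c in conditions:
            for k, v in _choice_truth(params_by_condition[c].choice_coefs).items():
                truths[("choice", c, k)] = v
    if "combined" in models and len(conditions) == 2:
        ct = _combined_optout_truth(
            params_by_condition["selection"].optout_coefs,
            params_by_condition["rejection"].optout_coefs,
        )
        for k, v in ct.items():
            truths[("combined_optout", "both", k)] = v

    estimates: dict[tuple[str, str, str], list[float]] = {k: [] for k in truths}
    covered: dict[tuple[str, str, str], list[bool]] = {k: [] for k in truths}

    base = np.random.SeedSequence(seed)
    rep_seeds = base.spawn(n_reps)
    for rep in range(n_reps):
        trials = simulate_study(
            params_by_condition, n_agents, n_ballots, rep_seeds[rep],
            noise_sd=noise_sd, design=design,
        )
        retained, _ = apply_exclusions(trials)
        if len(retained) == 0:
            continue
        fits: dict[tuple[str, str], FitResult] = {}
        for c in conditions:
            sub = retained[retained["condition"] == c]
            if len(sub) == 0:
                continue
            if "optout" in models:
                fits[("optout", c)] = OptOutModel(sub).fit()
            if "choice" in models:
                fits[("choice", c)] = ChoiceModel(sub).fit()
        if ("combined_optout", "both", "intercept") in truths and retained[
            "condition"
        ].nunique() == 2:
            fits[("combined_optout", "both")] = fit_condition_interaction(retained)
        for (model, c, coefficient), truth in truths.items():
            fr = fits.get((model, c))
            if fr is None or not fr.converged:
                continue
            est = fr.coefficients[coefficient]
            lo, hi = fr.ci95[coefficient]
            estimates[(model, c, coefficient)].append(est)
            covered[(model, c, coefficient)].append(lo <= truth <= hi)

    rows = []
    for key, truth in truths.items():
        ests = np.asarray(estimates[key], dtype=float)
        cov = np.asarray(covered[key], dtype=float)
        if ests.size == 0:
            rows.append((*key, truth, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        mean_est = float(ests.mean())
        rows.append(
            (
                *key,
                truth,
                mean_est,
                mean_est - truth,
                float(np.sqrt(np.mean((ests - truth) ** 2))),
                float(cov.mean()),
                int(ests.size),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "condition", "coefficient", "truth", "mean_estimate",
            "bias", "rmse", "coverage", "n_reps",
        ],
    )
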