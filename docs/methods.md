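# Methods

## The behavioral model

A voter facing a ballot with two candidates makes two nested decisions:
whether to cast a vote at all, and, if so, which candidate to pick.  Both
decisions are modeled as logistic functions of two ballot descriptors
derived from the voter's own issue ratings:

* **overall desirability** — the mean desirability of the two candidates;
  how good or bad the option set is in absolute terms;
* **relative desirability** — the difference between the two candidates'
  desirabilities; signed (left − right) for side-choice models, unsigned
  for opt-out and decision-time models.

Candidate desirability is the importance-weighted stance-alignment score

    D = (10/12) · Σ_{k=1,2} (importance_k + 3) · (1 − |Δstance_k| / 6)

with stances and importances on −3..3 sliders, so D ∈ [0, 10].  The
importance rescaling is the affine map x + 3 onto 0..6; alignment is 1 at
identical stances and 0 at the maximal gap of 6.

The key structural assumption is **goal congruency**: the sign of the
overall-desirability effect on opting out depends on the choice frame.
Under a selection frame ("vote for the better candidate"), bad option
sets are goal-incongruent and drive opt-outs; under a rejection frame
("vote against the worse candidate"), good option sets are the
incongruent ones, producing a weak opposite trend.

## Generative agents and their defaults

Each goal frame has an `AgentParams` triple of linear models on
*within-participant standardized* predictors (mean 0, sample SD 1 per
participant, `ddof=1`):

| model | predictors | selection | rejection |
|---|---|---|---|
| opt-out (logit) | overall | −2.72 | +0.71 |
| | unsigned relative | −0.92 | −0.92 |
| | trial order | 0 | 0 |
| | intercept | −0.393 | −0.695 |
| choice of left (logit) | signed relative | +2.75 | −1.67 |
| | overall, trial order, intercept | 0 | 0 |
| decision time (log10 s) | unsigned relative | −0.04 | −0.02 |
| | overall | −0.04 | +0.02 |
| | intercept / noise SD | 0.30 / 0.15 | 0.30 / 0.15 |

The slopes are the documented fixed-effects study estimates.  Intercepts
of the opt-out models are not reported as such; they are set to the logit
of the observed marginal opt-out rates (40.3% selection, 33.3%
rejection).  The rejection-frame unsigned-relative slope is likewise not
reported; it reuses the selection value on the assumption that the
indifference effect is frame-independent (equivalently, the
goal-by-relative interaction is zero).  On a −1/+1 goal coding these
defaults imply a goal-by-overall interaction of (0.71 + 2.72)/2 = 1.715
on the opt-out model and a goal-by-overall interaction of 0.03 on the
decision-time model, matching the reported interaction estimates.

In the rejection frame "choosing" a candidate means naming it as the one
voted against, which is why the choice slope is negative: the more
desirable the left candidate, the less likely it is picked for rejection.

Trials can be generated in two designs: `two_stage` (an opt-out Bernoulli
draw followed, on voted trials, by a side draw) and `trinary` (one
categorical draw over {no-vote, left, right} with the composed masses).
The two are distributionally identical; the test suite verifies this at
n = 10⁵.  An implicit per-trial deadline censors a trial with probability
0.001 (matching the 0.10–0.16% rates such deadlines produce in practice);
censored trials count as *not* abstaining in opt-out analyses and are
dropped from choice and decision-time analyses.  Between-agent
heterogeneity is available as Gaussian perturbation of any coefficient
(`heterogeneity`), with a diagonal covariance; the defaults are
homogeneous agents, which is what the recovery harness validates.

## Ballot design

Per participant: the 13 issues are ranked by importance (ties broken by
ascending issue id); ranks 1–8 feed the main task, 9–12 the practice
ballots, 13 is dropped.  The candidate table crosses the 28 unordered
top-8 issue pairs with 3 × 3 stance levels (left −3, neutral 0, right +3),
perturbs each stance with zero-mean Gaussian noise (default SD 0.3) and
clips to [−3, 3] — 252 candidates.

Each ballot is built by sampling a target point uniformly over the
feasible region of (overall, unsigned relative) desirability — the convex
hull of the descriptors of all admissible candidate pairs (four distinct
issues) — and selecting the admissible pair closest to the target in
Euclidean distance, ties broken by lexicographic candidate id.  Ballots
come in iterations of two with disjoint issue sets, so all 8 issues are
used once per iteration and each issue appears on exactly n/2 of the n
ballots (50 of 100 by default).  Sides are counterbalanced so the left
candidate is the more desirable one on exactly half the ballots, candidate
colors are counterbalanced, and presentation order is shuffled — all from
one seed, making ballot CSV exports byte-identical across reruns.

Design choices the task description leaves open, fixed here: the noise
law (truncated/clipped Gaussian, SD 0.3), uniform target sampling over
the empirical feasible region (sampled by area-weighted triangulation of
the hull polygon), the two tie-break rules above, and a retry/infeasible
error path for over-constrained matching.  Degenerate feasible regions
(all descriptors identical, or collinear) fall back to resampling the
realised descriptor points; with a real 252-candidate table this cannot
occur.

## Inference

Mixed-effects structure is deliberately reduced to fixed-effects logistic
(and OLS, for log-decision-time) regressions: the election simulator is
defined over exactly these fixed-effects models, and the recovery harness
shows the chain is consistent at the study scale.  Fitting is
maximum-likelihood via `statsmodels` (Newton, tolerance 1e-10, 100
iterations); Wald standard errors; 95% CIs as estimate ± 1.96·SE.
Perfect separation is flagged (`converged=False`) rather than raised.  A
`glmm_hook` on the model classes allows delegating to an external
mixed-model fitter without changing the surface.

Exclusions mirror the study rules: participants who never opt out, and
participants whose voted ballots are goal-inconsistent (selection: picked
the strictly less desirable candidate; rejection: named the strictly more
desirable one) on ≥ 50% of voted trials.  Exclusions are idempotent.

Quartile opt-out summaries bin the raw overall desirability into
equal-count quartiles within each participant (pooled binning available
by flag), report the pooled rate per quartile, and a normal-approximation
CI on the distribution of participant means.

The recovery experiment runs the full chain — generate profiles, design
ballots, simulate, exclude, standardize, fit — for many replicates and
reports per-coefficient bias, RMSE, and CI coverage.  At the study scale
(44 selection + 47 rejection agents × 100 ballots, 50 replicates) all
generating coefficients are recovered with |bias| < 0.1 and near-nominal
coverage; this is the package's acceptance surface.

## Elections

The voting agent is evaluated on 81 candidate pairs: desirabilities
(D_blue, D_red) ∈ {1..9}².  Predictors are standardized with population
centers and scales — by default the participant-averaged means and SDs of
the ballot descriptors from a synthetic 24-participant design population
(the exact values the original participants induced are not published, so
election outputs are directional, not numeric) — and trial order is fixed
at the standardized value of ballot 1.  Off-grid voter groups are handled
by evaluating the same models directly; the grid is a reporting surface,
not an interpolation table.

Elections are deterministic expectations: for each voter group,
votes_blue += count · p(not opt out) · p(vote received by Blue), where
under rejection a ballot naming Blue as rejected is a vote for Red.
Abstentions complete the partition, so vote conservation is exact.  The
default scenario crosses two archetypes — Blue Voters rating (Blue, Red)
= (4, 1), Red Voters (3, 6): equal 3-point margins, unequal overall
desirability — with four mixes of 10,000 voters: (500, 9500),
(3500, 6500), (6500, 3500), (9500, 500), plus a full-turnout variant with
the opt-out pathway disabled.  With the default agents, selection framing
lets the alienated Blue majority lose the (6500, 3500) election to the
higher-turnout Red minority, while rejection framing (and full turnout)
hands every mix to the majority archetype.  A seeded multinomial-sampling
mode exists for uncertainty bands but is not part of the primary output.

## Poll tests

The survey analyses compare undecided proportions between framing
conditions with a pooled two-proportion one-tailed z test.  Counts are
reconstructed from published group sizes and percentages by round-half-up
(with a warning if the back-computed percentage is off by more than 0.05
points).  The Yates continuity correction — shrinking |p₁ − p₂| by
0.5·(1/n₁ + 1/n₂), never past zero — is on by default: it is the form
that reproduces both published χ² statistics (20.3 and 10.6) from the
reconstructed counts, a match the test suite verifies empirically rather
than asserting by fiat.  χ² = z² with 1 df.

## What the synthetic data do and do not show

The profile generator draws stances and importances uniformly over the
continuous −3..3 slider range; real raters cluster, skew, and correlate
across issues, and real data contain participant-specific random slopes
that the homogeneous defaults omit.  Passing recovery therefore shows
that the estimation chain is consistent and unbiased *under the model*,
not that the model captures every feature of human raters; empirical
quartile opt-out *rates* depend on those random effects and are not
reproduced — only their ordering (monotone decreasing across desirability
quartiles under selection, flat-to-increasing under rejection) is
asserted.  Decision-time parameters enter generation and OLS fitting, but
only the sign structure of the goal-by-desirability interaction is
treated as meaningful.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are the study's
own: 100-ballot sets, 44/47 agents per frame, 50 recovery replicates.
Logistic fits are validated against a closed-form 2×2 log-odds ratio and
a brute-force likelihood grid search (agreement to 1e-4); the
desirability score against brute-force evaluation to 1e-12; the z test
against an independent pooled implementation to 1e-10 (continuity off).
Random streams derive from `numpy.random.SeedSequence` substreams of a
single seed everywhere, so every artifact — ballots, trials, fits,
manifests — is reproducible byte for byte.
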