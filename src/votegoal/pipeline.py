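"""Run configuration and the end-to-end pipeline.

The pipeline chains every stage -- synthetic profiles, ballot design,
trial simulation, exclusions, fixed-effects fits, quartile summaries, and
election scenarios -- under a single seed, and writes a manifest with
SHA-256 checksums so a rerun with the same configuration is byte-identical
and verifiable.  The global seed is expanded into per-stage substreams
(``numpy.random.SeedSequence.spawn``) so stages draw from independent,
reproducible streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ballot_design, behavior_sim, elections, inference

DESIGNS = ("two_stage", "trinary")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    seed: int
    n_selection: int = 44
    n_rejection: int = 47
    n_ballots: int = 100
    noise_sd: float = ballot_design.DEFAULT_NOISE_SD
    design: str = "two_stage"
    deadline_rate: float = behavior_sim.DEFAULT_DEADLINE_RATE
    params_path: str | None = None
    election_mixes: tuple[tuple[int, int], ...] = elections.DEFAULT_MIXES
    outdir: str = "votegoal_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required for any stochastic command")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if self.n_selection < 0 or self.n_rejection < 0:
            raise ConfigError("participant counts must be non-negative")
        if self.n_selection + self.n_rejection == 0:
            raise ConfigError("need at least one participant")
        if self.n_ballots <= 0 or self.n_ballots % 2:
            raise ConfigError("n_ballots must be a positive even number")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.design not in DESIGNS:
            raise ConfigError(f"design must be one of {DESIGNS}")
        object.__setattr__(
            self,
            "election_mixes",
            tuple((int(a), int(b)) for a, b in self.election_mixes),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        if "seed" not in data:
            raise ConfigError("config is missing the required 'seed' field")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["election_mixes"] = [list(m) for m in self.election_mixes]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute profiles -> ballots -> trials -> exclusions -> fits ->
    quartiles -> elections; write all artifacts plus a checksum manifest.

    Returns the manifest.  Deterministic for a fixed config: running twice
    produces byte-identical files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.params_path:
        params_by_condition = behavior_sim.load_params(config.params_path)
    else:
        params_by_condition = {
            c: behavior_sim.default_params(c) for c in ("selection", "rejection")
        }

    base = np.random.SeedSequence(config.seed)
    s_profiles, s_design, s_sim, s_std = base.spawn(4)

    # --- stage 1: profiles
    rng_prof = np.random.default_rng(s_profiles)
    profiles = []
    for cond, n in (("selection", config.n_selection),
                    ("rejection", config.n_rejection)):
        profiles.extend(behavior_sim.generate_profiles(n, cond, rng_prof))
    path = outdir / "profiles.csv"
    from .preferences import save_profiles

    save_profiles(profiles, path)
    artifacts["profiles"] = path

    # --- stage 2: ballots
    rng_design = np.random.default_rng(s_design)
    ballot_sets = []
    for p in profiles:
        table = ballot_design.build_candidate_table(p, config.noise_sd, rng_design)
        ballot_sets.append(
            ballot_design.generate_ballot_set(p, table, rng_design, config.n_ballots)
        )
    path = outdir / "ballots.csv"
    ballot_design.save_ballots(ballot_sets, path)
    artifacts["ballots"] = path

    # --- stage 3: trials
    trials = behavior_sim.simulate_dataset(
        profiles,
        ballot_sets,
        params_by_condition,
        design=config.design,
        seed=np.random.default_rng(s_sim),
        deadline_rate=config.deadline_rate,
    )
    path = outdir / "trials.csv"
    behavior_sim.save_trials(trials, path)
    artifacts["trials"] = path

    # --- stage 4: exclusions
    retained, exclusion_log = inference.apply_exclusions(trials)
    path = outdir / "exclusions.csv"
    exclusion_log.to_csv(path, index=False)
    artifacts["exclusions"] = path

    # --- stage 5: fits
    fits = {}
    for cond in ("selection", "rejection"):
        sub = retained[retained["condition"] == cond]
        if len(sub) == 0:
            continue
        fits[f"optout_{cond}"] = inference.OptOutModel(sub).fit().to_dict()
        fits[f"choice_{cond}"] = inference.ChoiceModel(sub).fit().to_dict()
        fits[f"rt_{cond}"] = inference.DecisionTimeModel(sub).fit().to_dict()
    if retained["condition"].nunique() == 2:
        fits["optout_combined"] = (
            inference.fit_condition_interaction(retained, "optout").to_dict()
        )
        fits["rt_combined"] = (
            inference.fit_condition_interaction(retained, "rt").to_dict()
        )
    path = outdir / "fits.json"
    path.write_text(json.dumps(fits, indent=2, sort_keys=True))
    artifacts["fits"] = path

    # --- stage 6: quartile summaries
    frames = []
    for cond in ("selection", "rejection"):
        sub = retained[retained["condition"] == cond]
        if len(sub) == 0:
            continue
        q = inference.quartile_optout_summary(sub)
        q.insert(0, "condition", cond)
        frames.append(q)
    path = outdir / "quartiles.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    artifacts["quartiles"] = path

    # --- stage 7: election scenarios
    std = elections.population_standardization(
        seed=int(s_std.generate_state(1)[0] % (2**31))
    )
    scenarios = elections.run_scenarios(
        params_by_goal=params_by_condition,
        mixes=config.election_mixes,
        standardization=std,
    )
    path = outdir / "elections.csv"
    scenarios.to_csv(path, index=False)
    artifacts["elections"] = path

    manifest = {
        "config": config.to_dict(),
        "artifacts": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
        "n_retained_participants": int(retained["participant_id"].nunique()),
        "n_excluded_participants": int(len(exclusion_log)),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
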