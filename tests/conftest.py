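import numpy as np
import pytest

from votegoal import behavior_sim, inference
from votegoal.preferences import IssueProfile, ParticipantProfile


def make_profile(stances, importances, condition="selection", pid="P001"):
    issues = tuple(
        IssueProfile(issue_id=i + 1, stance=float(s), importance_raw=float(w))
        for i, (s, w) in enumerate(zip(stances, importances))
    )
    return ParticipantProfile(pid, issues, condition)


@pytest.fixture
def ranked_profile():
    """Importances strictly decreasing with issue id: rank order == id order."""
    importances = np.linspace(3.0, -3.0, 13)
    stances = np.linspace(-3.0, 3.0, 13)
    return make_profile(stances, importances)


@pytest.fixture
def random_profile():
    return behavior_sim.generate_profiles(1, "selection", seed=11)[0]


@pytest.fixture(scope="session")
def sim_trials():
    """A small two-condition simulated study shared by inference tests."""
    params = {
        "selection": behavior_sim.SELECTION_PARAMS,
        "rejection": behavior_sim.REJECTION_PARAMS,
    }
    return inference.simulate_study(
        params, {"selection": 12, "rejection": 12}, n_ballots=100, seed=123
    )
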