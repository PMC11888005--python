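import json

import pytest

from hearsim import (
    ManualClock,
    NormativeRanges,
    ProtocolConfig,
    TechnicianNotes,
    default_name_pool,
    default_roster,
    derive_ground_truth,
    randomize_presentation,
    run_script,
    start_session,
)
from hearsim.trainee import notes_from_observations, protocol_actions


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def name_pool():
    return default_name_pool()


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def norms():
    return NormativeRanges()


@pytest.fixture(scope="session")
def roster_by_id(roster):
    return {p.id: p for p in roster}


def notes_from_truth(truth) -> TechnicianNotes:
    """Notes that copy the ground truth verbatim (the perfect answer sheet)."""
    fields = {
        f"{proc}_{side}": {"result": getattr(truth, proc)[side]}
        for proc in ("otoscopy", "tympanometry", "audiometry")
        for side in ("left", "right")
    }
    fields["final_recommendation"] = truth.recommendation.value
    return TechnicianNotes.model_validate(fields)


def run_compliant_session(base, name_pool, seed=11, protocol=None, norms=None, actions=None):
    """Script a full-protocol session on ``base`` with an ideal trainee."""
    protocol = protocol or ProtocolConfig()
    presentation = randomize_presentation(base, name_pool, seed)
    session = start_session("Test Student", presentation, seed, clock=ManualClock())
    run_script(session, actions if actions is not None else protocol_actions(protocol), close=False)
    session.save_notes(notes_from_observations(session, protocol, norms))
    session.close()
    return session


@pytest.fixture()
def demo_actions():
    from hearsim.session import load_actions
    from importlib import resources

    with resources.as_file(resources.files("hearsim").joinpath("data/demo_actions.json")) as p:
        return load_actions(p)


@pytest.fixture()
def truth_for(protocol, norms):
    def _truth(base):
        return derive_ground_truth(base, protocol, norms)

    return _truth
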