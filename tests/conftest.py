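import pytest

from afchoice import synthetic_data as sd
from afchoice.trial_model import TrialRecord, derive_encounters


@pytest.fixture(scope="session")
def forecaster_study():
    """One complete orangutan-style study from a default forecaster agent."""
    agent = sd.AgentSpec(mix_interaction_sd=0.5, seed=0)
    ds, report = sd.simulate_study(agent)
    assert report is None
    return ds


@pytest.fixture(scope="session")
def human_study():
    """A human-style study: no post-experimental pairwise phase, plus self-report."""
    agent = sd.AgentSpec(mix_interaction_sd=0.5, self_report_noise_sd=0.3, seed=1)
    return sd.simulate_study(agent, subject_species="human_style")


def make_trials(rows, phase="post_experimental", condition="not_applicable"):
    """Quickly build derived trial records from (left, right, chosen) triples."""
    trials = [
        TrialRecord(
            trial_index=i,
            phase=phase,
            condition=condition,
            left_item=left,
            right_item=right,
            chosen=chosen,
        )
        for i, (left, right, chosen) in enumerate(rows, start=1)
    ]
    counters = {}
    for t in trials:
        key = (t.phase, t.pair_key)
        counters[key] = counters.get(key, 0) + 1
        t.encounter_index = counters[key]
    return trials
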