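import numpy as np
import pytest

from rlreliability import (
    BanditConfig,
    ModelSpec,
    ParamSet,
    make_agent,
    run_bandit_session,
    run_reversal_session,
)


@pytest.fixture(scope="session")
def dual_spec():
    return ModelSpec(2, "single", "bandit")


@pytest.fixture(scope="session")
def dual_params():
    return ParamSet(tau=5.0, alpha_gain=0.7, alpha_loss=0.25)


@pytest.fixture(scope="session")
def bandit_session(dual_spec, dual_params):
    """One deterministic 160-trial bandit session from a generative agent."""
    agent = make_agent(dual_params, dual_spec, seed=11)
    return run_bandit_session(agent, BanditConfig(), seed=12)


@pytest.fixture(scope="session")
def reversal_session():
    spec = ModelSpec(2, "single", "reversal")
    params = ParamSet(tau=5.0, alpha_gain=0.7, alpha_loss=0.25)
    agent = make_agent(params, spec, seed=21)
    return run_reversal_session(agent, seed=22)


def make_trial_sequence(task, entries):
    """Hand-build a SessionData from compact per-trial tuples.

    Bandit entries: (pair_id, valence, chosen_index, reward, timed_out).
    Reversal entries: (state_label, chosen_index, reward, timed_out).
    """
    from rlreliability.tasks import SessionData, TrialRecord

    trials = []
    if task == "bandit":
        for i, (pair, valence, chosen, reward, to) in enumerate(entries):
            block = pair // 2
            slot = pair % 2
            canonical = (f"b{block}p{slot}A", f"b{block}p{slot}B")
            label = ("gain" if valence > 0 else "loss") + str(block // 2 + 1)
            trials.append(TrialRecord(
                trial_index=i, block_state=label, option_ids=canonical,
                choice=None if to else canonical[chosen], reward=0 if to else reward,
                correct_option=canonical[0], timed_out=to, pair_id=pair,
                chosen_index=-1 if to else chosen, valence=valence))
    else:
        canonical = ("circle", "square")
        for i, (label, chosen, reward, to) in enumerate(entries):
            correct = {"80/20": "circle", "20/80": "square", "50/50": None}[label]
            trials.append(TrialRecord(
                trial_index=i, block_state=label, option_ids=canonical,
                choice=None if to else canonical[chosen], reward=0 if to else reward,
                correct_option=correct, timed_out=to, pair_id=0,
                chosen_index=-1 if to else chosen, valence=0))
    n_pairs = 1 if task == "reversal" else max(t.pair_id for t in trials) + 1
    return SessionData("hand", "T1", task, trials, n_pairs=n_pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
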