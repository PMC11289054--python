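"""Generative environments for the two reinforcement-learning tasks.

Two seedable task environments are provided:

* a two-armed bandit with four gain/loss blocks in alternating (ABAB)
  order, two stimulus pairs per block with 80/20 and 70/30 congruent
  probabilistic feedback, 20 presentations per pair (160 trials);
* a probabilistic reversal-learning task with three reward states
  (80/20, 20/80, 50/50) and choice-dependent reversals, 250 trials.

Any choice-making agent implementing the :class:`Agent` protocol can be
run through either environment; the resulting :class:`SessionData` is the
common currency consumed by the behavioural metrics and model-fitting
modules, and serialises to/from a tidy CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BanditConfig",
    "ReversalConfig",
    "TrialRecord",
    "SessionData",
    "Agent",
    "RandomAgent",
    "FixedChoiceAgent",
    "run_bandit_session",
    "run_reversal_session",
    "reversal_should_switch",
    "inject_timeouts",
]

_CSV_COLUMNS = [
    "participant_id",
    "session",
    "task",
    "trial",
    "block_state",
    "option_left",
    "option_right",
    "choice",
    "reward",
    "timed_out",
]


@dataclass(frozen=True)
class BanditConfig:
    """Design of the two-armed bandit task.

    Defaults give 4 blocks x 2 pairs x 20 presentations = 160 trials.
    ``congruent_feedback_probs`` are the probabilities that feedback is
    congruent (the advantageous stimulus of the pair yields the good
    outcome) for the two pairs within every block. Gain blocks pay
    {+1, 0}, loss blocks {0, -1}.
    """

    n_blocks: int = 4
    pairs_per_block: int = 2
    congruent_feedback_probs: tuple[float, ...] = (0.8, 0.7)
    presentations_per_pair: int = 20
    timeout_rate: float = 0.0
    first_block_valence: Optional[str] = None  # "gain"/"loss"; None = random

    def __post_init__(self) -> None:
        if self.pairs_per_block != len(self.congruent_feedback_probs):
            raise ValueError("need one congruent-feedback probability per pair")
        for p in self.congruent_feedback_probs:
            # 1.0 allowed: the deterministic-feedback variant used in tests
            if not 0.0 < p <= 1.0:
                raise ValueError(f"congruent feedback probability {p} outside (0, 1]")
        if not 0.0 <= self.timeout_rate <= 1.0:
            raise ValueError("timeout_rate must lie in [0, 1]")
        if self.first_block_valence not in (None, "gain", "loss"):
            raise ValueError("first_block_valence must be 'gain', 'loss' or None")
        if min(self.n_blocks, self.pairs_per_block, self.presentations_per_pair) < 1:
            raise ValueError("counts must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.pairs_per_block * self.presentations_per_pair

    @property
    def n_pairs(self) -> int:
        return self.n_blocks * self.pairs_per_block

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "pairs_per_block": self.pairs_per_block,
            "congruent_feedback_probs": list(self.congruent_feedback_probs),
            "presentations_per_pair": self.presentations_per_pair,
            "timeout_rate": self.timeout_rate,
            "first_block_valence": self.first_block_valence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BanditConfig":
        d = dict(d)
        if "congruent_feedback_probs" in d:
            d["congruent_feedback_probs"] = tuple(d["congruent_feedback_probs"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "BanditConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ReversalConfig:
    """Design of the reversal-learning task.

    The three states are reward-probability pairs for the two stimuli.
    A reversal occurs once the participant chose the most rewarding
    option at least ``criterion_hits`` times within the last
    ``criterion_window`` trials of the current state, or after
    ``max_trials_per_state`` trials in the state. The session always
    lasts ``total_trials`` trials. Rewards are +1/-1.
    """

    states: tuple[tuple[float, float], ...] = ((0.8, 0.2), (0.2, 0.8), (0.5, 0.5))
    criterion_hits: int = 7
    criterion_window: int = 10
    max_trials_per_state: int = 16
    total_trials: int = 250
    timeout_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.states) != 3:
            raise ValueError("exactly three reward states are required")
        for pr in self.states:
            for p in pr:
                if not 0.0 <= p <= 1.0:
                    raise ValueError("state reward probabilities must lie in [0, 1]")
        if not 0.0 <= self.timeout_rate <= 1.0:
            raise ValueError("timeout_rate must lie in [0, 1]")
        if self.criterion_hits > self.criterion_window:
            raise ValueError("criterion_hits cannot exceed criterion_window")

    def to_dict(self) -> dict:
        return {
            "states": [list(s) for s in self.states],
            "criterion_hits": self.criterion_hits,
            "criterion_window": self.criterion_window,
            "max_trials_per_state": self.max_trials_per_state,
            "total_trials": self.total_trials,
            "timeout_rate": self.timeout_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReversalConfig":
        d = dict(d)
        if "states" in d:
            d["states"] = tuple(tuple(s) for s in d["states"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "ReversalConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    block_state: str
    option_ids: tuple[str, str]  # (left, right) as displayed
    choice: Optional[str]  # chosen option id; None when timed out
    reward: int  # in {-1, 0, +1}; 0 for timed-out trials
    correct_option: Optional[str]  # advantageous stimulus; None if undefined
    timed_out: bool = False
    # internal bookkeeping used by the likelihood encoder
    pair_id: int = 0  # Q-slot index (bandit: per pair; reversal: 0)
    chosen_index: int = -1  # canonical index of choice within the pair
    valence: int = 0  # +1 gain block, -1 loss block, 0 reversal


@dataclass
class SessionData:
    """One participant-session of ordered trials."""

    participant_id: str
    session_label: str  # "T1" / "T2"
    task_kind: str  # "bandit" / "reversal"
    trials: list[TrialRecord] = field(default_factory=list)
    rng_seed: Optional[int] = None
    n_pairs: int = 1  # number of Q slots (bandit pairs); 1 for reversal

    def __post_init__(self) -> None:
        if self.task_kind not in ("bandit", "reversal"):
            raise ValueError("task_kind must be 'bandit' or 'reversal'")
        for i, tr in enumerate(self.trials):
            if tr.trial_index != i:
                raise ValueError("trial_index must increase strictly from 0")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_valid_trials(self) -> int:
        return sum(not t.timed_out for t in self.trials)

    @property
    def timeout_fraction(self) -> float:
        return 0.0 if not self.trials else 1 - self.n_valid_trials / len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "participant_id": self.participant_id,
                    "session": self.session_label,
                    "task": self.task_kind,
                    "trial": t.trial_index,
                    "block_state": t.block_state,
                    "option_left": t.option_ids[0],
                    "option_right": t.option_ids[1],
                    "choice": "" if t.choice is None else t.choice,
                    "reward": t.reward,
                    "timed_out": int(t.timed_out),
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionData":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.sort_values("trial")
        pid = str(df["participant_id"].iloc[0])
        label = str(df["session"].iloc[0])
        task = str(df["task"].iloc[0])
        trials = []
        for i, row in enumerate(df.itertuples(index=False)):
            choice = None if (pd.isna(row.choice) or row.choice == "") else str(row.choice)
            trials.append(
                _rebuild_trial(
                    task,
                    i,
                    str(row.block_state),
                    (str(row.option_left), str(row.option_right)),
                    choice,
                    int(row.reward),
                    bool(int(row.timed_out)),
                )
            )
        n_pairs = 1 if task == "reversal" else len({t.pair_id for t in trials})
        return cls(pid, label, task, trials, n_pairs=max(n_pairs, 1))

    @classmethod
    def from_csv(cls, path) -> "SessionData":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


class Agent(Protocol):
    """Choice policy driven by a task environment.

    ``choose`` receives the Q-slot (stimulus-pair) index and the two
    canonical stimulus ids, and returns 0 or 1 (canonical index of the
    chosen stimulus). ``learn`` delivers the feedback of the trial.
    """

    def choose(self, pair_id: int, option_ids: tuple[str, str]) -> int: ...

    def learn(self, pair_id: int, chosen_index: int, reward: int, valence: int) -> None: ...


class RandomAgent:
    """Chooses uniformly at random; ignores feedback."""

    def __init__(self, seed: Optional[int] = None) -> None:
        self._rng = np.random.default_rng(seed)

    def choose(self, pair_id, option_ids):
        return int(self._rng.integers(2))

    def learn(self, pair_id, chosen_index, reward, valence):
        pass


class FixedChoiceAgent:
    """Always chooses the stimulus with the given canonical index."""

    def __init__(self, index: int = 0) -> None:
        self.index = index

    def choose(self, pair_id, option_ids):
        return self.index

    def learn(self, pair_id, chosen_index, reward, valence):
        pass


def _bandit_stimuli(block: int, slot: int) -> tuple[str, str]:
    # canonical order: index 0 is the advantageous stimulus of the pair
    base = f"b{block}p{slot}"
    return (base + "A", base + "B")


def _rebuild_trial(
    task: str,
    index: int,
    block_state: str,
    displayed: tuple[str, str],
    choice: Optional[str],
    reward: int,
    timed_out: bool,
) -> TrialRecord:
    """Reconstruct the internal bookkeeping fields from the CSV columns."""
    if task == "bandit":
        # stimulus ids encode block/pair/slot: "b{block}p{slot}{A|B}"
        name = displayed[0]
        block = int(name[1 : name.index("p")])
        slot = int(name[name.index("p") + 1 : -1])
        canonical = _bandit_stimuli(block, slot)
        valence = 1 if block_state.startswith("gain") else -1
        # pair ids are block-major; the generator uses 2 pairs per block
        pair_id = block * 2 + slot
        correct = canonical[0]
    else:
        canonical = ("circle", "square")
        valence = 0
        pair_id = 0
        if block_state == "80/20":
            correct = "circle"
        elif block_state == "20/80":
            correct = "square"
        else:
            correct = None
    chosen_index = -1 if choice is None else canonical.index(choice)
    return TrialRecord(
        trial_index=index,
        block_state=block_state,
        option_ids=displayed,
        choice=choice,
        reward=reward,
        correct_option=correct,
        timed_out=timed_out,
        pair_id=pair_id,
        chosen_index=chosen_index,
        valence=valence,
    )


def run_bandit_session(
    agent: Agent,
    config: BanditConfig = BanditConfig(),
    seed: Optional[int] = None,
    participant_id: str = "sim",
    session_label: str = "T1",
) -> SessionData:
    """Run an agent through one bandit session.

    Within each trial a congruency indicator is drawn with the pair's
    congruent-feedback probability. Under congruent feedback the
    advantageous stimulus yields the good outcome of the block (+1 in
    gain blocks, 0 in loss blocks) and the other stimulus the bad one;
    incongruent feedback swaps them, so the two options' outcomes are
    anti-coupled within every trial.
    """
    rng = np.random.default_rng(seed)
    if config.first_block_valence is None:
        start_gain = bool(rng.integers(2))
    else:
        start_gain = config.first_block_valence == "gain"

    trials: list[TrialRecord] = []
    index = 0
    gain_count = 0
    loss_count = 0
    for block in range(config.n_blocks):
        gain = start_gain if block % 2 == 0 else not start_gain
        if gain:
            gain_count += 1
            valence_label = f"gain{gain_count}"
        else:
            loss_count += 1
            valence_label = f"loss{loss_count}"
        # interleave the block's pairs in seeded random order
        slots = np.repeat(np.arange(config.pairs_per_block), config.presentations_per_pair)
        rng.shuffle(slots)
        for slot in slots:
            slot = int(slot)
            pair_id = block * config.pairs_per_block + slot
            canonical = _bandit_stimuli(block, slot)
            flip = bool(rng.integers(2))
            displayed = (canonical[1], canonical[0]) if flip else canonical
            timed_out = bool(rng.random() < config.timeout_rate)
            if timed_out:
                trials.append(
                    TrialRecord(index, valence_label, displayed, None, 0, canonical[0],
                                True, pair_id, -1, 1 if gain else -1)
                )
                index += 1
                continue
            chosen = int(agent.choose(pair_id, canonical))
            if chosen not in (0, 1):
                raise ValueError("agent returned an option not on offer")
            congruent = bool(rng.random() < config.congruent_feedback_probs[slot])
            # chose advantageous (index 0) and congruent -> good outcome
            good = (chosen == 0) == congruent
            if gain:
                reward = 1 if good else 0
            else:
                reward = 0 if good else -1
            valence = 1 if gain else -1
            agent.learn(pair_id, chosen, reward, valence)
            trials.append(
                TrialRecord(index, valence_label, displayed, canonical[chosen], reward,
                            canonical[0], False, pair_id, chosen, valence)
            )
            index += 1
    return SessionData(participant_id, session_label, "bandit", trials,
                       rng_seed=seed, n_pairs=config.n_pairs)


def reversal_should_switch(state_history: Sequence[bool], config: ReversalConfig = ReversalConfig()) -> bool:
    """Decide whether the current reward state should reverse.

    ``state_history`` holds, for each trial since the last reversal, a
    flag for whether the most-rewarding option was chosen. A reversal
    occurs when at least ``criterion_hits`` of the last
    ``min(criterion_window, n)`` flags are true, or when the state has
    lasted ``max_trials_per_state`` trials.
    """
    n = len(state_history)
    if n == 0:
        return False
    if n >= config.max_trials_per_state:
        return True
    window = list(state_history)[-config.criterion_window:]
    return sum(window) >= config.criterion_hits


def run_reversal_session(
    agent: Agent,
    config: ReversalConfig = ReversalConfig(),
    seed: Optional[int] = None,
    participant_id: str = "sim",
    session_label: str = "T1",
) -> SessionData:
    """Run an agent through one reversal-learning session.

    The session starts in one of the two asymmetric states (chosen at
    random); after each reversal the next state is drawn uniformly from
    the two states other than the current one. In the 50/50 state the
    "most rewarding" stimulus for the switch rule is the one that had
    reward probability 0.2 in the preceding state.
    """
    rng = np.random.default_rng(seed)
    canonical = ("circle", "square")
    state_labels = []
    for pr in config.states:
        state_labels.append(f"{int(round(pr[0] * 100))}/{int(round(pr[1] * 100))}")

    asym = [i for i, pr in enumerate(config.states) if pr[0] != pr[1]]
    state = int(rng.choice(asym)) if asym else 0
    prev_state = None
    history: list[bool] = []
    trials: list[TrialRecord] = []
    for index in range(config.total_trials):
        probs = config.states[state]
        if probs[0] > probs[1]:
            best = 0
        elif probs[1] > probs[0]:
            best = 1
        else:
            # most-rewarding for the switch rule: the stimulus that was
            # least rewarding in the preceding state
            prev = config.states[prev_state] if prev_state is not None else None
            best = (0 if prev[0] < prev[1] else 1) if prev is not None else 0
        correct = canonical[best] if probs[0] != probs[1] else None

        timed_out = bool(rng.random() < config.timeout_rate)
        if timed_out:
            trials.append(TrialRecord(index, state_labels[state], canonical, None, 0,
                                      correct, True, 0, -1, 0))
        else:
            chosen = int(agent.choose(0, canonical))
            if chosen not in (0, 1):
                raise ValueError("agent returned an option not on offer")
            reward = 1 if rng.random() < probs[chosen] else -1
            agent.learn(0, chosen, reward, 0)
            trials.append(TrialRecord(index, state_labels[state], canonical,
                                      canonical[chosen], reward, correct, False, 0, chosen, 0))
            history.append(chosen == best)
        if reversal_should_switch(history, config):
            others = [s for s in range(len(config.states)) if s != state]
            prev_state, state = state, int(rng.choice(others))
            history = []
    return SessionData(participant_id, session_label, "reversal", trials,
                       rng_seed=seed, n_pairs=1)


def inject_timeouts(session: SessionData, rate: float, seed: Optional[int] = None) -> SessionData:
    """Return a copy of the session with trials timed out i.i.d. at ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_trials = []
    for t in session.trials:
        if not t.timed_out and rng.random() < rate:
            t = replace(t, timed_out=True, choice=None, reward=0, chosen_index=-1)
        new_trials.append(t)
    return SessionData(session.participant_id, session.session_label, session.task_kind,
                       new_trials, rng_seed=session.rng_seed, n_pairs=session.n_pairs)
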