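"""Rescorla-Wagner model variants: value updating, softmax choice, likelihood.

The model space crosses the number of learning rates (one, or separate
``alpha_gain``/``alpha_loss``) with the update rule (chosen option only,
full double updating of the unchosen option, or ``kappa``-weighted double
updating), giving six variants. Values ``Q`` start at zero, prediction
errors are ``delta = r - Q_chosen``, and choices follow a logistic
softmax with inverse temperature ``tau`` in [0, 20].

For double updating the unchosen option's counterfactual reward is
recoded task-specifically: in the bandit it is block-wise piecewise
(``r_chosen = 0`` in a gain block maps to +1, ``r_chosen = +/-1`` maps to
0, ``r_chosen = 0`` in a loss block maps to -1); in the reversal task it
is simply ``-r_chosen``.

The trial-by-trial likelihood replay is compiled with numba; a batched
variant evaluates many (session, parameter-set) lanes at once and is the
workhorse of the hierarchical sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .tasks import SessionData

__all__ = [
    "ModelSpec",
    "ParamSet",
    "QState",
    "choice_prob",
    "update",
    "negative_log_likelihood",
    "make_agent",
    "RWAgent",
    "encode_session",
    "MODEL_SPECS",
]

TAU_MAX = 20.0
PROB_FLOOR = 1e-12

_UPDATE_RULES = ("single", "full_du", "kappa_du")
_GATINGS = ("pe_sign", "reward_sign")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model variants, bound to a task.

    ``task_kind`` governs the counterfactual-reward recoding of the
    double-update rules and which sessions the model may be fit to.
    """

    n_learning_rates: int = 1
    update_rule: str = "single"
    task_kind: str = "bandit"

    def __post_init__(self) -> None:
        if self.n_learning_rates not in (1, 2):
            raise ValueError("n_learning_rates must be 1 or 2")
        if self.update_rule not in _UPDATE_RULES:
            raise ValueError(f"update_rule must be one of {_UPDATE_RULES}")
        if self.task_kind not in ("bandit", "reversal"):
            raise ValueError("task_kind must be 'bandit' or 'reversal'")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["tau"]
        if self.n_learning_rates == 1:
            names.append("alpha")
        else:
            names.extend(["alpha_gain", "alpha_loss"])
        if self.update_rule == "kappa_du":
            names.append("kappa")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple((0.0, TAU_MAX) if n == "tau" else (0.0, 1.0) for n in self.param_names)

    @property
    def name(self) -> str:
        lr = "simple" if self.n_learning_rates == 1 else "dual"
        rule = {"single": "rl", "full_du": "rl_du", "kappa_du": "rl_kdu"}[self.update_rule]
        return f"{lr}_{rule}"


#: All six variants for a given task, keyed by their short name.
def MODEL_SPECS(task_kind: str = "bandit") -> dict[str, ModelSpec]:
    specs = {}
    for n_lr in (1, 2):
        for rule in _UPDATE_RULES:
            s = ModelSpec(n_lr, rule, task_kind)
            specs[s.name] = s
    return specs


@dataclass(frozen=True)
class ParamSet:
    """Free parameters of a model variant; unused fields stay None."""

    tau: float
    alpha: Optional[float] = None
    alpha_gain: Optional[float] = None
    alpha_loss: Optional[float] = None
    kappa: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= TAU_MAX:
            raise ValueError(f"tau={self.tau} outside [0, {TAU_MAX}]")
        for name in ("alpha", "alpha_gain", "alpha_loss", "kappa"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        vals = []
        for name in spec.param_names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"parameter {name} required by {spec.name} is missing")
            vals.append(v)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_vector(cls, x: np.ndarray, spec: ModelSpec) -> "ParamSet":
        return cls(**dict(zip(spec.param_names, map(float, x))))

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def effective(self, spec: ModelSpec) -> tuple[float, float, float, float, bool]:
        """(tau, a_gain, a_loss, kappa, double_update) for the kernel."""
        if spec.n_learning_rates == 1:
            a_gain = a_loss = self.alpha
        else:
            a_gain, a_loss = self.alpha_gain, self.alpha_loss
        if spec.update_rule == "single":
            return self.tau, a_gain, a_loss, 0.0, False
        kappa = 1.0 if spec.update_rule == "full_du" else self.kappa
        return self.tau, a_gain, a_loss, kappa, True


@dataclass
class QState:
    """Option values per active stimulus pair, initialised at zero."""

    q: np.ndarray  # shape (n_pairs, 2)

    @classmethod
    def zeros(cls, n_pairs: int = 1) -> "QState":
        return cls(np.zeros((n_pairs, 2)))

    def copy(self) -> "QState":
        return QState(self.q.copy())


def choice_prob(q_left: float, q_right: float, tau: float) -> float:
    """Softmax probability of choosing the left option."""
    return 1.0 / (1.0 + math.exp(-tau * (q_left - q_right)))


def _recode_unchosen(reward: int, valence: int, bandit: bool) -> float:
    if not bandit:
        return -float(reward)
    if reward == 0:
        return 1.0 if valence > 0 else -1.0
    return 0.0


def update(
    q: QState,
    choice: int,
    reward: int,
    params: ParamSet,
    spec: ModelSpec,
    block_valence: int = 0,
    pair_id: int = 0,
    gating: str = "pe_sign",
) -> QState:
    """One value-update step; returns a new QState.

    ``block_valence`` is +1 for bandit gain blocks, -1 for loss blocks
    and ignored for the reversal task. With two learning rates the rate
    is gated by prediction-error sign by default (``alpha_gain`` when
    ``delta >= 0``), applied separately to the unchosen update.
    """
    if reward not in (-1, 0, 1):
        raise ValueError("reward must be in {-1, 0, +1}")
    if gating not in _GATINGS:
        raise ValueError(f"gating must be one of {_GATINGS}")
    tau, a_gain, a_loss, kappa, du = params.effective(spec)
    out = q.copy()
    u = 1 - choice
    delta = reward - out.q[pair_id, choice]
    if gating == "pe_sign":
        alpha = a_gain if delta >= 0 else a_loss
    else:
        alpha = a_gain if _positive_feedback(reward, block_valence, spec.task_kind) else a_loss
    out.q[pair_id, choice] += alpha * delta
    if du:
        r_u = _recode_unchosen(reward, block_valence, spec.task_kind == "bandit")
        delta_u = r_u - out.q[pair_id, u]
        if gating == "pe_sign":
            alpha_u = a_gain if delta_u >= 0 else a_loss
        else:
            alpha_u = alpha
        out.q[pair_id, u] += kappa * alpha_u * delta_u
    return out


def _positive_feedback(reward: int, valence: int, task_kind: str) -> bool:
    if task_kind == "bandit":
        return reward == (1 if valence > 0 else 0)
    return reward == 1


@dataclass(frozen=True)
class EncodedSession:
    """Array view of a session consumed by the compiled likelihood."""

    pair_id: np.ndarray
    chosen: np.ndarray
    reward: np.ndarray
    valence: np.ndarray
    timed_out: np.ndarray
    n_pairs: int
    n_valid: int


def encode_session(session: SessionData) -> EncodedSession:
    n = len(session.trials)
    pair_id = np.zeros(n, dtype=np.int64)
    chosen = np.zeros(n, dtype=np.int64)
    reward = np.zeros(n, dtype=np.int64)
    valence = np.zeros(n, dtype=np.int64)
    timed_out = np.zeros(n, dtype=np.bool_)
    for i, t in enumerate(session.trials):
        pair_id[i] = t.pair_id
        chosen[i] = t.chosen_index
        reward[i] = t.reward
        valence[i] = t.valence
        timed_out[i] = t.timed_out
    return EncodedSession(pair_id, chosen, reward, valence, timed_out,
                          session.n_pairs, int((~timed_out).sum()))


@njit(cache=True)
def _nll_core(pair_id, chosen, reward, valence, timed_out, n_pairs,
              tau, a_gain, a_loss, kappa, du, bandit, gate_reward_sign):
    q = np.zeros((n_pairs, 2))
    nll = 0.0
    for t in range(pair_id.shape[0]):
        if timed_out[t]:
            continue
        p = pair_id[t]
        c = chosen[t]
        u = 1 - c
        pc = 1.0 / (1.0 + math.exp(-tau * (q[p, c] - q[p, u])))
        if pc < PROB_FLOOR:
            pc = PROB_FLOOR
        nll -= math.log(pc)
        r = float(reward[t])
        delta = r - q[p, c]
        if gate_reward_sign:
            if bandit:
                pos = reward[t] == (1 if valence[t] > 0 else 0)
            else:
                pos = reward[t] == 1
            alpha = a_gain if pos else a_loss
        else:
            alpha = a_gain if delta >= 0.0 else a_loss
        q[p, c] += alpha * delta
        if du:
            if bandit:
                if reward[t] == 0:
                    r_u = 1.0 if valence[t] > 0 else -1.0
                else:
                    r_u = 0.0
            else:
                r_u = -r
            delta_u = r_u - q[p, u]
            if gate_reward_sign:
                alpha_u = alpha
            else:
                alpha_u = a_gain if delta_u >= 0.0 else a_loss
            q[p, u] += kappa * alpha_u * delta_u
    return nll


@njit(cache=True)
def _nll_batch_core(pair_id, chosen, reward, valence, timed_out, n_pairs,
                    tau, a_gain, a_loss, kappa, du, bandit, gate_reward_sign):
    n = tau.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _nll_core(pair_id[i], chosen[i], reward[i], valence[i], timed_out[i],
                           n_pairs, tau[i], a_gain[i], a_loss[i], kappa[i],
                           du, bandit, gate_reward_sign)
    return out


def negative_log_likelihood(
    params: ParamSet,
    session: SessionData | EncodedSession,
    spec: ModelSpec,
    gating: str = "pe_sign",
) -> float:
    """Negative log likelihood of the observed choices under a model.

    Timed-out trials are skipped. Q values reset to zero for every new
    bandit pair; the reversal task keeps one persistent pair across
    reversals. Choice probabilities are floored at 1e-12 before the log.
    """
    enc = session if isinstance(session, EncodedSession) else encode_session(session)
    if enc.n_valid == 0:
        raise ValueError("session has no valid (non-timed-out) trials")
    if gating not in _GATINGS:
        raise ValueError(f"gating must be one of {_GATINGS}")
    tau, a_gain, a_loss, kappa, du = params.effective(spec)
    return float(
        _nll_core(enc.pair_id, enc.chosen, enc.reward, enc.valence, enc.timed_out,
                  enc.n_pairs, tau, a_gain, a_loss, kappa, du,
                  spec.task_kind == "bandit", gating == "reward_sign")
    )


def nll_vector(x: np.ndarray, enc: EncodedSession, spec: ModelSpec, gating: str = "pe_sign") -> float:
    """Likelihood on a raw parameter vector (optimizer objective)."""
    tau = x[0]
    if spec.n_learning_rates == 1:
        a_gain = a_loss = x[1]
        k_idx = 2
    else:
        a_gain, a_loss = x[1], x[2]
        k_idx = 3
    if spec.update_rule == "single":
        kappa, du = 0.0, False
    elif spec.update_rule == "full_du":
        kappa, du = 1.0, True
    else:
        kappa, du = x[k_idx], True
    return float(
        _nll_core(enc.pair_id, enc.chosen, enc.reward, enc.valence, enc.timed_out,
                  enc.n_pairs, tau, a_gain, a_loss, kappa, du,
                  spec.task_kind == "bandit", gating == "reward_sign")
    )


class RWAgent:
    """Generative agent: softmax choice from its Q values, then update.

    Composing this agent with a task environment reproduces the model's
    generative process exactly (same equations as the likelihood).
    """

    def __init__(self, params: ParamSet, spec: ModelSpec,
                 seed: Optional[int] = None, gating: str = "pe_sign") -> None:
        self.params = params
        self.spec = spec
        self.gating = gating
        self._rng = np.random.default_rng(seed)
        self._q: dict[int, QState] = {}

    def _slot(self, pair_id: int) -> QState:
        if pair_id not in self._q:
            self._q[pair_id] = QState.zeros(1)
        return self._q[pair_id]

    def choose(self, pair_id: int, option_ids) -> int:
        q = self._slot(pair_id).q
        p0 = choice_prob(q[0, 0], q[0, 1], self.params.tau)
        return 0 if self._rng.random() < p0 else 1

    def learn(self, pair_id: int, chosen_index: int, reward: int, valence: int) -> None:
        self._q[pair_id] = update(self._slot(pair_id), chosen_index, reward,
                                  self.params, self.spec, valence, 0, self.gating)


def make_agent(params: ParamSet, spec: ModelSpec, seed: Optional[int] = None,
               gating: str = "pe_sign") -> RWAgent:
    """Build the generative choice policy for a parameter set."""
    params.to_vector(spec)  # validates completeness for the spec
    return RWAgent(params, spec, seed=seed, gating=gating)
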