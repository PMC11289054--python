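"""Model-free behavioural measures and the participant-exclusion pipeline.

Accuracy, win-stay and lose-shift are the three standard summary
measures. Timed-out trials, and reversal trials in the 50/50 state, are
excluded from accuracy. Feedback valence is block-relative in the
bandit task (gain block: +1 is positive, 0 negative; loss block: 0 is
positive — an avoided loss — and -1 negative) and sign-based in the
reversal task. Win-stay/lose-shift transitions are computed within a
stimulus pair (consecutive presentations of the same pair), since
"same stimulus" is undefined across bandit pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .tasks import SessionData

__all__ = [
    "BehaviorSummary",
    "accuracy",
    "win_stay",
    "lose_shift",
    "behavior_summary",
    "apply_exclusions",
    "summaries_to_frame",
]

#: Exclusion thresholds: timeout fraction above 20% or accuracy below 55%.
MAX_TIMEOUT_FRACTION = 0.20
MIN_ACCURACY = 0.55


@dataclass(frozen=True)
class BehaviorSummary:
    participant_id: str
    session_label: str
    accuracy: float          # NaN when undefined
    win_stay: float
    lose_shift: float
    n_valid_trials: int
    timeout_fraction: float
    valid_id: bool = True


def accuracy(session: SessionData) -> float:
    """Fraction of eligible trials where the advantageous stimulus was chosen.

    Timed-out trials and trials without a defined advantageous stimulus
    (the reversal 50/50 state) are excluded; NaN if nothing remains.
    """
    if not session.trials:
        raise ValueError("empty session")
    hits = total = 0
    for t in session.trials:
        if t.timed_out or t.correct_option is None:
            continue
        total += 1
        hits += t.choice == t.correct_option
    return hits / total if total else math.nan


def _positive(reward: int, valence: int, task_kind: str) -> bool:
    if task_kind == "bandit":
        return reward == (1 if valence > 0 else 0)
    return reward == 1


def _transitions(session: SessionData):
    """Yield (prev, cur) pairs of consecutive same-pair non-timed-out trials."""
    last_by_pair: dict[int, object] = {}
    for t in session.trials:
        if t.timed_out:
            # a timeout breaks the transition chain of its pair
            last_by_pair.pop(t.pair_id, None)
            continue
        prev = last_by_pair.get(t.pair_id)
        if prev is not None:
            yield prev, t
        last_by_pair[t.pair_id] = t


def _stay_shift(session: SessionData, after_positive: bool) -> float:
    if len(session.trials) < 2:
        raise ValueError("need at least two trials")
    num = den = 0
    for prev, cur in _transitions(session):
        if _positive(prev.reward, prev.valence, session.task_kind) != after_positive:
            continue
        den += 1
        same = cur.choice == prev.choice
        num += same if after_positive else not same
    return num / den if den else math.nan


def win_stay(session: SessionData) -> float:
    """P(repeat previous choice | previous feedback positive)."""
    return _stay_shift(session, after_positive=True)


def lose_shift(session: SessionData) -> float:
    """P(switch choice | previous feedback negative)."""
    return _stay_shift(session, after_positive=False)


def behavior_summary(session: SessionData, valid_id: bool = True) -> BehaviorSummary:
    return BehaviorSummary(
        participant_id=session.participant_id,
        session_label=session.session_label,
        accuracy=accuracy(session),
        win_stay=win_stay(session),
        lose_shift=lose_shift(session),
        n_valid_trials=session.n_valid_trials,
        timeout_fraction=session.timeout_fraction,
        valid_id=valid_id,
    )


def apply_exclusions(
    summaries_t1: dict[str, BehaviorSummary],
    summaries_t2: dict[str, BehaviorSummary],
    id_validity: Optional[dict[str, bool]] = None,
) -> tuple[list[str], dict[str, int]]:
    """Retain participants passing all inclusion rules at both sessions.

    Rules per session: timeout fraction <= 20%, overall accuracy >= 55%,
    valid participant id (an external flag standing in for free-text
    misunderstanding checks). Only "returners" — present and passing at
    both sessions — are retained. Returns the retained ids (sorted) and
    per-rule exclusion counts.
    """
    counts = {"invalid_id": 0, "timeout": 0, "low_accuracy": 0, "not_returner": 0,
              "retained": 0}
    retained = []
    all_ids = sorted(set(summaries_t1) | set(summaries_t2))
    for pid in all_ids:
        s1 = summaries_t1.get(pid)
        s2 = summaries_t2.get(pid)
        if s1 is None or s2 is None:
            counts["not_returner"] += 1
            continue
        ok = True
        if id_validity is not None and not id_validity.get(pid, True):
            counts["invalid_id"] += 1
            ok = False
        if not (s1.valid_id and s2.valid_id):
            if id_validity is None or id_validity.get(pid, True):
                counts["invalid_id"] += 1
            ok = False
        if s1.timeout_fraction > MAX_TIMEOUT_FRACTION or s2.timeout_fraction > MAX_TIMEOUT_FRACTION:
            counts["timeout"] += 1
            ok = False
        if not (s1.accuracy >= MIN_ACCURACY and s2.accuracy >= MIN_ACCURACY):
            counts["low_accuracy"] += 1
            ok = False
        if ok:
            retained.append(pid)
    counts["retained"] = len(retained)
    return retained, counts


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tidy (participant, session, measure, value) table."""
    rows = []
    for s in summaries:
        for measure in ("accuracy", "win_stay", "lose_shift", "timeout_fraction"):
            rows.append({"participant": s.participant_id, "session": s.session_label,
                         "measure": measure, "value": getattr(s, measure)})
    return pd.DataFrame(rows)


def exclusion_report_json(counts: dict[str, int]) -> str:
    return json.dumps(counts, indent=2, sort_keys=True)
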