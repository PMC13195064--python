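"""Randomised construction of forced-choice matching sessions.

Each trial shows two Czech words and the two foreign translations; the
participant matches them.  A session for a 68-concept lexicon has 34 trials:
an independent random perfect matching of the concepts into pairs, shuffled
trial order, and inversion flags (foreign pair displayed in reversed order,
making the correct mapping diagonal) balanced exactly within the session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .lexicon_io import StudyLexicon, WordRecord

__all__ = ["Trial", "Session", "build_sessions", "score_response"]


@dataclass(frozen=True)
class Trial:
    """Two concepts shown together; ``inverse=1`` means the foreign pair is
    displayed in reversed order (correct mapping is diagonal on screen)."""

    czech_pair: tuple[WordRecord, WordRecord]
    foreign_pair: tuple[WordRecord, WordRecord]
    inverse: int
    order_index: int

    def __post_init__(self):
        cz = {w.concept_id for w in self.czech_pair}
        fo = {w.concept_id for w in self.foreign_pair}
        if cz != fo:
            raise ValidationError(
                "foreign pair must be the translations of the Czech pair"
            )
        if len(cz) != 2:
            raise ValidationError("the two concepts of a trial must differ")
        if self.inverse not in (0, 1):
            raise ValidationError("inverse flag must be 0 or 1")


@dataclass(frozen=True)
class Session:
    """One participant's ordered list of trials."""

    participant_id: str
    trials: tuple[Trial, ...]
    seed: int

    def __post_init__(self):
        seen: list[str] = []
        for t in self.trials:
            seen.extend(w.concept_id for w in t.czech_pair)
        if len(seen) != len(set(seen)):
            raise ValidationError("a concept appears in more than one trial")


def build_sessions(
    lexicon: StudyLexicon,
    n_participants: int,
    seed: int,
    exact_balance: bool = True,
) -> list[Session]:
    """Build one randomised session per participant.

    Concepts are paired by an independent uniform random perfect matching
    per participant; trial order is shuffled; half of the trials (exactly,
    by default, or by independent coin flips with ``exact_balance=False``)
    are inverted.  Fully reproducible from ``seed``.
    """
    records = list(lexicon.records)
    n = len(records)
    if n < 2 or n % 2:
        raise ValidationError(f"need an even number of concepts >= 2, got {n}")
    n_trials = n // 2
    sessions = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_participants)
    for p in range(n_participants):
        rng = np.random.default_rng(child_seeds[p])
        perm = rng.permutation(n)
        inverses = np.zeros(n_trials, dtype=int)
        if exact_balance:
            inverses[rng.choice(n_trials, n_trials // 2, replace=False)] = 1
        else:
            inverses = rng.integers(0, 2, n_trials)
        trials = []
        for t in range(n_trials):
            w1, w2 = records[perm[2 * t]], records[perm[2 * t + 1]]
            trials.append(Trial(
                czech_pair=(w1, w2),
                foreign_pair=(w2, w1) if inverses[t] else (w1, w2),
                inverse=int(inverses[t]),
                order_index=t,
            ))
        sessions.append(Session(
            participant_id=f"p{p:04d}",
            trials=tuple(trials),
            seed=seed,
        ))
    return sessions


def score_response(trial: Trial, chosen_diagonal: int) -> int:
    """1 if the chosen mapping (diagonal vs vertical) is the true one.

    Choosing the diagonal mapping is correct exactly on inverse trials.
    """
    return int(chosen_diagonal == trial.inverse)
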