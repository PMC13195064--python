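"""Trial-level predictors for the matching task.

Every trial shows two concepts; its predictors quantify the cues a
participant could exploit:

* **length agreement** LA(C1,C2,T1,T2) = sign((C1-C2)(T1-T2)) *
  sqrt(|(C1-C2)(T1-T2)|) — the signed geometric mean of the two
  within-language phoneme-count differences.  Zero when either language's
  pair has equal lengths; negative when the length differences point in
  opposite directions (a confusing configuration);
* **frequency (log) agreement** — the same functional form on natural-log
  corpus frequencies;
* **phonological similarity** PS = Dist(C1,T2) + Dist(C2,T1) - Dist(C1,T1)
  - Dist(C2,T2), computed once with the feature-weighted edit distance and
  once with the 12-feature vector distance; positive when the true mapping
  is phonologically closer than the crossed one;
* **cognate score** of the pair (sum of the two words' codings),
  **part-of-speech mismatch**, **semantic distance** (Euclidean distance of
  the two *Czech* words' embeddings), and the design variables **inverse
  trial** and **trial order**.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PredictorUnavailableError, ValidationError
from .experiment_design import Session, Trial
from .lexicon_io import WordRecord
from .phonodistance import (
    SegmentFeatureTable,
    feature_edit_distance,
    load_default_table,
    vector_distance,
    word_feature_vector,
)

__all__ = [
    "TrialPredictors",
    "length_agreement",
    "logfreq_agreement",
    "phonological_similarity",
    "cognate_pair_score",
    "pos_mismatch",
    "semantic_distance",
    "trial_predictors",
    "predictor_frame",
    "standardize_predictors",
    "Standardization",
    "PREDICTOR_NAMES",
]


@dataclass(frozen=True)
class TrialPredictors:
    """The covariate vector of one trial."""

    cognate: float
    pos_mismatch: float
    semantic_distance: float
    edit_phon_similarity: float
    vector_phon_similarity: float
    length_agreement: float
    logfreq_agreement: float
    inverse_trial: int
    trial_order: int

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(float(v)):
                raise ValidationError(f"non-finite predictor {f.name}")
        if self.inverse_trial not in (0, 1):
            raise ValidationError("inverse_trial must be 0 or 1")


PREDICTOR_NAMES = tuple(f.name for f in dc_fields(TrialPredictors))


def _signed_agreement(c1: float, c2: float, t1: float, t2: float) -> float:
    prod = (c1 - c2) * (t1 - t2)
    return math.copysign(math.sqrt(abs(prod)), prod) if prod else 0.0


def length_agreement(c1_len: int, c2_len: int, t1_len: int, t2_len: int) -> float:
    """Signed geometric mean of the within-language length differences."""
    return _signed_agreement(c1_len, c2_len, t1_len, t2_len)


def logfreq_agreement(c1_lf: float, c2_lf: float, t1_lf: float, t2_lf: float) -> float:
    """Length-agreement functional form on log corpus frequencies."""
    return _signed_agreement(c1_lf, c2_lf, t1_lf, t2_lf)


def phonological_similarity(
    d_c1t1: float, d_c1t2: float, d_c2t1: float, d_c2t2: float
) -> float:
    """Crossed-minus-matched distance sum; positive when matched pairs are
    closer than crossed pairs."""
    return d_c1t2 + d_c2t1 - d_c1t1 - d_c2t2


def cognate_pair_score(w1: WordRecord, w2: WordRecord) -> float:
    """Sum of the two words' cognacy codings."""
    return w1.cognate_score + w2.cognate_score


def pos_mismatch(w1: WordRecord, w2: WordRecord) -> int:
    """1 iff the two words belong to different word classes."""
    if not w1.pos or not w2.pos:
        raise PredictorUnavailableError("part-of-speech label missing")
    return int(w1.pos != w2.pos)


def semantic_distance(w1: WordRecord, w2: WordRecord, normalize: bool = False) -> float:
    """Euclidean distance between the two Czech words' embeddings."""
    if w1.embedding is None or w2.embedding is None:
        raise PredictorUnavailableError(
            f"embedding missing for {w1.concept_id!r} or {w2.concept_id!r}"
        )
    a = np.asarray(w1.embedding, float)
    b = np.asarray(w2.embedding, float)
    if a.shape != b.shape:
        raise ValidationError("embedding dimensions differ")
    if normalize:
        a = a / np.linalg.norm(a)
        b = b / np.linalg.norm(b)
    return float(np.linalg.norm(a - b))


def trial_predictors(
    trial: Trial,
    table: SegmentFeatureTable | None = None,
) -> TrialPredictors:
    """Compute the full covariate vector for one trial.

    Distances use the Czech pair in presentation order against the
    translations in their *concept* pairing (the display inversion does not
    change which word translates which).
    """
    table = table or load_default_table()
    w1, w2 = trial.czech_pair
    d = {
        (i, j): feature_edit_distance(a.czech_ipa, b.foreign_ipa, table)
        for i, a in enumerate((w1, w2))
        for j, b in enumerate((w1, w2))
    }
    v = {w.concept_id: word_feature_vector(w.czech_ipa, table) for w in (w1, w2)}
    vf = {w.concept_id: word_feature_vector(w.foreign_ipa, table) for w in (w1, w2)}
    dv = {
        (i, j): vector_distance(v[a.concept_id], vf[b.concept_id])
        for i, a in enumerate((w1, w2))
        for j, b in enumerate((w1, w2))
    }
    return TrialPredictors(
        cognate=cognate_pair_score(w1, w2),
        pos_mismatch=pos_mismatch(w1, w2),
        semantic_distance=semantic_distance(w1, w2),
        edit_phon_similarity=phonological_similarity(
            d[(0, 0)], d[(0, 1)], d[(1, 0)], d[(1, 1)]
        ),
        vector_phon_similarity=phonological_similarity(
            dv[(0, 0)], dv[(0, 1)], dv[(1, 0)], dv[(1, 1)]
        ),
        length_agreement=length_agreement(
            w1.czech_len, w2.czech_len, w1.foreign_len, w2.foreign_len
        ),
        logfreq_agreement=logfreq_agreement(
            w1.czech_logfreq, w2.czech_logfreq,
            w1.foreign_logfreq, w2.foreign_logfreq,
        ),
        inverse_trial=trial.inverse,
        trial_order=trial.order_index,
    )


def predictor_frame(
    sessions: Iterable[Session],
    table: SegmentFeatureTable | None = None,
) -> pd.DataFrame:
    """One row per (participant, trial) with all predictors.

    Identical concept pairs are computed once and reused across sessions.
    """
    table = table or load_default_table()
    cache: dict[tuple[str, str], TrialPredictors] = {}
    rows = []
    for s in sessions:
        for t in s.trials:
            key = (t.czech_pair[0].concept_id, t.czech_pair[1].concept_id)
            base = cache.get(key)
            if base is None:
                base = trial_predictors(t, table)
                cache[key] = base
            row = {name: getattr(base, name) for name in PREDICTOR_NAMES}
            row["inverse_trial"] = t.inverse
            row["trial_order"] = t.order_index
            row["participant_id"] = s.participant_id
            row["session_trial_index"] = t.order_index
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Standardization:
    """Centering/scaling used on a predictor table, kept so a fit can be
    mapped back to the raw scale."""

    means: dict[str, float]
    sds: dict[str, float]

    def unstandardize(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c, m in self.means.items():
            out[c] = out[c] * self.sds[c] + m
        return out


def standardize_predictors(
    df: pd.DataFrame,
    columns: Sequence[str] = PREDICTOR_NAMES,
) -> tuple[pd.DataFrame, Standardization]:
    """Center each covariate to mean 0 and scale to unit (ddof=0) variance,
    within one language dataset.  Raises for constant columns."""
    out = df.copy()
    means, sds = {}, {}
    for c in columns:
        x = df[c].to_numpy(float)
        m, s = float(x.mean()), float(x.std())
        if s == 0.0:
            raise ValidationError(f"zero-variance covariate {c!r}")
        out[c] = (x - m) / s
        means[c], sds[c] = m, s
    return out, Standardization(means, sds)
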