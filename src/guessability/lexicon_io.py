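"""Reading and writing study lexicons, response logs and configuration.

Formats are UTF-8 delimited text.  Lexicons are tab-separated (transliterated
forms may contain commas next to diacritics; tabs are safer); response logs
are comma-separated.  IPA is normalised to NFC on input.  Validation is
strict: bad rows raise with their row number, nothing is dropped silently.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ParseError,
    ReferentialError,
    SchemaError,
    ValidationError,
)
from .phonodistance import SegmentFeatureTable, load_default_table, segment_ipa

__all__ = [
    "WordRecord",
    "StudyLexicon",
    "ResponseRecord",
    "read_lexicon",
    "write_lexicon",
    "read_responses",
    "write_responses",
    "read_config",
]

LEXICON_COLUMNS = [
    "concept_id", "czech_form", "foreign_form", "czech_ipa", "foreign_ipa",
    "czech_len", "foreign_len", "czech_logfreq", "foreign_logfreq",
    "pos", "cognate_score", "embedding",
]

RESPONSE_COLUMNS = [
    "participant_id", "session_trial_index", "concept_id_1", "concept_id_2",
    "inverse", "correct", "age", "gender",
]


@dataclass(frozen=True)
class WordRecord:
    """One concept in one language pair.

    ``cognate_score`` is the per-word cognacy coding (1 full, 0.5 partial,
    0 none; other values in [0, 1] permitted).  ``embedding`` is the Czech
    word embedding used for semantic distance; optional.
    """

    concept_id: str
    czech_form: str
    foreign_form: str
    czech_ipa: str
    foreign_ipa: str
    czech_len: int
    foreign_len: int
    czech_logfreq: float
    foreign_logfreq: float
    pos: str
    cognate_score: float = 0.0
    embedding: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.czech_len < 0 or self.foreign_len < 0:
            raise ValidationError(f"{self.concept_id}: negative phoneme count")
        if not 0.0 <= self.cognate_score <= 1.0:
            raise ValidationError(
                f"{self.concept_id}: cognate_score {self.cognate_score} outside [0, 1]"
            )


@dataclass(frozen=True)
class StudyLexicon:
    """An ordered collection of WordRecords for one language pair."""

    language_pair: str
    records: tuple[WordRecord, ...]

    def __post_init__(self):
        ids = [r.concept_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate concept_id(s): {sorted(dupes)}")
        dims = {len(r.embedding) for r in self.records if r.embedding is not None}
        if len(dims) > 1:
            raise ValidationError(f"inconsistent embedding dimensions: {sorted(dims)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, concept_id: str) -> WordRecord:
        for r in self.records:
            if r.concept_id == concept_id:
                return r
        raise ReferentialError(f"unknown concept_id {concept_id!r}")

    def validate_lengths(self, table: SegmentFeatureTable | None = None) -> None:
        """Check stored phoneme counts against the IPA segmentation."""
        table = table or load_default_table()
        for r in self.records:
            for side, ipa, n in (
                ("czech", r.czech_ipa, r.czech_len),
                ("foreign", r.foreign_ipa, r.foreign_len),
            ):
                got = len(segment_ipa(ipa, table))
                if got != n:
                    raise ValidationError(
                        f"{r.concept_id}: {side} length {n} != {got} segments in {ipa!r}"
                    )


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's answer to one trial."""

    participant_id: str
    session_trial_index: int
    trial: "object"  # experiment_design.Trial; kept loose to avoid a cycle
    correct: int
    age: float | None = None
    gender: str | None = None

    def __post_init__(self):
        if self.correct not in (0, 1):
            raise ValidationError(
                f"participant {self.participant_id}, trial "
                f"{self.session_trial_index}: correct={self.correct} not in {{0,1}}"
            )


def _norm(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def read_lexicon(
    path: str | Path,
    language_pair: str | None = None,
    column_map: Mapping[str, str] | None = None,
    validate: bool = True,
) -> StudyLexicon:
    """Read a tab-separated lexicon.

    ``column_map`` renames external headers to the canonical column names,
    so deposited files with a different layout can be adapted.  With
    ``validate`` the stored phoneme counts are checked against the packaged
    segmentation.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        fields = [column_map.get(c, c) if column_map else c for c in reader.fieldnames]
        missing = [c for c in LEXICON_COLUMNS if c != "embedding" and c not in fields]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        records = []
        for rownum, raw in enumerate(reader, start=2):
            row = {column_map.get(k, k) if column_map else k: v
                   for k, v in raw.items()}
            try:
                emb_raw = (row.get("embedding") or "").strip()
                emb = tuple(float(x) for x in emb_raw.split(";")) if emb_raw else None
                rec = WordRecord(
                    concept_id=row["concept_id"].strip(),
                    czech_form=_norm(row["czech_form"]),
                    foreign_form=_norm(row["foreign_form"]),
                    czech_ipa=_norm(row["czech_ipa"]),
                    foreign_ipa=_norm(row["foreign_ipa"]),
                    czech_len=int(row["czech_len"]),
                    foreign_len=int(row["foreign_len"]),
                    czech_logfreq=float(row["czech_logfreq"]),
                    foreign_logfreq=float(row["foreign_logfreq"]),
                    pos=row["pos"].strip(),
                    cognate_score=float(row["cognate_score"]),
                )
            except ValidationError:
                raise
            except (KeyError, ValueError) as exc:
                raise ParseError(str(exc), row=rownum) from exc
            if emb is not None:
                rec = replace(rec, embedding=emb)
            records.append(rec)
    lex = StudyLexicon(
        language_pair=language_pair or path.stem,
        records=tuple(records),
    )
    if validate and records:
        lex.validate_lengths()
    return lex


def write_lexicon(lexicon: StudyLexicon, path: str | Path) -> None:
    """Write a lexicon back to the canonical tab-separated layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LEXICON_COLUMNS)
        for r in lexicon.records:
            emb = ";".join(format(x, ".4g") for x in r.embedding) if r.embedding else ""
            writer.writerow([
                r.concept_id, r.czech_form, r.foreign_form, r.czech_ipa,
                r.foreign_ipa, r.czech_len, r.foreign_len,
                format(r.czech_logfreq, ".6g"), format(r.foreign_logfreq, ".6g"),
                r.pos, format(r.cognate_score, ".4g"), emb,
            ])


def read_responses(path: str | Path, lexicon: StudyLexicon) -> list[ResponseRecord]:
    """Read a response CSV, rebuilding trial references against ``lexicon``.

    Rows are re-ordered within each participant by ``session_trial_index``;
    participants keep their order of first appearance.
    """
    from .experiment_design import Trial  # local import; Trial needs WordRecord

    path = Path(path)
    out: list[ResponseRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = [c for c in RESPONSE_COLUMNS
                   if c not in reader.fieldnames and c not in ("age", "gender")]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            try:
                idx = int(row["session_trial_index"])
                inverse = int(row["inverse"])
                correct = int(row["correct"])
            except ValueError as exc:
                raise ParseError(str(exc), row=rownum) from exc
            if inverse not in (0, 1):
                raise ValidationError(f"row {rownum}: inverse={inverse} not in {{0,1}}")
            w1 = lexicon.by_id(row["concept_id_1"].strip())
            w2 = lexicon.by_id(row["concept_id_2"].strip())
            age = float(row["age"]) if (row.get("age") or "").strip() else None
            gender = (row.get("gender") or "").strip() or None
            out.append(ResponseRecord(
                participant_id=row["participant_id"].strip(),
                session_trial_index=idx,
                trial=Trial(czech_pair=(w1, w2),
                            foreign_pair=(w2, w1) if inverse else (w1, w2),
                            inverse=inverse, order_index=idx),
                correct=correct,
                age=age,
                gender=gender,
            ))
    order = {p: i for i, p in enumerate(dict.fromkeys(r.participant_id for r in out))}
    out.sort(key=lambda r: (order[r.participant_id], r.session_trial_index))
    return out


def write_responses(responses: Iterable[ResponseRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESPONSE_COLUMNS)
        for r in responses:
            writer.writerow([
                r.participant_id, r.session_trial_index,
                r.trial.czech_pair[0].concept_id, r.trial.czech_pair[1].concept_id,
                r.trial.inverse, r.correct,
                "" if r.age is None else r.age,
                r.gender or "",
            ])


def load_synthetic_lexicon(language: str) -> StudyLexicon:
    """Load a packaged synthetic stand-in lexicon (68 concepts).

    These fixtures are generated by :mod:`guessability.synthetic_data` under
    the study-shaped configuration (fixed seed 68) and stand in for the
    study's deposited word lists, which are not redistributed here.
    """
    from importlib import resources

    name = f"lexicon_synthetic_{language}.tsv"
    with resources.as_file(resources.files("guessability.data") / name) as p:
        return read_lexicon(p, language_pair=f"czech-{language}")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for rownum, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"expected 'key = value', got {line!r}", row=rownum)
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg
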