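"""Responses, answer keys, and the word-presence scoring procedure.

The exam's free-text parts 3-6 follow the SBAR handover structure
(Situation, Background, Assessment, Recommendation). Each part carries a
handful of concept questions (ids like ``"3-1"``); a concept is credited —
one binary point, at most once — when any of its accept strings, after
notation-variant expansion and tokenization to standard forms, occurs as a
contiguous subsequence of the tokenized response for that part. Misspelled
or out-of-list words never match: matching is exact by design, because the
answers exist to convey information reliably.

Subjects with any "ongoing" record are excluded, as are subjects whose
texts are all empty across parts 3-6 (nonresponse). Partial responders are
kept and score zero on their empty parts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd

from .lexicon import Lexicon, expand_variants
from .tokenizer import tokenize

logger = logging.getLogger(__name__)

PARTS = (3, 4, 5, 6)

#: Scorable questions per part; part 4 loses one question whose concept
#: ("the state when he lost consciousness") only exists as a sentence and
#: admits no word list.
PART_MAX = {3: 5, 4: 3, 5: 5, 6: 5}
TOTAL_MAX = sum(PART_MAX.values())  # 18


class ValidationError(ValueError):
    """Raised for structurally invalid keys, records or sheet pairs."""


@dataclass(frozen=True)
class ResponseRecord:
    subject_id: str
    part: int
    text: str
    status: str = "complete"  # "complete" | "ongoing"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.part not in PARTS:
            raise ValidationError(f"part must be one of {PARTS}, got {self.part}")
        if self.status not in ("complete", "ongoing"):
            raise ValidationError(f"status must be complete|ongoing, got {self.status!r}")


@dataclass(frozen=True)
class Question:
    id: str
    concept: str
    accept: tuple[str, ...]
    scorable: bool = True

    @property
    def part(self) -> int:
        return int(self.id.split("-", 1)[0])


@dataclass(frozen=True)
class AnswerKey:
    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        seen = set()
        for q in self.questions:
            if q.id in seen:
                raise ValidationError(f"duplicate question id {q.id!r}")
            seen.add(q.id)
            if q.part not in PARTS:
                raise ValidationError(f"question {q.id!r}: part outside {PARTS}")
            if q.scorable and not q.accept:
                raise ValidationError(f"scorable question {q.id!r} has an empty accept list")

    @property
    def scorable_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions if q.scorable)

    def __getitem__(self, qid: str) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise KeyError(qid)


def load_answer_key(source: IO[str] | str) -> AnswerKey:
    """Read the answer-key JSON document.

    Schema: ``{"questions": [{"id": "3-1", "concept": ..., "accept": [...],
    "scorable": true}, ...]}``.
    """
    doc = json.loads(source if isinstance(source, str) else source.read())
    try:
        items = doc["questions"]
    except (TypeError, KeyError):
        raise ValidationError("answer key document must contain a 'questions' list") from None
    questions = []
    for item in items:
        questions.append(
            Question(
                id=str(item["id"]),
                concept=str(item.get("concept", "")),
                accept=tuple(item.get("accept", ())),
                scorable=bool(item.get("scorable", True)),
            )
        )
    return AnswerKey(tuple(questions))


def dump_answer_key(key: AnswerKey) -> str:
    doc = {
        "questions": [
            {"id": q.id, "concept": q.concept, "accept": list(q.accept), "scorable": q.scorable}
            for q in key.questions
        ]
    }
    return json.dumps(doc, ensure_ascii=False, indent=2)


@dataclass(frozen=True)
class CompiledAnswerKey:
    """Per scorable question: the deduplicated set of accept token-sequences.

    Every accept string is first enlarged by notation-variant expansion
    (Arabic/Roman/Chinese/full-width numerals), then tokenized to standard
    forms with the same lexicon the responses will be tokenized with.
    """

    sequences: Mapping[str, frozenset[tuple[str, ...]]]
    question_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "question_ids", tuple(self.sequences.keys()))
        for qid, seqs in self.sequences.items():
            if not seqs:
                raise ValidationError(f"question {qid!r}: no accept sequences after compilation")
            if any(len(s) == 0 for s in seqs):
                raise ValidationError(f"question {qid!r}: empty accept sequence")


def compile_answer_key(key: AnswerKey, lex: Lexicon) -> CompiledAnswerKey:
    from .tokenizer import UNKNOWN_CHAR_COST, normalize_text, segment

    compiled: dict[str, frozenset[tuple[str, ...]]] = {}
    for q in key.questions:
        if not q.scorable:
            continue
        seqs = set()
        for accept in q.accept:
            for variant in sorted(expand_variants(accept)):
                norm = normalize_text(variant)
                if not norm:
                    continue
                res = segment(norm, lex)
                if all(t.cost == UNKNOWN_CHAR_COST for t in res.tokens):
                    logger.warning(
                        "question %s: accept string %r tokenizes entirely to unknown characters",
                        q.id, variant,
                    )
                seqs.add(res.standard_forms)
        compiled[q.id] = frozenset(seqs)
    return CompiledAnswerKey(compiled)


def filter_valid_responses(
    records: Iterable[ResponseRecord],
) -> tuple[list[ResponseRecord], list[tuple[str, str]]]:
    """Split a corpus into kept records and ``(subject_id, reason)`` exclusions.

    A subject is excluded as ``"ongoing"`` if any of their records is still
    in progress, and as ``"nonresponse"`` if every text over parts 3-6 is
    empty (missing parts count as empty). Exclusion order follows first
    appearance in the corpus.
    """
    records = list(records)
    order: list[str] = []
    by_subject: dict[str, list[ResponseRecord]] = {}
    for r in records:
        if r.subject_id not in by_subject:
            order.append(r.subject_id)
            by_subject[r.subject_id] = []
        by_subject[r.subject_id].append(r)

    kept: list[ResponseRecord] = []
    excluded: list[tuple[str, str]] = []
    keep_set = set()
    for sid in order:
        recs = by_subject[sid]
        if any(r.status == "ongoing" for r in recs):
            excluded.append((sid, "ongoing"))
        elif all(not r.text.strip() for r in recs):
            excluded.append((sid, "nonresponse"))
        else:
            keep_set.add(sid)
    kept = [r for r in records if r.subject_id in keep_set]
    return kept, excluded


def match_concept(
    tokens: tuple[str, ...], accepts: frozenset[tuple[str, ...]] | set[tuple[str, ...]]
) -> tuple[bool, tuple[int, int] | None]:
    """Scan for any accept sequence as a contiguous token subsequence.

    Returns ``(matched, span)`` where ``span`` is the leftmost (then
    shortest) matching token-index interval, or ``None``. Equality is exact
    on standard forms, so misspelled or out-of-list words never match.
    """
    if not accepts:
        raise ValidationError("accepts must be non-empty")
    best: tuple[int, int] | None = None
    for seq in accepts:
        k = len(seq)
        if k == 0 or k > len(tokens):
            continue
        for i in range(len(tokens) - k + 1):
            if tokens[i : i + k] == tuple(seq):
                cand = (i, i + k)
                if best is None or cand < best:
                    best = cand
                break
    return (best is not None), best


@dataclass(frozen=True)
class ScoreSheet:
    """Binary points over (subject, scorable question) with part subtotals."""

    subjects: tuple[str, ...]
    question_ids: tuple[str, ...]
    cells: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (sid, qid), v in self.cells.items():
            if v not in (0, 1):
                raise ValidationError(f"cell ({sid},{qid}) must be 0 or 1, got {v}")
        expected = {(s, q) for s in self.subjects for q in self.question_ids}
        if set(self.cells.keys()) != expected:
            missing = sorted(expected - set(self.cells.keys()))[:5]
            extra = sorted(set(self.cells.keys()) - expected)[:5]
            raise ValidationError(f"cell set mismatch; missing {missing}, unexpected {extra}")

    def point(self, subject_id: str, question_id: str) -> int:
        return self.cells[(subject_id, question_id)]

    def part_subtotal(self, subject_id: str, part: int) -> int:
        return sum(
            self.cells[(subject_id, q)]
            for q in self.question_ids
            if int(q.split("-", 1)[0]) == part
        )

    def total(self, subject_id: str) -> int:
        return sum(self.cells[(subject_id, q)] for q in self.question_ids)

    def totals(self) -> dict[str, int]:
        return {s: self.total(s) for s in self.subjects}

    def part_totals(self, part: int) -> dict[str, int]:
        return {s: self.part_subtotal(s, part) for s in self.subjects}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row: dict[str, object] = {"subject_id": s}
            for q in self.question_ids:
                row[q] = self.cells[(s, q)]
            for p in PARTS:
                row[f"part{p}"] = self.part_subtotal(s, p)
            row["total"] = self.total(s)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, dest: IO[str]) -> None:
        self.to_frame().to_csv(dest, sep="\t", index=False)


def score_sheet_from_frame(df: pd.DataFrame) -> ScoreSheet:
    qids = [c for c in df.columns if "-" in c]
    subjects = tuple(str(s) for s in df["subject_id"])
    cells = {
        (str(row["subject_id"]), q): int(row[q]) for _, row in df.iterrows() for q in qids
    }
    return ScoreSheet(subjects, tuple(qids), cells)


def load_score_sheet(source: IO[str]) -> ScoreSheet:
    return score_sheet_from_frame(pd.read_csv(source, sep="\t"))


def score_corpus(
    corpus: Iterable[ResponseRecord], ckey: CompiledAnswerKey, lex: Lexicon
) -> ScoreSheet:
    """Run the scoring procedure over every kept subject.

    Per subject and part, the part's text is tokenized once; each scorable
    question of that part is then checked independently, and the cell is 1
    iff any of its accept sequences occurs in the token sequence — never
    more than one point per question however many accept words appear.
    Missing parts score zero across that part's questions.
    """
    corpus = list(corpus)
    subjects: list[str] = []
    texts: dict[tuple[str, int], str] = {}
    for r in corpus:
        if r.subject_id not in subjects:
            subjects.append(r.subject_id)
        texts[(r.subject_id, r.part)] = r.text

    by_part: dict[int, list[str]] = {p: [] for p in PARTS}
    for qid in ckey.question_ids:
        by_part[int(qid.split("-", 1)[0])].append(qid)

    cells: dict[tuple[str, str], int] = {}
    for sid in subjects:
        for part, qids in by_part.items():
            if not qids:
                continue
            text = texts.get((sid, part), "")
            tokens = tokenize(text, lex) if text else ()
            for qid in qids:
                matched, _ = match_concept(tokens, ckey.sequences[qid])
                cells[(sid, qid)] = int(matched)
    return ScoreSheet(tuple(subjects), tuple(ckey.question_ids), cells)


def load_responses(source: IO[str]) -> list[ResponseRecord]:
    """Read the responses CSV (columns subject_id, part, text, status)."""
    df = pd.read_csv(source, dtype={"subject_id": str}, keep_default_na=False)
    required = {"subject_id", "part", "text", "status"}
    if not required.issubset(df.columns):
        raise ValidationError(f"responses file must have columns {sorted(required)}")
    return [
        ResponseRecord(str(r.subject_id), int(r.part), str(r.text), str(r.status))
        for r in df.itertuples()
    ]


def dump_responses(records: Iterable[ResponseRecord], dest: IO[str]) -> None:
    df = pd.DataFrame(
        [
            {"subject_id": r.subject_id, "part": r.part, "text": r.text, "status": r.status}
            for r in records
        ]
    )
    df.to_csv(dest, index=False)
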