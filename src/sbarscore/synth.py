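"""Synthetic answer corpora with paired machine/human ground truth.

No response corpus from the original exam administration is publicly
deposited, so everything downstream is exercised on generated data. The
generator emulates the study's structure: 39 subjects each answer four
SBAR parts (Situation, Background, Assessment, Recommendation) against a
key of 19 concept questions of which 18 are scorable, and each included
concept may be perturbed in one of the ways that made machine and human
scores diverge in practice:

* **out-of-list synonym** — the respondent writes a semantically valid
  word the accept list does not contain ("blackout" for syncope);
* **misspelling** — a single-character corruption; the machine is strict,
  the emulated human by default fails to notice (configurable);
* **fused / conjugated form** — a surface only matchable through a
  user-dictionary entry that is deliberately withheld, emulating
  over-division of compounds and verb+particle forms.

The emulated human credits understanding (synonyms, sentences, fused
forms) and then flips cells at configurable error rates. Ground-truth
machine and human score sheets are computed at generation time by
construction, not by running the scorer, so they are a valid oracle for
end-to-end tests. Identical configs reproduce identical corpora and files.

Default rates mirror the observed study tallies at n=39: roughly 31% of
cells credited by the human reference, about 5% of credited concepts
perturbed into machine misses, and a ~1.4% human flip rate on credited
cells (the "human error" rows), no spurious human credits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .lexicon import Lexicon, LexiconEntry, expand_variants, merge_dictionaries, write_lexicon
from .scoring import (
    AnswerKey,
    Question,
    ResponseRecord,
    ScoreSheet,
    ValidationError,
    dump_answer_key,
    dump_responses,
)
from .tokenizer import normalize_text

# ---------------------------------------------------------------------------
# The exam-shaped answer key: parts 3-6 with 5/4/5/5 questions, one of which
# (4-3, a concept that only exists as a sentence) is unscorable.

_KEY_SPEC: list[tuple[str, str, tuple[str, ...], bool]] = [
    ("3-1", "name", ("yoshinaga seiichi", "yoshinaga"), True),
    ("3-2", "age", ("45-year-old", "45yo"), True),
    ("3-3", "sex", ("male", "man"), True),
    ("3-4", "provisional diagnosis", ("pulmonary thromboembolism", "pulmonary embolism"), True),
    ("3-5", "chief complaint", ("syncope", "loss of consciousness"), True),
    ("4-1", "history", ("fracture", "leg fracture"), True),
    ("4-2", "medications", ("amlodipine", "no medications"), True),
    ("4-3", "state when he lost consciousness", (), False),
    ("4-4", "duration", ("few minutes", "within minutes"), True),
    ("5-1", "tachypnea", ("tachypnea", "rapid breathing"), True),
    ("5-2", "jugular vein distention", ("jugular vein distention", "jugular vein distension"), True),
    ("5-3", "diastolic murmur", ("diastolic murmur",), True),
    ("5-4", "increased pulmonic component of S2", ("2p", "increased 2p"), True),
    ("5-5", "bone fracture", ("bone fracture",), True),
    ("6-1", "electrocardiogram", ("electrocardiogram", "ecg"), True),
    ("6-2", "cardiac ultrasound", ("echocardiography", "cardiac ultrasound"), True),
    ("6-3", "contrast CT", ("contrast ct", "computed tomography"), True),
    ("6-4", "anticoagulant drugs", ("anticoagulant", "anticoagulation"), True),
    ("6-5", "thrombolytic drugs", ("thrombolytic", "thrombolysis"), True),
]

#: Out-of-list synonyms a human credits but no accept list contains.
_SYNONYMS: dict[str, str] = {
    "3-1": "the usual patient",
    "3-2": "middle-aged",
    "3-3": "gentleman",
    "3-4": "lung clot",
    "3-5": "blackout",
    "4-1": "injury",
    "4-2": "calcium blocker",
    "4-4": "brief spell",
    "5-1": "fast breaths",
    "5-2": "neck vein bulging",
    "5-3": "heart noise",
    "5-4": "loud second tone",
    "5-5": "broken bone",
    "6-1": "heart tracing",
    "6-2": "echo",
    "6-3": "scanning",
    "6-4": "blood thinner",
    "6-5": "clot buster",
}

#: Distractor vocabulary, disjoint from every accept variant and synonym.
_FILLERS = (
    "patient", "visited", "emergency", "room", "with", "his", "wife", "last",
    "night", "admitted", "for", "workup", "stable", "now", "history", "was",
    "noted", "on", "exam", "we", "plan", "to", "start", "therapy", "after",
    "tests", "team", "will", "follow", "and", "chart", "review", "shows",
    "findings", "today", "during", "rounds", "nurse", "reported", "values",
)

#: Compounds matchable only through the user dictionary (cost-1 entries);
#: the base dictionary carries only their over-dividing pieces.
_USER_COMPOUNDS = {"ultrasound": ("ultra", "sound")}


def build_answer_key() -> AnswerKey:
    return AnswerKey(tuple(Question(*row) for row in _KEY_SPEC))


def _accept_words(key: AnswerKey) -> set[str]:
    words = set()
    for q in key.questions:
        for a in q.accept:
            for variant in expand_variants(a):
                norm = normalize_text(variant)
                words.update(w for w in norm.split(" ") if w)
    return words


def build_lexicons(key: AnswerKey | None = None) -> tuple[Lexicon, Lexicon]:
    """(base, user) dictionaries covering the synthetic vocabulary.

    Base entries cost 10; the user dictionary registers compounds at cost 1
    so they beat their over-dividing pieces in the lattice. A literal
    space entry lets segmentation tile spaced text without unknown arcs.
    """
    key = key or build_answer_key()
    base_words = _accept_words(key)
    for syn in _SYNONYMS.values():
        base_words.update(syn.split(" "))
    base_words.update(_FILLERS)
    for compound, pieces in _USER_COMPOUNDS.items():
        base_words.discard(compound)
        base_words.update(pieces)

    entries = [LexiconEntry(" ", " ", "other", 1)]
    for w in sorted(base_words):
        entries.append(LexiconEntry(w, w, "noun", 10))
    # plural/derived surfaces unified onto one standard form
    entries.append(LexiconEntry("anticoagulants", "anticoagulant", "noun", 10))
    base = Lexicon(entries)
    user = Lexicon([LexiconEntry(c, c, "noun", 1) for c in sorted(_USER_COMPOUNDS)])
    return base, user


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for corpus generation (probabilities all in [0,1])."""

    n_subjects: int = 39
    p_include: float = 0.31
    p_oov_synonym: float = 0.03
    p_misspell: float = 0.01
    p_fuse: float = 0.01
    human_error_fn: float = 0.014
    human_error_fp: float = 0.0
    human_lenient_misspell: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.p_include, self.p_oov_synonym, self.p_misspell, self.p_fuse,
            self.human_error_fn, self.human_error_fp,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.p_oov_synonym + self.p_misspell + self.p_fuse > 1.0 + 1e-12:
            raise ValidationError("perturbation probabilities must sum to at most 1")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CorpusBundle:
    responses: tuple[ResponseRecord, ...]
    answer_key: AnswerKey
    base_lexicon: Lexicon
    user_lexicon: Lexicon
    lexicon: Lexicon  # merged
    truth_machine: ScoreSheet
    truth_human: ScoreSheet
    config: SynthConfig | None = None


def _forbidden_substrings(key: AnswerKey, part: int) -> set[str]:
    """Normalized accept variants of the part's questions; a perturbed chunk
    must not contain any of them, so ground truth stays exact."""
    out = set()
    for q in key.questions:
        if q.part != part:
            continue
        for a in q.accept:
            for v in expand_variants(a):
                norm = normalize_text(v)
                if norm:
                    out.add(norm)
    return out


def _misspell(word_chunk: str, rng: np.random.Generator, forbidden: set[str]) -> str:
    """One-character substitution guaranteed outside every accept variant."""
    chars = list(word_chunk)
    positions = [i for i, c in enumerate(chars) if c != " "]
    for _ in range(50):
        i = int(rng.integers(0, len(positions)))
        pos = positions[i]
        orig = chars[pos]
        repl = chr((ord(orig) - ord("a") + 1 + int(rng.integers(0, 24))) % 26 + ord("a"))
        if repl == orig:
            continue
        cand = "".join(chars[:pos] + [repl] + chars[pos + 1:])
        if not any(f in cand for f in forbidden):
            return cand
    raise RuntimeError("could not produce a safe misspelling")  # pragma: no cover


def _fused(word_chunk: str, forbidden: set[str]) -> str:
    """Conjugated/fused surface: stem-altered and space-fused, matchable only
    via a user-dictionary entry that is never provided.

    Every word loses its tail and the words fuse together before the
    conjugation suffix, so neither the full accept string nor any
    single-word accept survives as a substring."""
    words = word_chunk.split(" ")
    cand = "".join(w[: max(1, len(w) - 2)] for w in words) + "tta"
    assert not any(f in cand for f in forbidden)
    return cand


def generate_corpus(cfg: SynthConfig) -> CorpusBundle:
    """Generate responses plus exact machine and human truth sheets.

    Per subject and scorable question: with ``p_include`` the concept is
    embedded (one accept string amid distractor fillers); an embedded
    concept is perturbed into an out-of-list synonym / misspelling / fused
    form with the respective probabilities (mutually exclusive). The
    machine truth cell is 1 iff the embedded string survives unperturbed;
    the human truth credits understanding, honors the misspelling
    strictness flag, then applies the error flip rates.
    """
    rng = np.random.default_rng(cfg.seed)
    key = build_answer_key()
    base, user = build_lexicons(key)
    merged = merge_dictionaries(base, user)
    scorable = [q for q in key.questions if q.scorable]

    responses: list[ResponseRecord] = []
    m_cells: dict[tuple[str, str], int] = {}
    h_cells: dict[tuple[str, str], int] = {}
    subjects = [f"s{i + 1:03d}" for i in range(cfg.n_subjects)]

    for sid in subjects:
        part_chunks: dict[int, list[str]] = {p: [] for p in (3, 4, 5, 6)}
        for q in scorable:
            forbidden = _forbidden_substrings(key, q.part)
            fillers = [
                _FILLERS[int(rng.integers(0, len(_FILLERS)))]
                for _ in range(int(rng.integers(1, 4)))
            ]
            part_chunks[q.part].extend(fillers)
            include = rng.random() < cfg.p_include
            if not include:
                m_cells[(sid, q.id)] = 0
                h_cells[(sid, q.id)] = 0
                continue
            accept = q.accept[int(rng.integers(0, len(q.accept)))]
            u = rng.random()
            if u < cfg.p_oov_synonym:
                chunk = _SYNONYMS[q.id]
                machine, human = 0, 1
            elif u < cfg.p_oov_synonym + cfg.p_misspell:
                chunk = _misspell(normalize_text(accept), rng, forbidden)
                machine, human = 0, 1 if cfg.human_lenient_misspell else 0
            elif u < cfg.p_oov_synonym + cfg.p_misspell + cfg.p_fuse:
                chunk = _fused(normalize_text(accept), forbidden)
                machine, human = 0, 1
            else:
                chunk = accept
                machine, human = 1, 1
            part_chunks[q.part].append(chunk)
            m_cells[(sid, q.id)] = machine
            h_cells[(sid, q.id)] = human

        # independent human error flips
        for q in scorable:
            h = h_cells[(sid, q.id)]
            if h == 1 and rng.random() < cfg.human_error_fn:
                h_cells[(sid, q.id)] = 0
            elif h == 0 and rng.random() < cfg.human_error_fp:
                h_cells[(sid, q.id)] = 1

        for p in (3, 4, 5, 6):
            responses.append(
                ResponseRecord(sid, p, " ".join(part_chunks[p]), "complete")
            )

    qids = tuple(q.id for q in scorable)
    truth_machine = ScoreSheet(tuple(subjects), qids, m_cells)
    truth_human = ScoreSheet(tuple(subjects), qids, h_cells)
    return CorpusBundle(
        tuple(responses), key, base, user, merged, truth_machine, truth_human, cfg
    )


def regression_fixture() -> CorpusBundle:
    """Deterministic hand-built corpus covering the discrepancy taxonomy.

    Eight subjects answer all four parts with every concept embedded except
    one manipulated cell each, so the expected machine and human points of
    every cell are known by construction:

    ========  ======  ===================================  =======  =====
    subject   cell    manipulation                         machine  human
    ========  ======  ===================================  =======  =====
    d01       —       none (clean ceiling)                 1        1
    d02       3-5     out-of-list synonym ("blackout")     0        1
    d03       3-5     sentence-form phrasing               0        1
    d04       6-2     under-specified term ("echo")        0        1
    d05       5-2     misspelled word (human lenient)      0        1
    d06       4-1     fused/conjugated, user dict lacks    0        1
    d07       4-2     human error flip on a correct cell   1        0
    d08       6-5     concept omitted (both judge wrong)   0        0
    ========  ======  ===================================  =======  =====
    """
    key = build_answer_key()
    base, user = build_lexicons(key)
    merged = merge_dictionaries(base, user)
    scorable = [q for q in key.questions if q.scorable]
    qids = tuple(q.id for q in scorable)

    manipulations: dict[str, tuple[str, str, int, int]] = {
        # subject -> (question, replacement chunk, machine point, human point)
        "d02": ("3-5", "blackout", 0, 1),
        "d03": ("3-5", "he was plunged into darkness and fell", 0, 1),
        "d04": ("6-2", "perform an echo to check valve motion", 0, 1),
        "d05": ("5-2", "jugolar vein distention", 0, 1),
        "d06": ("4-1", "fracturtta", 0, 1),
        "d07": ("4-2", "medications: amlodipine", 1, 0),
        "d08": ("6-5", "", 0, 0),
    }

    responses: list[ResponseRecord] = []
    m_cells: dict[tuple[str, str], int] = {}
    h_cells: dict[tuple[str, str], int] = {}
    subjects = tuple(f"d{i + 1:02d}" for i in range(8))
    for sid in subjects:
        manip = manipulations.get(sid)
        part_chunks: dict[int, list[str]] = {p: ["the", "patient"] for p in (3, 4, 5, 6)}
        for q in scorable:
            if manip and manip[0] == q.id:
                chunk, machine, human = manip[1], manip[2], manip[3]
            else:
                chunk, machine, human = q.accept[0], 1, 1
            if chunk:
                part_chunks[q.part].append(chunk)
            m_cells[(sid, q.id)] = machine
            h_cells[(sid, q.id)] = human
        for p in (3, 4, 5, 6):
            responses.append(ResponseRecord(sid, p, " ".join(part_chunks[p]), "complete"))

    return CorpusBundle(
        tuple(responses),
        key,
        base,
        user,
        merged,
        ScoreSheet(subjects, qids, m_cells),
        ScoreSheet(subjects, qids, h_cells),
        None,
    )


def write_corpus(bundle: CorpusBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the bundle in the package's standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths = {
        "responses": outdir / "responses.csv",
        "answer_key": outdir / "answer_key.json",
        "base_lexicon": outdir / "base.lex.tsv",
        "user_lexicon": outdir / "user.lex.tsv",
        "truth_machine": outdir / "truth" / "machine.tsv",
        "truth_human": outdir / "truth" / "human.tsv",
    }
    with open(paths["responses"], "w", encoding="utf-8", newline="") as f:
        dump_responses(bundle.responses, f)
    paths["answer_key"].write_text(dump_answer_key(bundle.answer_key), encoding="utf-8")
    with open(paths["base_lexicon"], "w", encoding="utf-8") as f:
        write_lexicon(bundle.base_lexicon, f)
    with open(paths["user_lexicon"], "w", encoding="utf-8") as f:
        write_lexicon(bundle.user_lexicon, f)
    with open(paths["truth_machine"], "w", encoding="utf-8") as f:
        bundle.truth_machine.to_tsv(f)
    with open(paths["truth_human"], "w", encoding="utf-8") as f:
        bundle.truth_human.to_tsv(f)
    return paths
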