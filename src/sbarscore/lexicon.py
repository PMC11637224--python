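"""Segmentation lexicons and notation-variant expansion.

A lexicon is a multiset of (surface, standard form, part-of-speech, cost)
entries indexed for prefix lookup at arbitrary text positions — the arc
inventory of the minimum-cost lattice in :mod:`sbarscore.tokenizer`. Costs
are positive integers; lower cost wins during path search, which is how a
low-cost user dictionary overrides an over-dividing base dictionary without
any explicit conflict policy.

The on-disk dialect is a 4-column UTF-8 TSV (``surface<TAB>standard_form
<TAB>pos<TAB>cost``) with ``#`` comment lines, conventionally ``*.lex.tsv``.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .tokenizer import normalize_text

POS_TAGS = ("noun", "verb", "particle", "other")


class LexiconError(ValueError):
    """Raised for malformed lexicon input."""


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary word: a surface string with its canonical citation form.

    ``cost`` is the (positive) contribution of this arc to a segmentation
    path; user-dictionary compounds conventionally carry cost 1 so they
    dominate any multi-piece division of the same span.
    """

    surface: str
    standard_form: str
    pos: str
    cost: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise LexiconError("entry surface must be non-empty after normalization")
        if not self.standard_form:
            raise LexiconError("entry standard_form must be non-empty")
        if self.pos not in POS_TAGS:
            raise LexiconError(f"unknown pos tag {self.pos!r}; expected one of {POS_TAGS}")
        if not isinstance(self.cost, int) or self.cost < 1:
            raise LexiconError(f"cost must be a positive integer, got {self.cost!r}")


class Lexicon:
    """Multiset of entries with prefix lookup by first character.

    Duplicate surfaces are allowed and coexist; the tokenizer's path search
    resolves preference through cost, mirroring the merge of a general
    dictionary, a medical-term dictionary and a user dictionary.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._entries: list[LexiconEntry] = list(entries)
        self._by_first: dict[str, list[LexiconEntry]] = defaultdict(list)
        self.max_surface_len = 0
        for e in self._entries:
            self._by_first[e.surface[0]].append(e)
            self.max_surface_len = max(self.max_surface_len, len(e.surface))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return sorted_key(self) == sorted_key(other)

    def lookup(self, text: str, pos: int) -> list[LexiconEntry]:
        """All entries whose surface is a prefix of ``text`` at ``pos``."""
        if pos >= len(text):
            return []
        out = []
        for e in self._by_first.get(text[pos], ()):
            if text.startswith(e.surface, pos):
                out.append(e)
        return out

    def add(self, entry: LexiconEntry) -> None:
        self._entries.append(entry)
        self._by_first[entry.surface[0]].append(entry)
        self.max_surface_len = max(self.max_surface_len, len(entry.surface))


def sorted_key(lex: Lexicon) -> list[tuple[str, str, str, int]]:
    """Canonical multiset representation, for equality and serialization."""
    return sorted((e.surface, e.standard_form, e.pos, e.cost) for e in lex)


def load_lexicon(source: IO[str] | str) -> Lexicon:
    """Parse the 4-column TSV dialect into a :class:`Lexicon`.

    Surfaces are normalized with :func:`~sbarscore.tokenizer.normalize_text`
    so lookup operates in the same character space as normalized responses.
    Malformed lines (wrong column count, non-positive or non-integer cost)
    raise :class:`LexiconError` naming the line number; an empty stream
    yields a valid empty lexicon.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    entries = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise LexiconError(f"line {lineno}: expected 4 tab-separated columns, got {len(cols)}")
        surface, standard_form, pos, cost_s = cols
        try:
            cost = int(cost_s)
        except ValueError:
            raise LexiconError(f"line {lineno}: cost {cost_s!r} is not an integer") from None
        norm_surface = normalize_text(surface) if surface != " " else " "
        try:
            entries.append(LexiconEntry(norm_surface, standard_form, pos, cost))
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from None
    return Lexicon(entries)


def write_lexicon(lex: Lexicon, dest: IO[str]) -> None:
    """Serialize in the canonical sorted order (round-trips with load)."""
    for surface, standard_form, pos, cost in sorted_key(lex):
        dest.write(f"{surface}\t{standard_form}\t{pos}\t{cost}\n")


def merge_dictionaries(base: Lexicon, user: Lexicon) -> Lexicon:
    """Multiset union; associative and order-insensitive up to entry multiset."""
    return Lexicon(list(base) + list(user))


# ---------------------------------------------------------------------------
# Notation-variant expansion
#
# Exam answers write small ordinals in Arabic, Roman, Chinese or full-width
# form interchangeably (e.g. the pulmonic second-sound component "IIp" vs
# "2p" vs "IIp"). Accept lists are enlarged by a fixed built-in table covering
# 0-20; responses are never mutated.

_CHINESE = {
    0: "零", 1: "一", 2: "二", 3: "三", 4: "四", 5: "五", 6: "六", 7: "七",
    8: "八", 9: "九", 10: "十", 11: "十一", 12: "十二", 13: "十三", 14: "十四",
    15: "十五", 16: "十六", 17: "十七", 18: "十八", 19: "十九", 20: "二十",
}
_ROMAN_ASCII = {
    1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII",
    9: "IX", 10: "X", 11: "XI", 12: "XII", 13: "XIII", 14: "XIV", 15: "XV",
    16: "XVI", 17: "XVII", 18: "XVIII", 19: "XIX", 20: "XX",
}
# Dedicated Unicode roman-numeral codepoints exist only for 1-12.
_ROMAN_UNICODE = {
    1: "Ⅰ", 2: "Ⅱ", 3: "Ⅲ", 4: "Ⅳ", 5: "Ⅴ", 6: "Ⅵ", 7: "Ⅶ", 8: "Ⅷ",
    9: "Ⅸ", 10: "Ⅹ", 11: "Ⅺ", 12: "Ⅻ",
}


def _fullwidth(s: str) -> str:
    """ASCII digits/Latin folded to their full-width compatibility forms."""
    return "".join(
        chr(ord(c) + 0xFEE0) if "0" <= c <= "9" or "a" <= c <= "z" or "A" <= c <= "Z" else c
        for c in s
    )


def _numeral_groups() -> dict[str, tuple[str, ...]]:
    """Map each numeral surface to every equal-valued alternative form."""
    by_form: dict[str, tuple[str, ...]] = {}
    for n in range(0, 21):
        forms = [str(n), _CHINESE[n], _fullwidth(str(n))]
        if n in _ROMAN_ASCII:
            forms.append(_ROMAN_ASCII[n])
        if n in _ROMAN_UNICODE:
            forms.append(_ROMAN_UNICODE[n])
        for f in forms:
            by_form[f] = tuple(forms)
    return by_form


_GROUPS = _numeral_groups()
#: Characters that may participate in a numeral run. Substitution only ever
#: rewrites a *maximal* run that exactly equals a known form, so roman "II"
#: is always read as two, never as two ones — the closure stays finite and
#: value-preserving, and ordinary lowercase words are untouched.
_NUMERAL_CHARS = frozenset("0123456789IVX" + "".join(_CHINESE.values()) + "".join(_ROMAN_UNICODE.values()) + _fullwidth("0123456789"))


def expand_variants(canonical: str) -> set[str]:
    """Closure of ``canonical`` under the built-in notation mapping table.

    Every maximal numeral run (Arabic, Roman, Chinese or full-width digit,
    values 0-20) is substituted by each equal-valued alternative form.
    Strings without numerals come back unchanged — width and case folding
    of ordinary text is :func:`~sbarscore.tokenizer.normalize_text`'s job.
    The result always contains the input and is a fixpoint: re-expanding
    every member adds nothing. Used only to enlarge accept lists, never to
    mutate responses.
    """
    if not canonical:
        raise ValueError("canonical string must be non-empty")
    out = {canonical}
    frontier = [canonical]
    while frontier:
        nxt = []
        for s in frontier:
            for cand in _single_step(s):
                if cand not in out:
                    out.add(cand)
                    nxt.append(cand)
        frontier = nxt
    return out


def _numeral_runs(s: str) -> Iterator[tuple[int, int]]:
    i = 0
    while i < len(s):
        if s[i] in _NUMERAL_CHARS:
            j = i
            while j < len(s) and s[j] in _NUMERAL_CHARS:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _single_step(s: str) -> Iterator[str]:
    for i, j in _numeral_runs(s):
        run = s[i:j]
        for other in _GROUPS.get(run, ()):
            if other != run:
                yield s[:i] + other + s[j:]
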