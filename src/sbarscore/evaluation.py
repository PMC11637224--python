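"""Machine-vs-human agreement: confusion matrix, metrics, rank test.

Human scoring is the reference: a *false positive* is a cell the machine
credited but the human did not, a *false negative* one the human credited
but the machine missed. Agreement is summarized by accuracy, precision,
recall and F1 over all (subject, scorable-question) cells, and the score
distributions are compared with a Mann-Whitney U test reported with the
standardized statistic Z and effect size r = Z / sqrt(n1 + n2).

Because totals are small integers (0-18) the rank test is heavy with ties;
the default p-value therefore uses the tie-corrected normal approximation
without continuity correction. Small tie-free samples get the exact
permutation distribution instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .scoring import ScoreSheet, ValidationError

#: Exact permutation p-values are used (no ties) up to this pooled size.
EXACT_MAX_POOLED = 16


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int  # human correct, machine correct
    fn: int  # human correct, machine mistake
    fp: int  # human mistake, machine correct
    tn: int  # both mistake

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class AgreementMetrics:
    accuracy: float
    recall: float
    precision: float
    f1: float

    def rounded(self, digits: int = 3) -> dict[str, float]:
        """Half-up rounding for reports; raw values stay on the dataclass."""
        def r(v: float) -> float:
            if math.isnan(v):
                return v
            return math.floor(v * 10**digits + 0.5) / 10**digits

        return {
            "accuracy": r(self.accuracy),
            "recall": r(self.recall),
            "precision": r(self.precision),
            "f1": r(self.f1),
        }


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    z_value: float
    p_value: float
    effect_size_r: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class DiscrepancyRecord:
    subject_id: str
    question_id: str
    human_point: int
    machine_point: int
    response_tokens: tuple[str, ...]
    nearest_accept: tuple[str, ...]
    edit_distance: int


def _check_aligned(human: ScoreSheet, machine: ScoreSheet) -> None:
    h = set(human.cells.keys())
    m = set(machine.cells.keys())
    if h != m:
        missing = sorted(h - m)[:10]
        extra = sorted(m - h)[:10]
        raise ValidationError(
            f"score sheets cover different cells; machine missing {missing}, extra {extra}"
        )


def confusion_matrix(human: ScoreSheet, machine: ScoreSheet) -> ConfusionMatrix:
    """Cross-tabulate every point-level cell, human as reference."""
    _check_aligned(human, machine)
    tp = fn = fp = tn = 0
    for cell, h in human.cells.items():
        m = machine.cells[cell]
        if h == 1 and m == 1:
            tp += 1
        elif h == 1 and m == 0:
            fn += 1
        elif h == 0 and m == 1:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fn, fp, tn)


def agreement_metrics(cm: ConfusionMatrix) -> AgreementMetrics:
    """Accuracy, recall, precision and F1 from the confusion counts.

    A ratio whose denominator is zero is reported as NaN (undefined), never
    coerced to 0; an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else math.nan
    f1 = 2 * cm.tp / (2 * cm.tp + cm.fn + cm.fp) if 2 * cm.tp + cm.fn + cm.fp else math.nan
    return AgreementMetrics(accuracy, recall, precision, f1)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    ranks = stats.rankdata(pooled)  # midranks for ties
    n1 = len(x)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    return u, ranks


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test with effect size r = Z/sqrt(n1+n2).

    U is the rank-sum statistic of ``x`` (midranks for ties); Z is the
    tie-corrected normal standardization of U without continuity correction,
    so r is 0 and p is 1 for completely tied inputs. For tie-free samples
    with pooled size <= 16 the p-value comes from exact enumeration of all
    C(n1+n2, n1) rank assignments: p = min(1, 2*min(P(U<=u), P(U>=u))).
    """
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    u, ranks = _u_statistic(x, y)
    n = n1 + n2

    mu = n1 * n2 / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if sigma2 > 0:
        z = (u - mu) / math.sqrt(sigma2)
    else:
        z = 0.0

    no_ties = len(tie_counts) == n
    if no_ties and n <= EXACT_MAX_POOLED:
        us = np.array(
            [sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2 for comb in combinations(range(n), n1)]
        )
        p_le = float(np.mean(us <= u + 1e-12))
        p_ge = float(np.mean(us >= u - 1e-12))
        p = min(1.0, 2 * min(p_le, p_ge))
        method = "exact"
    else:
        p = 2 * stats.norm.sf(abs(z)) if sigma2 > 0 else 1.0
        method = "asymptotic"

    r = z / math.sqrt(n)
    return RankTestResult(float(u), float(z), float(p), float(r), n1, n2, method)


def _token_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance over token sequences (unit costs)."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def discrepancy_table(
    human: ScoreSheet,
    machine: ScoreSheet,
    corpus,
    ckey,
    lex,
) -> list[DiscrepancyRecord]:
    """One record per disagreeing cell, with misspelling-triage evidence.

    Each record carries the response's standard-form tokens and the accept
    sequence nearest to them by token-wise edit distance — a small distance
    suggests a near-miss (misspelling or missing dictionary entry) worth
    adding to the word list or user dictionary during calibration.
    """
    from .tokenizer import tokenize

    _check_aligned(human, machine)
    texts = {(r.subject_id, r.part): r.text for r in corpus}
    token_cache: dict[tuple[str, int], tuple[str, ...]] = {}
    records = []
    for sid in human.subjects:
        for qid in human.question_ids:
            h = human.cells[(sid, qid)]
            m = machine.cells[(sid, qid)]
            if h == m:
                continue
            part = int(qid.split("-", 1)[0])
            if (sid, part) not in token_cache:
                token_cache[(sid, part)] = tokenize(texts.get((sid, part), ""), lex)
            tokens = token_cache[(sid, part)]
            nearest: tuple[str, ...] = ()
            best_d = -1
            for seq in sorted(ckey.sequences[qid]):
                d = _token_edit_distance(tokens, seq)
                if best_d < 0 or d < best_d:
                    best_d = d
                    nearest = tuple(seq)
            records.append(
                DiscrepancyRecord(sid, qid, h, m, tokens, nearest, best_d)
            )
    return records


def discrepancies_to_tsv(records: Iterable[DiscrepancyRecord], dest) -> None:
    dest.write(
        "subject_id\tquestion_id\thuman\tmachine\ttokens\tnearest_accept\tedit_distance\n"
    )
    for r in records:
        dest.write(
            f"{r.subject_id}\t{r.question_id}\t{r.human_point}\t{r.machine_point}\t"
            f"{' '.join(r.response_tokens)}\t{' '.join(r.nearest_accept)}\t{r.edit_distance}\n"
        )


def evaluation_report(
    human: ScoreSheet, machine: ScoreSheet, digits: int = 3
) -> dict:
    """Confusion counts, metrics (raw + rounded), and rank tests per part/total."""
    cm = confusion_matrix(human, machine)
    metrics = agreement_metrics(cm)
    from .scoring import PARTS

    rank_tests = {}
    h_tot = [human.total(s) for s in human.subjects]
    m_tot = [machine.total(s) for s in machine.subjects]
    rank_tests["total"] = mann_whitney(h_tot, m_tot)
    for p in PARTS:
        hp = [human.part_subtotal(s, p) for s in human.subjects]
        mp = [machine.part_subtotal(s, p) for s in machine.subjects]
        rank_tests[f"part{p}"] = mann_whitney(hp, mp)

    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn, "total": cm.total},
        "metrics_raw": {
            "accuracy": metrics.accuracy,
            "recall": metrics.recall,
            "precision": metrics.precision,
            "f1": metrics.f1,
        },
        "metrics": metrics.rounded(digits),
        "rank_tests": {
            k: {
                "u_statistic": v.u_statistic,
                "z_value": v.z_value,
                "p_value": v.p_value,
                "effect_size_r": v.effect_size_r,
                "n1": v.n1,
                "n2": v.n2,
                "method": v.method,
            }
            for k, v in rank_tests.items()
        },
    }
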