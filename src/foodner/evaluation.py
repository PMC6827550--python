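"""NER evaluation: span matching into TP/FP/FN/Partial and derived metrics.

Predicted food-chunk spans are cross-referenced with gold spans per recipe.
Exactly matching spans pair off as true positives; remaining predictions that
overlap a remaining gold span by at least one character pair off greedily
left-to-right as "Partial (Inconclusive)"; what is left is a false positive
(prediction side) or a false negative (gold side).  True negatives are not
modelled — the notion has no meaning for span extraction.  Partials are
omitted when computing precision, recall and F1; reported metrics are rounded
half-up to four decimals alongside full-precision values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FoodnerError, UndefinedMetricError

Span = tuple[int, int]


class Outcome(Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class SpanMatch:
    """One matching decision; TP/PARTIAL carry both spans, FP/FN one side."""

    outcome: Outcome
    gold: Span | None = None
    pred: Span | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    partial: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.partial) < 0:
            raise FoodnerError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.partial + other.partial,
        )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float

    def rounded(self, decimals: int = 4) -> "Metrics":
        return Metrics(
            round_half_up(self.precision, decimals),
            round_half_up(self.recall, decimals),
            round_half_up(self.f1, decimals),
        )


def round_half_up(value: float, decimals: int = 4) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _check_non_overlapping(spans: Sequence[Span], side: str) -> list[Span]:
    ordered = sorted(spans)
    for (s1, e1), (s2, _e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise FoodnerError(
                f"{side} spans overlap within one recipe: ({s1},{e1}) and ({s2},{_e2})"
            )
    for s, e in ordered:
        if s >= e:
            raise FoodnerError(f"{side} span ({s},{e}) is empty or inverted")
    return ordered


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_chunks(gold: Sequence[Span], pred: Sequence[Span]) -> list[SpanMatch]:
    """Match gold and predicted spans of one recipe into outcomes.

    Pass 1 pairs exactly equal spans as TP; pass 2 pairs remaining
    overlapping spans greedily left-to-right as PARTIAL; pass 3 labels
    leftovers FP (pred) / FN (gold).  Every input span gets one outcome.
    """
    gold_sorted = _check_non_overlapping(gold, "gold")
    pred_sorted = _check_non_overlapping(pred, "predicted")

    matches: list[SpanMatch] = []
    gold_left: list[Span] = []
    pred_set = set(pred_sorted)
    used_pred: set[Span] = set()
    for g in gold_sorted:
        if g in pred_set and g not in used_pred:
            matches.append(SpanMatch(Outcome.TP, gold=g, pred=g))
            used_pred.add(g)
        else:
            gold_left.append(g)
    pred_left = [p for p in pred_sorted if p not in used_pred]

    gi = 0
    for p in pred_left:
        while gi < len(gold_left) and gold_left[gi][1] <= p[0]:
            matches.append(SpanMatch(Outcome.FN, gold=gold_left[gi]))
            gi += 1
        if gi < len(gold_left) and _overlaps(p, gold_left[gi]):
            matches.append(SpanMatch(Outcome.PARTIAL, gold=gold_left[gi], pred=p))
            gi += 1
        else:
            matches.append(SpanMatch(Outcome.FP, pred=p))
    for g in gold_left[gi:]:
        matches.append(SpanMatch(Outcome.FN, gold=g))
    return matches


def count_outcomes(matches: Iterable[SpanMatch]) -> ConfusionCounts:
    """Tally matching outcomes (possibly pooled over many recipes)."""
    tally = {outcome: 0 for outcome in Outcome}
    for match in matches:
        tally[match.outcome] += 1
    return ConfusionCounts(
        tp=tally[Outcome.TP],
        fp=tally[Outcome.FP],
        fn=tally[Outcome.FN],
        partial=tally[Outcome.PARTIAL],
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision, recall and F1 from counts; Partials are ignored.

    Full-precision values are returned; use ``.rounded()`` for reporting.
    """
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn == 0")
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision, recall, f1)


def f1_from_pr(precision: float, recall: float, decimals: int = 4) -> float:
    """Harmonic mean of already-rounded precision and recall, rounded half-up."""
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    return round_half_up(2 * precision * recall / (precision + recall), decimals)


def evaluate_corpora(gold_corpus, pred_corpus) -> ConfusionCounts:
    """Match predicted vs gold annotations document-by-document (by id)."""
    gold_docs = {doc.id: doc for doc in gold_corpus.documents}
    pred_docs = {doc.id: doc for doc in pred_corpus.documents}
    total = ConfusionCounts()
    for doc_id in sorted(set(gold_docs) | set(pred_docs)):
        gold_spans = [
            (ann.offset, ann.end)
            for doc in [gold_docs.get(doc_id)]
            if doc is not None
            for passage in doc.passages
            for ann in passage.annotations
        ]
        pred_spans = [
            (ann.offset, ann.end)
            for doc in [pred_docs.get(doc_id)]
            if doc is not None
            for passage in doc.passages
            for ann in passage.annotations
        ]
        total = total + count_outcomes(match_chunks(gold_spans, pred_spans))
    return total


def compare_methods(
    counts_by_method: Mapping[str, ConfusionCounts], decimals: int = 4
) -> pd.DataFrame:
    """Tabulate counts and derived metrics for several NER methods.

    Rows: TPs, FPs, FNs, Partials, precision, recall, f1; one column per
    method.  A method with undefined metrics keeps its counts and gets NaN
    metric cells.
    """
    if not counts_by_method:
        raise FoodnerError("compare_methods needs at least one method")
    table: dict[str, dict[str, float]] = {}
    for name, counts in counts_by_method.items():
        column: dict[str, float] = {
            "TPs": counts.tp,
            "FPs": counts.fp,
            "FNs": counts.fn,
            "Partials": counts.partial,
        }
        try:
            m = metrics(counts).rounded(decimals)
            column.update(precision=m.precision, recall=m.recall, f1=m.f1)
        except UndefinedMetricError:
            column.update(precision=float("nan"), recall=float("nan"), f1=float("nan"))
        table[name] = column
    return pd.DataFrame(table)
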