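"""Span matching (TP/FP/FN/Partial) and the Partials-omitted metrics."""

import math
import random

import pytest

from foodner import (
    ConfusionCounts,
    Outcome,
    compare_methods,
    count_outcomes,
    f1_from_pr,
    match_chunks,
    metrics,
)
from foodner.exceptions import FoodnerError, UndefinedMetricError

# Published comparison counts for the four NER methods on the same 1000
# recipes; used as input data for the metric computations.
METHOD_COUNTS = {
    "FoodIE": ConfusionCounts(tp=11461, fp=258, fn=684, partial=359),
    "SNOMED CT": ConfusionCounts(tp=5100, fp=472, fn=5327, partial=2705),
    "OF": ConfusionCounts(tp=2279, fp=378, fn=9026, partial=1591),
    "FoodOn": ConfusionCounts(tp=5725, fp=1502, fn=4968, partial=2365),
}


# --- matching -------------------------------------------------------------------


def outcomes(gold, pred):
    return count_outcomes(match_chunks(gold, pred))


def test_identical_lists_all_tp():
    spans = [(0, 4), (10, 15), (20, 30)]
    assert outcomes(spans, spans) == ConfusionCounts(tp=3)


def test_prediction_overrunning_gold_is_partial():
    # gold 'passion fruit juice' vs predicted 'empty passion fruit juice'
    gold = [(6, 25)]
    pred = [(0, 25)]
    assert outcomes(gold, pred) == ConfusionCounts(partial=1)


def test_mixed_outcomes():
    gold = [(0, 5), (10, 20), (30, 40)]
    pred = [(0, 5), (12, 25), (50, 60)]
    counts = outcomes(gold, pred)
    assert counts == ConfusionCounts(tp=1, fp=1, fn=1, partial=1)


def test_every_span_gets_exactly_one_outcome():
    rng = random.Random(11)
    for _ in range(50):
        gold = random_spans(rng, rng.randint(0, 8))
        pred = random_spans(rng, rng.randint(0, 8))
        matches = match_chunks(gold, pred)
        gold_seen = [m.gold for m in matches if m.gold is not None]
        pred_seen = [m.pred for m in matches if m.pred is not None]
        assert sorted(gold_seen) == sorted(gold)
        assert sorted(pred_seen) == sorted(pred)
        counts = count_outcomes(matches)
        assert counts.tp + counts.fn + counts.partial == len(gold)
        assert counts.tp + counts.fp + counts.partial == len(pred)


def test_overlapping_input_spans_rejected():
    with pytest.raises(FoodnerError, match="overlap"):
        match_chunks([(0, 5), (3, 8)], [])
    with pytest.raises(FoodnerError):
        match_chunks([], [(2, 2)])  # empty span


# --- exhaustive oracle ------------------------------------------------------------


def random_spans(rng, n, length=60):
    """n (or fewer) sorted non-overlapping spans inside [0, length)."""
    points = sorted(rng.sample(range(length), min(2 * n, length)))
    spans = []
    it = iter(points)
    for start, end in zip(it, it):
        if start < end:
            spans.append((start, end))
    return spans


def oracle_counts(gold, pred):
    """Brute force with the same precedence: exact pairs first, then the
    maximum number of disjoint overlapping pairs; leftovers are FP/FN."""
    exact = set(gold) & set(pred)
    gold_rest = [g for g in gold if g not in exact]
    pred_rest = [p for p in pred if p not in exact]

    best = 0

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    def recurse(index, used, count):
        nonlocal best
        best = max(best, count)
        if index == len(pred_rest):
            return
        recurse(index + 1, used, count)
        for gi, g in enumerate(gold_rest):
            if gi not in used and overlaps(pred_rest[index], g):
                recurse(index + 1, used | {gi}, count + 1)

    recurse(0, frozenset(), 0)
    tp = len(exact)
    return ConfusionCounts(
        tp=tp,
        fp=len(pred) - tp - best,
        fn=len(gold) - tp - best,
        partial=best,
    )


def test_matching_agrees_with_exhaustive_oracle():
    rng = random.Random(42)
    for _ in range(50):
        gold = random_spans(rng, rng.randint(0, 8))
        pred = random_spans(rng, rng.randint(0, 8))
        assert outcomes(gold, pred) == oracle_counts(gold, pred), (gold, pred)


def test_removing_a_partial_pair_changes_no_metric():
    gold = [(0, 5), (10, 20), (30, 40)]
    pred = [(0, 5), (12, 25), (30, 40)]
    with_partial = metrics(outcomes(gold, pred))
    without = metrics(outcomes([(0, 5), (30, 40)], [(0, 5), (30, 40)]))
    assert math.isclose(with_partial.precision, without.precision)
    assert math.isclose(with_partial.recall, without.recall)


# --- metrics --------------------------------------------------------------------


def test_count_outcomes_empty():
    assert count_outcomes([]) == ConfusionCounts()


def test_metrics_published_1000_recipe_counts():
    m = metrics(METHOD_COUNTS["FoodIE"]).rounded(4)
    assert (m.precision, m.recall, m.f1) == (0.9780, 0.9437, 0.9605)


@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(1, 0, 0), (1.0, 1.0, 1.0)),
        (ConfusionCounts(3, 1, 2), (0.75, 0.6, 0.6667)),
    ],
)
def test_metrics_hand_computed(counts, expected):
    m = metrics(counts).rounded(4)
    assert (m.precision, m.recall, m.f1) == expected


def test_metrics_scale_invariant():
    base = metrics(ConfusionCounts(3, 1, 2))
    for k in (2, 7, 100):
        scaled = metrics(ConfusionCounts(3 * k, 1 * k, 2 * k))
        assert math.isclose(base.precision, scaled.precision)
        assert math.isclose(base.recall, scaled.recall)
        assert math.isclose(base.f1, scaled.f1)


def test_metrics_partials_are_ignored():
    assert metrics(ConfusionCounts(3, 1, 2, partial=999)) == metrics(
        ConfusionCounts(3, 1, 2)
    )


def test_zero_denominators_raise():
    with pytest.raises(UndefinedMetricError):
        metrics(ConfusionCounts(0, 0, 5))
    with pytest.raises(UndefinedMetricError):
        metrics(ConfusionCounts(0, 5, 0))


@pytest.mark.parametrize(
    "p, r, expected",
    [(0.9761, 0.9430, 0.9593), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5)],
)
def test_f1_from_pr(p, r, expected):
    assert f1_from_pr(p, r) == expected


def test_compare_methods_table_shape_and_ordering():
    table = compare_methods(METHOD_COUNTS)
    assert list(table.index) == ["TPs", "FPs", "FNs", "Partials", "precision", "recall", "f1"]
    assert table.loc["TPs"].idxmax() == "FoodIE"
    assert table.loc["FPs"].idxmin() == "FoodIE"
    assert table.loc["FNs"].idxmin() == "FoodIE"
    # derived precision ordering checked against direct computation
    direct = {
        name: counts.tp / (counts.tp + counts.fp)
        for name, counts in METHOD_COUNTS.items()
    }
    assert direct["FoodIE"] > direct["SNOMED CT"] > direct["OF"]
    precisions = table.loc["precision"]
    assert precisions["FoodIE"] > precisions["SNOMED CT"] > precisions["OF"]


def test_compare_methods_single_method():
    table = compare_methods({"only": ConfusionCounts(1, 0, 0)})
    assert list(table.columns) == ["only"]


def test_compare_methods_continues_past_undefined():
    table = compare_methods(
        {"ok": ConfusionCounts(1, 0, 0), "broken": ConfusionCounts(0, 0, 5)}
    )
    assert math.isnan(table.loc["precision", "broken"])
    assert table.loc["precision", "ok"] == 1.0
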