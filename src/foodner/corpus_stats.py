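"""Descriptive statistics over an annotated recipe corpus.

Three per-corpus distributions mirror the standard corpus summary: number of
words per recipe (whitespace tokens of the stored passage text), number of
food entities per recipe, and number of semantic tags per entity — overall
and split by recipe category.  Summaries report mean, median, mode and the
sample (n−1) standard deviation; the mode tie-break takes the smallest value.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .bioc import AnnotatedCorpus
from .exceptions import FoodnerError


@dataclass(frozen=True)
class StatsSummary:
    mean: float
    median: float
    mode: float
    sd: float
    n: int

    def as_dict(self, decimals: int = 2) -> dict[str, float]:
        return {
            "mean": round(self.mean, decimals),
            "median": round(self.median, decimals),
            "mode": round(self.mode, decimals),
            "sd": round(self.sd, decimals),
            "n": self.n,
        }


def summarize(values: list[float]) -> StatsSummary:
    """Summarize a non-empty list; for n == 1 the sd is 0.0 by convention."""
    if not values:
        raise FoodnerError("cannot summarize an empty list")
    n = len(values)
    ordered = sorted(values)
    mean = sum(values) / n
    mid = n // 2
    median = float(ordered[mid]) if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2
    best_count = max(Counter(values).values())
    mode = min(v for v, c in Counter(values).items() if c == best_count)
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return StatsSummary(mean=mean, median=median, mode=float(mode), sd=sd, n=n)


@dataclass
class CorpusDistributions:
    words_per_recipe: list[int]
    entities_per_recipe: list[int]
    tags_per_entity: list[int]


def corpus_distributions(
    corpus: AnnotatedCorpus,
) -> tuple[CorpusDistributions, dict[str, CorpusDistributions]]:
    """Overall and per-category value lists for the three corpus distributions."""
    overall = CorpusDistributions([], [], [])
    by_category: dict[str, CorpusDistributions] = {}
    for doc in corpus.documents:
        words = sum(len(passage.text.split()) for passage in doc.passages)
        annotations = [ann for passage in doc.passages for ann in passage.annotations]
        cat = by_category.setdefault(doc.category, CorpusDistributions([], [], []))
        for dist in (overall, cat):
            dist.words_per_recipe.append(words)
            dist.entities_per_recipe.append(len(annotations))
            dist.tags_per_entity.extend(len(ann.tags) for ann in annotations)
    return overall, by_category


def tag_frequency(corpus: AnnotatedCorpus, k: int) -> list[tuple[str, int]]:
    """Top-k semantic-tag codes by annotation count.

    An annotation with t tags contributes to t codes; ties break
    lexicographically by code.
    """
    if k < 1:
        raise FoodnerError("k must be >= 1")
    counter: Counter[str] = Counter()
    for _doc, _passage, ann in corpus.iter_annotations():
        for tag in ann.tags:
            counter[tag.code] += 1
    ranked = sorted(counter.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def stats_report(corpus: AnnotatedCorpus, decimals: int = 2, top_k: int = 10) -> dict:
    """JSON-ready report mirroring the summary-table structure."""
    overall, by_category = corpus_distributions(corpus)

    def block(dist: CorpusDistributions) -> dict:
        out = {}
        for name in ("words_per_recipe", "entities_per_recipe", "tags_per_entity"):
            values = getattr(dist, name)
            out[name] = summarize(values).as_dict(decimals) if values else None
        return out

    return {
        "overall": block(overall),
        "by_category": {cat: block(dist) for cat, dist in sorted(by_category.items())},
        "top_tags": tag_frequency(corpus, top_k),
    }
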