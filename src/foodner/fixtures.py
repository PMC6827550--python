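"""Deterministic synthetic recipes with gold annotations and perturbations.

The generator assembles short English instruction sentences ("Preheat the
oven.", "Add {ingredient}.", "Mix {a} and {b}.") from a vocabulary drawn from
the bundled lexicon, recording each gold food-chunk span at assembly time —
offsets are never recovered by string search.  Because every emitted chunk is
lexicon-covered and every template word is not, the rule pipeline recovers the
gold annotations exactly; this makes the generator a ground-truth harness for
the end-to-end pipeline, the evaluation protocol and the curation machinery.

``perturb`` degrades a gold corpus by a requested number of spurious spans
(false positives), deletions (false negatives) and one-token span expansions
("empty passion fruit juice"-style partials), returning the exact expected
confusion counts and the curation edit list that restores the gold corpus.

Synthetic by design: template language is far simpler than real recipe prose
(no quantities, no anaphora, no brand names).
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .bioc import AnnotatedCorpus, Annotation, Document, Passage
from .evaluation import ConfusionCounts
from .exceptions import FixtureError
from .lexicon import FALLBACK_TAG, Lexicon, default_lexicon
from .pipeline import CATEGORIES, FoodChunk, Recipe, tokenize
from .tag_assigner import (
    CorrectionRule,
    CurationEdit,
    EditKind,
    assign_tags,
    default_rules,
    post_process,
)

#: instruction templates; the second element is the number of ingredient slots,
#: the third whether the slots are joined by a connector into ONE food chunk.
_TEMPLATES: tuple[tuple[str, int, bool], ...] = (
    ("Preheat the oven.", 0, False),
    ("Rinse the saucepan.", 0, False),
    ("Add {}.", 1, False),
    ("Serve with {}.", 1, False),
    ("Stir in the {}.", 1, False),
    ("Pour the {} into a bowl.", 1, False),
    ("Mix {} and {}.", 2, True),
    ("Combine {} with {}.", 2, False),
)

DEFAULT_VOCAB: tuple[str, ...] = (
    "milk",
    "butter",
    "cheese",
    "flour",
    "sugar",
    "honey",
    "bread",
    "onion",
    "garlic",
    "beef",
    "pork",
    "rice",
    "cauliflower",
    "kefir",
    "salmon",
    "potato",
    "lemon",
    "vanilla",
    "coffee",
    "water",
    "grilled chicken",
    "tortilla chips",
    "passion fruit juice",
    "cream of tartar",
    "mashed potato",
    "dry ranch salad dressing mix",
)

_EQUAL_MIX = {cat: 1 / len(CATEGORIES) for cat in CATEGORIES}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 7
    n_recipes: int = 6
    category_mix: Mapping[str, float] = field(default_factory=lambda: dict(_EQUAL_MIX))
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    min_sentences: int = 3
    max_sentences: int = 6
    perturbation: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.n_recipes < 1:
            raise FixtureError("n_recipes must be >= 1")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise FixtureError("category mix proportions must sum to 1")
        if any(cat not in CATEGORIES for cat in self.category_mix):
            raise FixtureError("category mix contains an unknown category")
        if len(self.vocab) < 2:
            raise FixtureError("vocabulary too small: need at least 2 ingredients")


def _category_counts(spec: FixtureSpec) -> list[str]:
    """Largest-remainder apportionment of n_recipes over the category mix."""
    items = sorted(spec.category_mix.items())
    quotas = [(cat, spec.n_recipes * prop) for cat, prop in items]
    counts = {cat: int(q) for cat, q in quotas}
    remainder = spec.n_recipes - sum(counts.values())
    by_fraction = sorted(quotas, key=lambda cq: (-(cq[1] - int(cq[1])), cq[0]))
    for cat, _q in by_fraction[:remainder]:
        counts[cat] += 1
    labels: list[str] = []
    for cat, _ in items:
        labels.extend([cat] * counts[cat])
    return labels


def _chunk_tags(surface: str, lexicon: Lexicon, rules: Sequence[CorrectionRule]):
    token_surfaces = tuple(surface.split())
    chunk = FoodChunk(
        start=0,
        end=len(surface),
        surface=surface,
        token_indices=tuple(range(len(token_surfaces))),
        token_surfaces=token_surfaces,
    )
    return post_process(chunk, assign_tags(chunk, lexicon), rules)


def generate(
    spec: FixtureSpec, lexicon: Lexicon | None = None
) -> tuple[list[Recipe], AnnotatedCorpus]:
    """Build recipes and their gold BioC corpus for a fixture specification."""
    if lexicon is None:
        lexicon = default_lexicon()
    rules = default_rules()
    rng = random.Random(spec.seed)
    categories = _category_counts(spec)
    recipes: list[Recipe] = []
    corpus = AnnotatedCorpus(source="foodner-fixtures", date="20190101", key="fixtures")

    for i, category in enumerate(categories, start=1):
        n_sentences = rng.randint(spec.min_sentences, spec.max_sentences)
        parts: list[str] = []
        spans: list[tuple[int, int, str]] = []  # (start, end, surface)
        cursor = 0
        for _ in range(n_sentences):
            template, n_slots, joined = _TEMPLATES[rng.randrange(len(_TEMPLATES))]
            ingredients = [rng.choice(spec.vocab) for _ in range(n_slots)]
            prefix_len = len(template.split("{}")[0])
            sentence = template.format(*ingredients)
            if n_slots == 1:
                start = cursor + prefix_len
                spans.append((start, start + len(ingredients[0]), ingredients[0]))
            elif n_slots == 2:
                a, b = ingredients
                start_a = cursor + prefix_len
                middle = template.split("{}")[1]
                start_b = start_a + len(a) + len(middle)
                if joined:
                    surface = sentence[prefix_len : start_b - cursor + len(b)]
                    spans.append((start_a, start_b + len(b), surface))
                else:
                    spans.append((start_a, start_a + len(a), a))
                    spans.append((start_b, start_b + len(b), b))
            parts.append(sentence)
            cursor += len(sentence) + 1  # sentences joined with one space
        text = " ".join(parts)
        recipe = Recipe(id=f"r{i:03d}", category=category, text=text)
        recipes.append(recipe)
        passage = Passage(offset=0, text=text)
        for j, (start, end, surface) in enumerate(spans, start=1):
            assert text[start:end] == surface
            passage.annotations.append(
                Annotation(
                    id=str(j),
                    text=surface,
                    offset=start,
                    length=end - start,
                    tags=_chunk_tags(surface, lexicon, rules),
                )
            )
        corpus.documents.append(Document(id=recipe.id, category=category, passages=[passage]))
    corpus.validate()
    return recipes, corpus


def _word_span_before(text: str, offset: int) -> tuple[int, int] | None:
    """Span of the whitespace-separated word immediately before *offset*."""
    if offset < 2 or text[offset - 1] != " ":
        return None
    end = offset - 1
    start = end
    while start > 0 and text[start - 1] != " ":
        start -= 1
    return (start, end) if start < end else None


def perturb(
    gold: AnnotatedCorpus, n_fp: int = 0, n_fn: int = 0, n_partial: int = 0, seed: int = 0
) -> tuple[AnnotatedCorpus, ConfusionCounts, list[CurationEdit]]:
    """Degrade a gold corpus by exact FP/FN/Partial counts.

    Returns the perturbed (predicted) corpus, the confusion counts the
    evaluation protocol must report for (gold, perturbed), and the curation
    edits that restore the gold corpus.
    """
    pred = copy.deepcopy(gold)
    rng = random.Random(seed)
    edits: list[CurationEdit] = []

    all_refs = [
        (doc, passage, ann)
        for doc in pred.documents
        for passage in doc.passages
        for ann in passage.annotations
    ]
    total = len(all_refs)
    if n_fn + n_partial > total:
        raise FixtureError(
            f"requested {n_fn} FNs + {n_partial} partials but corpus has {total} annotations"
        )

    expandable = [
        ref
        for ref in all_refs
        if (span := _word_span_before(ref[1].text, ref[2].offset)) is not None
        and not any(
            other.end > span[0] and other.offset < span[1]
            for other in ref[1].annotations
            if other is not ref[2]
        )
    ]
    if n_partial > len(expandable):
        raise FixtureError(f"only {len(expandable)} annotations can be expanded to partials")
    partial_refs = rng.sample(expandable, n_partial)
    partial_ids = {id(ref[2]) for ref in partial_refs}
    fn_pool = [ref for ref in all_refs if id(ref[2]) not in partial_ids]
    fn_refs = rng.sample(fn_pool, n_fn)

    for doc, passage, ann in fn_refs:
        passage.annotations.remove(ann)
        edits.append(
            CurationEdit(
                kind=EditKind.INCLUDE_FN,
                recipe_id=doc.id,
                start=ann.offset,
                end=ann.end,
                text=ann.text,
                tags=ann.tags,
            )
        )

    for doc, passage, ann in partial_refs:
        word_start, _word_end = _word_span_before(passage.text, ann.offset)
        expanded = Annotation(
            id=ann.id,
            text=passage.text[word_start : ann.end],
            offset=word_start,
            length=ann.end - word_start,
            tags=ann.tags,
        )
        passage.annotations[passage.annotations.index(ann)] = expanded
        edits.append(
            CurationEdit(
                kind=EditKind.EXCLUDE_FP,
                recipe_id=doc.id,
                start=expanded.offset,
                end=expanded.end,
                text=expanded.text,
            )
        )
        edits.append(
            CurationEdit(
                kind=EditKind.INCLUDE_FN,
                recipe_id=doc.id,
                start=ann.offset,
                end=ann.end,
                text=ann.text,
                tags=ann.tags,
            )
        )

    gold_spans = {
        doc.id: [(ann.offset, ann.end) for p in doc.passages for ann in p.annotations]
        for doc in gold.documents
    }
    candidates = []
    for doc in pred.documents:
        for passage in doc.passages:
            taken = [(a.offset, a.end) for a in passage.annotations] + gold_spans[doc.id]
            for token in tokenize(passage.text):
                if not token.surface.isalpha() or len(token.surface) < 2:
                    continue
                if any(token.end > s and token.start < e for s, e in taken):
                    continue
                candidates.append((doc, passage, token))
    if n_fp > len(candidates):
        raise FixtureError(f"only {len(candidates)} token spans available for FP injection")
    for doc, passage, token in rng.sample(candidates, n_fp):
        fp_ann = Annotation(
            id=f"fp{token.start}",
            text=token.surface,
            offset=token.start,
            length=token.end - token.start,
            tags=frozenset({FALLBACK_TAG}),
        )
        passage.annotations.append(fp_ann)
        edits.append(
            CurationEdit(
                kind=EditKind.EXCLUDE_FP,
                recipe_id=doc.id,
                start=fp_ann.offset,
                end=fp_ann.end,
                text=fp_ann.text,
            )
        )

    for doc in pred.documents:
        for passage in doc.passages:
            passage.annotations.sort(key=lambda a: (a.offset, a.length))
    pred.validate()
    # excludes must run before includes so partial restorations never collide
    edits.sort(key=lambda e: 0 if e.kind is EditKind.EXCLUDE_FP else 1)
    expected = ConfusionCounts(
        tp=total - n_fn - n_partial, fp=n_fp, fn=n_fn, partial=n_partial
    )
    return pred, expected, edits
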