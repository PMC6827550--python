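"""Semantic-tag assignment for food chunks, plus corrections and curation.

A chunk's candidate tags are the union of its tokens' lexicon tags, filtered
through a fallback ladder: keep the Food-and-drink (AG) subset when present;
otherwise keep Animals/Plants (AE/AF) tags; otherwise fall back to the
top-level ``AG.01[Food]`` tag, so every chunk carries at least one tag.

Two correction layers follow.  Token-triggered rules fix systematic tagger
artefacts (e.g. a tea-manufacture tag riding along with every 'mixture');
they ship as a small TSV table users can extend.  Curation edits are an
explicit, replayable record of manual corpus review: excluding false
positives, inserting missed entities, and adding/removing individual tags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .bioc import AnnotatedCorpus, Annotation, next_annotation_id
from .exceptions import CurationError, LexiconError
from .lexicon import FALLBACK_TAG, Lexicon, SemanticTag, parse_tag
from .pipeline import FoodChunk


def assign_tags(chunk: FoodChunk, lexicon: Lexicon) -> frozenset[SemanticTag]:
    """Tag a chunk from the union of its tokens' lexicon tags (AG → AE/AF →
    ``AG.01[Food]`` fallback ladder)."""
    union: set[SemanticTag] = set()
    for surface in chunk.token_surfaces:
        union |= lexicon.lookup(surface)
    ag = {t for t in union if t.category == "AG"}
    if ag:
        return frozenset(ag)
    if union:
        return frozenset(union)
    return frozenset({FALLBACK_TAG})


class RuleAction(Enum):
    REMOVE_TAG = "REMOVE_TAG"
    REPLACE_TAG = "REPLACE_TAG"


@dataclass(frozen=True)
class CorrectionRule:
    """Token-triggered tag correction: when *trigger* occurs in a chunk,
    remove (or replace) *tag* in that chunk's tag set."""

    trigger: str
    action: RuleAction
    tag: SemanticTag
    replacement: SemanticTag | None = None

    def __post_init__(self) -> None:
        if not self.trigger:
            raise ValueError("correction rule trigger must be non-empty")
        if self.action is RuleAction.REPLACE_TAG and self.replacement is None:
            raise ValueError("REPLACE_TAG rule needs a replacement tag")


def post_process(
    chunk: FoodChunk,
    tags: Iterable[SemanticTag],
    rules: Sequence[CorrectionRule],
) -> frozenset[SemanticTag]:
    """Apply every rule whose trigger occurs (case-insensitively) among the
    chunk's tokens; an emptied tag set is restored to ``AG.01[Food]``.
    Idempotent for a fixed rule table."""
    result = set(tags)
    chunk_tokens = {surface.lower() for surface in chunk.token_surfaces}
    for rule in rules:
        if rule.trigger not in chunk_tokens:
            continue
        if rule.tag in result:
            result.discard(rule.tag)
            if rule.action is RuleAction.REPLACE_TAG and rule.replacement is not None:
                result.add(rule.replacement)
    if not result:
        result.add(FALLBACK_TAG)
    return frozenset(result)


def load_rules(path: str | Path) -> list[CorrectionRule]:
    """Load a correction-rule TSV: ``trigger<TAB>ACTION<TAB>TAG[<TAB>REPLACEMENT]``."""
    rules = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise LexiconError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
        try:
            action = RuleAction(fields[1])
        except ValueError as exc:
            raise LexiconError(f"{path}:{lineno}: unknown action {fields[1]!r}") from exc
        replacement = parse_tag(fields[3]) if len(fields) == 4 else None
        rules.append(
            CorrectionRule(
                trigger=fields[0].lower(),
                action=action,
                tag=parse_tag(fields[2]),
                replacement=replacement,
            )
        )
    return rules


def default_rules() -> list[CorrectionRule]:
    """The bundled rule table (the 'mixture', 'mashed' and 'water' fixes)."""
    from importlib.resources import files

    return load_rules(Path(str(files("foodner.data") / "rules.tsv")))


class EditKind(Enum):
    EXCLUDE_FP = "EXCLUDE_FP"
    INCLUDE_FN = "INCLUDE_FN"
    REMOVE_TAG = "REMOVE_TAG"
    ADD_TAG = "ADD_TAG"


@dataclass(frozen=True)
class CurationEdit:
    """One replayable manual-review edit against an annotated corpus."""

    kind: EditKind
    recipe_id: str
    start: int
    end: int
    text: str
    tags: frozenset[SemanticTag] = frozenset()


def _find_annotation(doc_passages, edit: CurationEdit):
    for passage in doc_passages:
        for i, ann in enumerate(passage.annotations):
            if ann.offset == edit.start and ann.end == edit.end:
                return passage, i, ann
    return None


def apply_curation(
    corpus: AnnotatedCorpus, edits: Sequence[CurationEdit]
) -> AnnotatedCorpus:
    """Replay curation edits, in order, against a copy of the corpus.

    EXCLUDE_FP removes the referenced annotation; INCLUDE_FN inserts a new one
    (its text must equal the passage slice at the stated offsets); REMOVE_TAG /
    ADD_TAG mutate an annotation's tag set, never leaving it empty.  An empty
    edit list is the identity.
    """
    import copy

    result = copy.deepcopy(corpus)
    docs_by_id = {doc.id: doc for doc in result.documents}
    for edit in edits:
        doc = docs_by_id.get(edit.recipe_id)
        if doc is None:
            raise CurationError(f"edit references unknown recipe {edit.recipe_id!r}: {edit}")
        if edit.kind is EditKind.INCLUDE_FN:
            passage = doc.passages[0]
            rel = edit.start - passage.offset
            if passage.text[rel : rel + (edit.end - edit.start)] != edit.text:
                raise CurationError(
                    f"INCLUDE_FN text {edit.text!r} does not match recipe "
                    f"{edit.recipe_id!r} slice at {edit.start}:{edit.end}"
                )
            if not edit.tags:
                raise CurationError(f"INCLUDE_FN needs at least one tag: {edit}")
            new_ann = Annotation(
                id=next_annotation_id(doc),
                text=edit.text,
                offset=edit.start,
                length=edit.end - edit.start,
                tags=frozenset(edit.tags),
            )
            passage.annotations.append(new_ann)
            passage.annotations.sort(key=lambda a: (a.offset, a.length))
            continue
        found = _find_annotation(doc.passages, edit)
        if found is None:
            raise CurationError(
                f"edit references missing annotation at {edit.start}:{edit.end} "
                f"in recipe {edit.recipe_id!r}: {edit}"
            )
        passage, index, ann = found
        if edit.kind is EditKind.EXCLUDE_FP:
            passage.annotations.pop(index)
        elif edit.kind is EditKind.REMOVE_TAG:
            tags = set(ann.tags) - set(edit.tags)
            if not tags:
                tags = {FALLBACK_TAG}
            passage.annotations[index] = replace(ann, tags=frozenset(tags))
        elif edit.kind is EditKind.ADD_TAG:
            passage.annotations[index] = replace(
                ann, tags=frozenset(set(ann.tags) | set(edit.tags))
            )
    result.validate()
    return result
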