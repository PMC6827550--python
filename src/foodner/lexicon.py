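"""Hierarchical semantic tags and token-level lexicon lookup.

Food entities are annotated with tags drawn from a Hansard-corpus-style
hierarchy: dot-separated codes such as ``AG.01.h.02.d`` ("Cabbage/kale")
under three top-level categories — ``AG`` (Food and drink), ``AE`` (Animals)
and ``AF`` (Plants).  The lexicon maps normalized token lemmas to sets of
such tags; it is the pluggable knowledge resource the NER pipeline consumes.
Tags written with colons (``AG:01``) are accepted on parse and normalized to
the dot dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import LexiconError, TagParseError

TOP_CATEGORIES = ("AG", "AE", "AF")

#: one hierarchy component below the top category: "01", "h", "af", "b2"
_COMPONENT_RE = re.compile(r"^(?:\d{2}|[a-z]{1,2}|[a-z]\d)$")
_TAG_RE = re.compile(r"^\s*(?P<code>[A-Za-z0-9.:]+)\s?\[(?P<label>[^\[\]]*)\]\s*$")

FALLBACK_TAG_STRING = "AG.01[Food]"


@dataclass(frozen=True, order=True)
class SemanticTag:
    """One hierarchical semantic tag, e.g. code ``AG.01.t.07``, label ``Cooking``."""

    code: str
    label: str = field(compare=False, default="")

    @property
    def category(self) -> str:
        return self.code.split(".", 1)[0]

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.code.split("."))

    def __str__(self) -> str:  # bracket notation
        return format_tag(self)


class FoodEvidence(Enum):
    """How strongly a tag set supports food-hood: AG beats AE/AF beats nothing."""

    STRONG = "STRONG"
    WEAK = "WEAK"
    NONE = "NONE"


def _validate_code(code: str, source: str) -> str:
    parts = code.replace(":", ".").split(".")
    if parts[0] not in TOP_CATEGORIES:
        raise TagParseError(f"unknown top category {parts[0]!r} in tag {source!r}")
    for part in parts[1:]:
        if not _COMPONENT_RE.match(part):
            raise TagParseError(f"bad code component {part!r} in tag {source!r}")
    return ".".join(parts)


def parse_tag(tag_string: str) -> SemanticTag:
    """Parse bracket notation ``CODE[Label]`` (optional space before the bracket).

    >>> parse_tag("AG.01.h.02.d [Cabbage/kale]").code
    'AG.01.h.02.d'
    """
    match = _TAG_RE.match(tag_string)
    if match is None:
        raise TagParseError(f"malformed semantic tag {tag_string!r}")
    code = _validate_code(match.group("code"), tag_string)
    return SemanticTag(code=code, label=match.group("label").strip())


def format_tag(tag: SemanticTag) -> str:
    """Render a tag in the canonical no-space dialect ``CODE[Label]``."""
    return f"{tag.code}[{tag.label}]"


def parent(tag: SemanticTag, registry: Mapping[str, str] | None = None) -> SemanticTag | None:
    """Drop the final code component; ``None`` for a bare top category.

    Parent labels are resolved from *registry* (code → label) when available,
    otherwise left empty: the full tag inventory is not bundled.
    """
    parts = tag.components
    if len(parts) == 1:
        return None
    code = ".".join(parts[:-1])
    label = (registry or {}).get(code, "")
    return SemanticTag(code=code, label=label)


FALLBACK_TAG = parse_tag(FALLBACK_TAG_STRING)


def food_evidence(tags: Iterable[SemanticTag]) -> FoodEvidence:
    """STRONG if any AG tag, else WEAK if any AE/AF tag, else NONE."""
    level = FoodEvidence.NONE
    for tag in tags:
        if tag.category == "AG":
            return FoodEvidence.STRONG
        if tag.category in ("AE", "AF"):
            level = FoodEvidence.WEAK
    return level


def _normalize(token_text: str) -> str:
    return " ".join(token_text.lower().split())


@dataclass
class Lexicon:
    """Normalized lemma → set of semantic tags, plus a code → label registry.

    The registry is built from the tags seen in the lexicon file and is used
    to resolve labels for hierarchy parents.
    """

    entries: dict[str, frozenset[SemanticTag]] = field(default_factory=dict)
    registry: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lemma, tags in self.entries.items():
            if lemma != _normalize(lemma):
                raise LexiconError(f"lexicon key {lemma!r} is not normalized")
            if not tags:
                raise LexiconError(f"lexicon entry {lemma!r} has no tags")
            for tag in tags:
                self.registry.setdefault(tag.code, tag.label)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, lemma: str, tags: Iterable[SemanticTag]) -> None:
        lemma = _normalize(lemma)
        merged = frozenset(self.entries.get(lemma, frozenset())) | frozenset(tags)
        self.entries[lemma] = merged
        for tag in merged:
            self.registry.setdefault(tag.code, tag.label)

    def lookup(self, token_text: str) -> frozenset[SemanticTag]:
        """Case-insensitive lookup with naive plural stripping ("s", then "es")."""
        norm = _normalize(token_text)
        hit = self.entries.get(norm)
        if hit is None and norm.endswith("s"):
            hit = self.entries.get(norm[:-1])
        if hit is None and norm.endswith("es"):
            hit = self.entries.get(norm[:-2])
        return hit if hit is not None else frozenset()

    def evidence(self, token_text: str) -> FoodEvidence:
        return food_evidence(self.lookup(token_text))


def lookup(lexicon: Lexicon, token_text: str) -> frozenset[SemanticTag]:
    return lexicon.lookup(token_text)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a TSV lexicon: ``lemma<TAB>TAG[;TAG...]``; '#' lines are comments.

    Duplicate lemma rows are merged by tag-set union.
    """
    lexicon = Lexicon()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated fields")
        lemma, tag_field = fields
        try:
            tags = [parse_tag(part) for part in tag_field.split(";") if part.strip()]
        except TagParseError as exc:
            raise LexiconError(f"{path}:{lineno}: {exc}") from exc
        if not tags:
            raise LexiconError(f"{path}:{lineno}: no tags for lemma {lemma!r}")
        lexicon.add(lemma, tags)
    return lexicon


def default_lexicon() -> Lexicon:
    """The bundled fixture lexicon (small, synthetic coverage)."""
    from importlib.resources import files

    return load_lexicon(Path(str(files("foodner.data") / "lexicon.tsv")))
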