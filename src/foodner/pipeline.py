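"""The rule-based food NER pipeline.

Steps, in order: clean the raw recipe text (transliteration, character
whitelist, whitespace collapse), tokenize with character offsets, POS-tag
with a two-tagger ensemble, classify each token into one of four classes
(FOOD_HEAD, FOOD_MOD, CONNECTOR, NON_FOOD) using lexicon evidence, and chain
classified tokens into food chunks — contiguous token runs that each name a
single food concept.  The pipeline is fully deterministic: no step uses
randomness, so identical input always yields identical chunks.

POS taggers are pluggable: any callable mapping a token sequence to an
equal-length sequence of coarse labels satisfies the contract.  Two
deterministic reference taggers ship with the package (`LexiconRuleTagger`,
`SuffixRuleTagger`); they differ on purpose so the ensemble has genuine
disagreements to resolve.
"""

from __future__ import annotations

import re
import string
import unicodedata
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

from .exceptions import TaggerContractError
from .lexicon import FoodEvidence, Lexicon, SemanticTag

CATEGORIES = (
    "Appetizers/Snacks",
    "Breakfast/Lunch",
    "Dessert",
    "Dinner",
    "Drinks",
)
UNKNOWN_CATEGORY = "unknown"

DEFAULT_CONNECTORS = frozenset({"of", "and", "-", "&"})


class PosLabel(Enum):
    NOUN = "NOUN"
    PROPN = "PROPN"
    ADJ = "ADJ"
    VERB = "VERB"
    VERB_PART = "VERB_PART"
    ADV = "ADV"
    DET = "DET"
    ADP = "ADP"
    CCONJ = "CCONJ"
    NUM = "NUM"
    PUNCT = "PUNCT"
    OTHER = "OTHER"


class TokenClass(Enum):
    FOOD_HEAD = "FOOD_HEAD"
    FOOD_MOD = "FOOD_MOD"
    CONNECTOR = "CONNECTOR"
    NON_FOOD = "NON_FOOD"


@dataclass(frozen=True)
class Recipe:
    """One recipe: an id, a category from the five dish groups, and free text."""

    id: str
    category: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("recipe id must be non-empty")
        if self.category not in CATEGORIES and self.category != UNKNOWN_CATEGORY:
            raise ValueError(f"unknown recipe category {self.category!r}")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    pos: PosLabel | None = None
    token_class: TokenClass | None = None


@dataclass(frozen=True)
class FoodChunk:
    """A contiguous token span naming one food concept, with cleaned-text offsets."""

    start: int
    end: int
    surface: str
    token_indices: tuple[int, ...]
    token_surfaces: tuple[str, ...]
    tags: frozenset[SemanticTag] = frozenset()


# --- step 1: pre-processing -------------------------------------------------

_ALLOWED_CHARS = frozenset(string.ascii_letters + string.digits + ".,;:()'/-%")


def preprocess(raw_text: str) -> str:
    """Clean raw recipe text: transliterate to ASCII, whitelist characters,
    collapse whitespace.  Idempotent; the output is the authoritative text all
    offsets refer to."""
    text = unicodedata.normalize("NFKD", raw_text)
    text = text.encode("ascii", "ignore").decode("ascii")
    text = "".join(c if c in _ALLOWED_CHARS or c.isspace() else " " for c in text)
    return " ".join(text.split())


# --- step 1b: tokenization --------------------------------------------------

_TOKEN_RE = re.compile(r"[.,;:()]|[^\s.,;:()]+")


def tokenize(cleaned: str) -> list[Token]:
    """Whitespace tokenization with ``.,;:()`` split off as their own tokens;
    hyphens and apostrophes stay inside tokens."""
    return [
        Token(surface=m.group(0), start=m.start(), end=m.end())
        for m in _TOKEN_RE.finditer(cleaned)
    ]


# --- step 2: POS tagging ----------------------------------------------------

Tagger = Callable[[Sequence[Token]], Sequence[PosLabel]]

_DETS = frozenset("a an the this that these those some any each every all".split())
_ADPS = frozenset(
    "of in on with for to from into over under at by until about through onto".split()
)
_CCONJS = frozenset({"and", "or", "but", "nor", "&"})
_ADVS = frozenset(
    "well thoroughly gently lightly evenly immediately then together aside completely".split()
)
_PRONOUNS = frozenset("it they you we i them your its".split())
# imperative cooking verbs that are verbs in any position
_PURE_VERBS = frozenset(
    """add serve bake stir combine pour heat drain preheat place cook boil simmer
    remove cover sprinkle spread bring let cut chop slice beat whisk fold garnish
    season grease arrange transfer repeat refrigerate chill cool reduce melt""".split()
)
# verb/noun homographs: verbs sentence-initially (imperatives), nouns elsewhere
_AMBIG_VERB_NOUN = frozenset("mix grill blend whip toast roast steam".split())

_SENTENCE_BREAKS = frozenset({".", ";", ":"})


def _sentence_initial_flags(tokens: Sequence[Token]) -> list[bool]:
    flags = []
    initial = True
    for token in tokens:
        flags.append(initial)
        initial = token.surface in _SENTENCE_BREAKS
    return flags


def _closed_class(lower: str) -> PosLabel | None:
    if lower in _DETS:
        return PosLabel.DET
    if lower in _CCONJS:
        return PosLabel.CCONJ
    if lower in _ADPS:
        return PosLabel.ADP
    if lower in _ADVS:
        return PosLabel.ADV
    if lower in _PRONOUNS:
        return PosLabel.OTHER
    return None


class LexiconRuleTagger:
    """Deterministic tagger that treats lexicon-known tokens as nouns.

    Rule order: punctuation/number → closed classes → adjectives → '-ed'
    participles → imperative verbs (positional for homographs) → lexicon
    nouns → '-ly' adverbs → default NOUN.
    """

    ADJECTIVES = frozenset(
        "dry fresh hot cold large small medium empty golden soft firm smooth fine warm ripe".split()
    )

    def __init__(self, lexicon: Lexicon | None = None, extra_nouns: Iterable[str] = ()):
        self.lexicon = lexicon
        self.extra_nouns = frozenset(w.lower() for w in extra_nouns)

    def __call__(self, tokens: Sequence[Token]) -> list[PosLabel]:
        labels = []
        for token, initial in zip(tokens, _sentence_initial_flags(tokens)):
            labels.append(self._tag_one(token.surface, initial))
        return labels

    def _tag_one(self, surface: str, sentence_initial: bool) -> PosLabel:
        lower = surface.lower()
        if all(c in ".,;:()" for c in lower):
            return PosLabel.PUNCT
        if re.fullmatch(r"\d+([./-]\d+)*%?", lower):
            return PosLabel.NUM
        closed = _closed_class(lower)
        if closed is not None:
            return closed
        if lower in self.ADJECTIVES:
            return PosLabel.ADJ
        if lower.endswith("ed") and len(lower) > 3:
            return PosLabel.VERB_PART
        if lower in _PURE_VERBS:
            return PosLabel.VERB
        if lower in _AMBIG_VERB_NOUN:
            return PosLabel.VERB if sentence_initial else PosLabel.NOUN
        known_noun = lower in self.extra_nouns or (
            self.lexicon is not None and bool(self.lexicon.lookup(lower))
        )
        if known_noun:
            return PosLabel.NOUN
        if lower.endswith("ly") and len(lower) > 3:
            return PosLabel.ADV
        return PosLabel.NOUN


class SuffixRuleTagger:
    """Deterministic suffix/closed-class tagger with no lexicon knowledge.

    Differs from :class:`LexiconRuleTagger` by tagging '-ing' forms as
    participles and a few stative verbs ('empty', 'top', 'set') as verbs —
    deliberate disagreements for the ensemble to arbitrate.
    """

    VERBS = _PURE_VERBS | frozenset({"empty", "top", "set", "fill", "turn"})

    def __call__(self, tokens: Sequence[Token]) -> list[PosLabel]:
        labels = []
        for token, initial in zip(tokens, _sentence_initial_flags(tokens)):
            labels.append(self._tag_one(token.surface, initial))
        return labels

    def _tag_one(self, surface: str, sentence_initial: bool) -> PosLabel:
        lower = surface.lower()
        if all(c in ".,;:()" for c in lower):
            return PosLabel.PUNCT
        if re.fullmatch(r"\d+([./-]\d+)*%?", lower):
            return PosLabel.NUM
        closed = _closed_class(lower)
        if closed is not None:
            return closed
        if lower in self.VERBS:
            return PosLabel.VERB
        if lower in _AMBIG_VERB_NOUN:
            return PosLabel.VERB if sentence_initial else PosLabel.NOUN
        if lower.endswith("ed") and len(lower) > 3:
            return PosLabel.VERB_PART
        if lower.endswith("ing") and len(lower) > 4:
            return PosLabel.VERB_PART
        if lower.endswith("ly") and len(lower) > 3:
            return PosLabel.ADV
        if surface[:1].isupper() and not sentence_initial:
            return PosLabel.PROPN
        return PosLabel.NOUN


def pos_tag(tokens: Sequence[Token], tagger: Tagger) -> list[PosLabel]:
    """Apply a tagger and enforce the one-label-per-token contract."""
    labels = list(tagger(tokens))
    if len(labels) != len(tokens):
        raise TaggerContractError(
            f"tagger returned {len(labels)} labels for {len(tokens)} tokens"
        )
    return labels


#: preference order for the noun/adjectival reading on food-evidence tokens
_ENSEMBLE_PRIORITY = {PosLabel.NOUN: 0, PosLabel.ADJ: 1, PosLabel.VERB_PART: 2}


def ensemble_pos(
    labels_a: Sequence[PosLabel],
    labels_b: Sequence[PosLabel],
    tokens: Sequence[Token],
    lexicon: Lexicon,
) -> list[PosLabel]:
    """Merge two taggers' outputs.

    Agreements are kept.  On disagreement, a token with lexicon food evidence
    takes the noun/adjectival reading (NOUN > ADJ > VERB_PART); with no food
    evidence, tagger A wins — which reproduces the known failure mode where a
    contextual verb like 'empty' survives as an adjective.
    """
    if not (len(labels_a) == len(labels_b) == len(tokens)):
        raise TaggerContractError("ensemble inputs must have equal lengths")
    merged = []
    for label_a, label_b, token in zip(labels_a, labels_b, tokens):
        if label_a == label_b:
            merged.append(label_a)
            continue
        if lexicon.evidence(token.surface) is not FoodEvidence.NONE:
            candidates = [
                lab for lab in (label_a, label_b) if lab in _ENSEMBLE_PRIORITY
            ]
            if candidates:
                merged.append(min(candidates, key=_ENSEMBLE_PRIORITY.__getitem__))
                continue
        merged.append(label_a)
    return merged


# --- step 3: token classification -------------------------------------------


def classify_tokens(
    tokens: Sequence[Token],
    pos_labels: Sequence[PosLabel],
    lexicon: Lexicon,
    connectors: frozenset[str] = DEFAULT_CONNECTORS,
) -> list[TokenClass]:
    """Four-class rule engine.

    FOOD_HEAD: noun/proper-noun with food evidence; FOOD_MOD: adjective or
    participle with food evidence; CONNECTOR: a connector word whose nearest
    non-connector neighbours on both sides are food tokens; else NON_FOOD.
    Connector resolution runs after head/mod assignment.
    """
    if len(tokens) != len(pos_labels):
        raise TaggerContractError("tokens and POS labels must have equal lengths")
    classes: list[TokenClass] = []
    for token, pos in zip(tokens, pos_labels):
        evidence = lexicon.evidence(token.surface)
        if pos in (PosLabel.NOUN, PosLabel.PROPN) and evidence is not FoodEvidence.NONE:
            classes.append(TokenClass.FOOD_HEAD)
        elif pos in (PosLabel.ADJ, PosLabel.VERB_PART) and evidence is not FoodEvidence.NONE:
            classes.append(TokenClass.FOOD_MOD)
        else:
            classes.append(TokenClass.NON_FOOD)

    food = (TokenClass.FOOD_HEAD, TokenClass.FOOD_MOD)
    is_conn_word = [t.surface.lower() in connectors for t in tokens]
    for i, token in enumerate(tokens):
        if not is_conn_word[i] or classes[i] in food:
            continue
        left = i - 1
        while left >= 0 and is_conn_word[left] and classes[left] not in food:
            left -= 1
        right = i + 1
        while right < len(tokens) and is_conn_word[right] and classes[right] not in food:
            right += 1
        if (
            left >= 0
            and right < len(tokens)
            and classes[left] in food
            and classes[right] in food
        ):
            classes[i] = TokenClass.CONNECTOR
    return classes


# --- step 4: chunking ---------------------------------------------------------


def extract_chunks(tokens: Sequence[Token], cleaned_text: str) -> list[FoodChunk]:
    """Chain classified tokens into food chunks.

    Chunks are maximal contiguous runs of {FOOD_HEAD, FOOD_MOD, CONNECTOR};
    runs without a FOOD_HEAD are dropped and boundary CONNECTORs trimmed.
    """
    chunky = (TokenClass.FOOD_HEAD, TokenClass.FOOD_MOD, TokenClass.CONNECTOR)
    chunks: list[FoodChunk] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        indices = list(run)
        run.clear()
        if not any(tokens[i].token_class is TokenClass.FOOD_HEAD for i in indices):
            return
        while tokens[indices[0]].token_class is TokenClass.CONNECTOR:
            indices.pop(0)
        while tokens[indices[-1]].token_class is TokenClass.CONNECTOR:
            indices.pop()
        start = tokens[indices[0]].start
        end = tokens[indices[-1]].end
        chunks.append(
            FoodChunk(
                start=start,
                end=end,
                surface=cleaned_text[start:end],
                token_indices=tuple(indices),
                token_surfaces=tuple(tokens[i].surface for i in indices),
            )
        )

    for i, token in enumerate(tokens):
        if token.token_class in chunky:
            run.append(i)
        else:
            flush()
    flush()
    return chunks


# --- end-to-end ---------------------------------------------------------------


def annotate_recipe(
    recipe: Recipe,
    lexicon: Lexicon,
    tagger_a: Tagger | None = None,
    tagger_b: Tagger | None = None,
    rules: Sequence["CorrectionRule"] | None = None,  # noqa: F821
    connectors: frozenset[str] = DEFAULT_CONNECTORS,
) -> list[FoodChunk]:
    """Run the full pipeline on one recipe and return tagged food chunks."""
    from .tag_assigner import assign_tags, default_rules, post_process

    if tagger_a is None:
        tagger_a = LexiconRuleTagger(lexicon)
    if tagger_b is None:
        tagger_b = SuffixRuleTagger()
    if rules is None:
        rules = default_rules()

    cleaned = preprocess(recipe.text)
    tokens = tokenize(cleaned)
    labels_a = pos_tag(tokens, tagger_a)
    labels_b = pos_tag(tokens, tagger_b)
    labels = ensemble_pos(labels_a, labels_b, tokens, lexicon)
    classes = classify_tokens(tokens, labels, lexicon, connectors=connectors)
    tokens = [
        replace(tok, pos=pos, token_class=cls)
        for tok, pos, cls in zip(tokens, labels, classes)
    ]
    chunks = extract_chunks(tokens, cleaned)
    tagged = []
    for chunk in chunks:
        tags = assign_tags(chunk, lexicon)
        tags = post_process(chunk, tags, rules)
        tagged.append(replace(chunk, tags=frozenset(tags)))
    return tagged
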