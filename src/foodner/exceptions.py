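"""Exception hierarchy.

Everything user-facing derives from :class:`FoodnerError` so the CLI can map
validation problems to a single exit code.
"""


class FoodnerError(ValueError):
    """Base class for all validation and format errors raised by foodner."""


class TagParseError(FoodnerError):
    """A semantic-tag string does not follow the CODE[Label] grammar."""


class LexiconError(FoodnerError):
    """A lexicon or rule file could not be parsed."""


class TaggerContractError(FoodnerError):
    """A plugged-in POS tagger violated the one-label-per-token contract."""


class CorpusError(FoodnerError):
    """An annotated corpus violates its structural invariants."""


class CurationError(FoodnerError):
    """A curation edit references a missing recipe/annotation or mismatching text."""


class UndefinedMetricError(FoodnerError):
    """Precision or recall has a zero denominator."""


class FixtureError(FoodnerError):
    """A fixture specification is infeasible for the available vocabulary."""
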