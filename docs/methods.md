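# Methods

## Problem and model

`foodner` extracts food entities from free-text recipe instructions with a
deterministic rule pipeline and annotates them with hierarchical semantic
tags. The unit of annotation is the *food chunk*: a contiguous token span
naming a single food concept. The tag inventory follows the Hansard/USAS
convention — dot-separated codes under three top categories, `AG` (Food and
drink, with subtrees such as `AG.01` Food, `AG.02` food production, `AG.03`
hunting), `AE` (Animals) and `AF` (Plants). The toolkit is
lexicon-parameterized: all food knowledge lives in a TSV mapping token lemmas
to tag sets, so the same engine runs against a toy lexicon or a full
semantic-analysis resource.

Assumptions: input is English instruction-style prose; food-hood is decided
by lexicon evidence at the token level plus part-of-speech constraints, not
by context; one recipe is one passage, and all offsets refer to the cleaned
text (ASCII after transliteration, so character and byte offsets coincide).

## Pipeline details and numerical choices

**Pre-processing** normalizes to NFKD, strips non-ASCII marks, replaces any
character outside `[A-Za-z0-9 .,;:()'/-%]` with a space and collapses
whitespace. The operation is idempotent, which makes the cleaned text a safe
fixed point for offsets.

**Tokenization** splits on whitespace and breaks `.,;:()` into separate
tokens; hyphens and apostrophes stay word-internal (`club-soda`, `chef's`).

**POS tagging** uses a coarse 12-label set (NOUN, PROPN, ADJ, VERB,
VERB_PART, ADV, DET, ADP, CCONJ, NUM, PUNCT, OTHER) — the downstream rules
only consume these distinctions. Taggers are a pluggable contract (token
sequence in, equal-length label sequence out); any external tagger can be
adapted via a mapping to the coarse set. The package ships two deterministic
reference taggers so that the two-tagger ensemble architecture is exercised
offline and reproducibly:

- `LexiconRuleTagger` — closed-class word lists, a small adjective list,
  `-ed` participles, and lexicon-known tokens as nouns;
- `SuffixRuleTagger` — no lexicon access; additionally treats `-ing` forms
  as participles and a few stative verbs (`empty`, `top`, `set`) as verbs.

Their deliberate differences give the ensemble genuine disagreements.
Verb/noun homographs common in recipes (`mix`, `grill`, `blend`, `toast`, …)
are tagged VERB sentence-initially (imperatives) and NOUN elsewhere; this
one-line context rule is what lets `dry ranch salad dressing mix` survive as
a five-token chunk while `Mix flour and sugar.` starts with a verb.

**Ensemble rule**: agreement wins; on disagreement, a token with lexicon food
evidence takes the noun/adjectival reading with priority NOUN > ADJ >
VERB_PART; otherwise tagger A's label is kept. Keeping A's label on
no-evidence disagreement intentionally preserves the known failure mode where
a contextual verb (`empty` in "empty passion fruit juice") survives as an
adjective — the source of *Partial* matches in evaluation.

**Classification** marks nouns/proper nouns with food evidence as
`FOOD_HEAD`, adjectives/participles with food evidence as `FOOD_MOD`, and —
after head/mod assignment — connector words (default set `of`, `and`, `-`,
`&`, configurable) whose nearest non-connector neighbours on both sides are
food tokens as `CONNECTOR`. Evidence is *strong* for AG tags and *weak* for
AE/AF; both suffice for food-hood, so animal/plant-only tokens (e.g.
`venison`) are still extracted.

**Chunking** takes maximal runs of food tokens, requires at least one head,
and trims boundary connectors. A consequence of the connector rule is that
coordinated ingredients (`milk and flour`) merge into one chunk; the
synthetic generator records gold spans accordingly.

**Tag assignment** unions the lexicon tags of all chunk tokens and applies
the fallback ladder at chunk level: if any AG tag is present, only the AG
subset is kept (so `grilled chicken` keeps both the cooking-process and the
fowl tag while an incidental animal tag would be dropped); otherwise all
AE/AF tags are kept (no preference between them — both categories are
retained when AG is absent); otherwise the chunk falls back to `AG.01[Food]`.
Every chunk therefore carries ≥ 1 tag. **Correction rules** then fix
systematic tagger artefacts; the bundled table holds the three documented
fixes (remove `AG.01.af[Tea manufacture]` on `mixture`, remove
`AG.01.ae.03[Brewing]` on `mashed`, replace a bare `AG.01[Food]` with
`AG.01.z[Water]` on `water`) and is a TSV users can extend. Rules that empty
a tag set restore the fallback tag, keeping post-processing idempotent.

## Corpus format

BioC XML, one document per recipe with a `category` infon, one passage at
offset 0 holding the cleaned text, and per annotation a `semantic_tags` infon
(semicolon-joined bracket notation, sorted by code), a `location`
(offset + length) and the text. Sorting the tag join and fixing element order
makes serialization byte-stable, which the tests rely on
(`write(read(write(c))) == write(c)`). The space-before-bracket tag dialect
and colon-separated codes are accepted on read and normalized on write.
Curation edits (exclude a false positive, include a missed entity, add/remove
tags) are an explicit replayable list rather than in-place mutation, so the
curated/un-curated distinction stays reproducible.

## Evaluation protocol

Per recipe, exact span matches pair off as TP first; remaining predictions
that overlap a remaining gold span by ≥ 1 character pair off greedily
left-to-right as Partial (each span consumed once); leftovers are FP/FN.
For two families of internally non-overlapping intervals, this greedy pairing
attains the maximum number of partial pairs; the test suite checks it against
an exhaustive enumeration oracle on all instances with ≤ 8 spans per side.
Precision/recall/F1 ignore partials, are computed at full precision and
rounded half-up to 4 decimals only for reporting (`decimal`-based, so
0.97798… prints as 0.9780). Zero denominators raise rather than silently
reporting 0. True negatives are undefined for span extraction and not
modelled.

## Synthetic data

`fixtures.generate` assembles recipes from eight instruction templates and a
26-item ingredient vocabulary (single- and multi-word, including the
connector phrase `cream of tartar` and the correction-rule triggers `water`
and `mashed potato`), 3–6 sentences per recipe, categories apportioned over
the five dish groups by largest remainder (equal fifths by default). Gold
offsets are recorded at assembly time, never recovered by string search, and
gold tags are computed with the same assignment/post-processing functions the
pipeline uses. Because every ingredient is lexicon-covered and no template
word is, the pipeline recovers the gold corpus exactly — which is the point:
the generator is a ground-truth harness for the pipeline composition, the
evaluation bookkeeping and curation replay, not a model of culinary language.
Passing these tests shows the machinery is self-consistent; it does *not*
show field performance on real recipes, which contain quantities, brand
names, anaphora and vocabulary far beyond the fixture lexicon.

`fixtures.perturb` injects an exact number of false positives (spurious
single-token spans overlapping no gold span), false negatives (deletions) and
partials (expanding a gold span one word to the left, mimicking the
"empty passion fruit juice" tagger failure), and returns both the expected
confusion counts and the curation edit list that restores gold. All
randomness is `random.Random(seed)`; the same seed gives the same corpus on
any platform.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| connector set | `of, and, -, &` | config-exposed; widening it merges more coordinated chunks |
| ensemble priority | NOUN > ADJ > VERB_PART | applied only with food evidence |
| plural stripping | `-s`, then `-es` | deterministic lookup normalization; no full lemmatizer at the lexicon layer |
| metric rounding | 4 decimals, half-up | reporting only |
| stats conventions | sample (n−1) SD; mode ties → smallest; 2-decimal reporting | affect reporting, not the distributions |
| generator | seed 7, 6 recipes, equal category mix | acceptance-scale default; 50 recipes in the acceptance script |

## Design choices and limitations

- Concept alignment is an exact join on normalized names (lowercase,
  single-spaced); fuzzy or semantic matching would be unverifiable here.
  Artificial IDs are `RESOURCE:000001…` in first-appearance order.
- The full Hansard/USAS tag inventory is not bundled; the code→label registry
  is built from the lexicon file and hierarchy parents outside it get empty
  labels.
- Corpus-scale figures (hundreds of thousands of annotations, ontology
  alignment counts) depend on external recipe collections and ontology
  services and are out of scope; the structural property suites stand in for
  them.
- The rule taggers are intentionally small; on real prose their coarse labels
  will be wrong more often than a trained tagger's, and the pluggable
  contract is the intended path to better POS input.
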