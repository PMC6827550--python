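# foodner

Rule-based **food named-entity recognition** for recipe text, with
hierarchical semantic tagging, BioC corpus I/O, NER evaluation and
cross-resource concept alignment.

Recipes carry rich information about food, but unlike genes, drugs or
diseases, food entities have few annotated corpora or extraction tools.
`foodner` is a toolkit for building and evaluating such corpora: it extracts
*food chunks* — contiguous token spans that each name a single food concept,
such as `grilled chicken` — from free-text recipe instructions, and annotates
every chunk with hierarchical semantic tags (codes like `AG.01.h.02.d`
"Cabbage/kale" under the top categories **AG** Food and drink, **AE** Animals,
**AF** Plants). It is aimed at text-mining researchers and dietitians who
need weakly annotated food corpora, gold-standard curation tooling, or a
deterministic rule baseline to compare learned NER models against.

## The method

1. **Pre-processing** — transliterate to ASCII, drop non-standard characters,
   collapse whitespace. The cleaned text is the single authoritative string
   all character offsets refer to.
2. **POS ensemble** — two pluggable taggers label every token with a coarse
   part of speech; disagreements on tokens with lexicon food evidence resolve
   toward the noun/adjectival reading (NOUN > ADJ > participle), otherwise
   tagger A wins.
3. **Token classification** — each token becomes `FOOD_HEAD` (noun with food
   evidence), `FOOD_MOD` (adjective/participle with food evidence),
   `CONNECTOR` (`of`, `and`, … between food tokens) or `NON_FOOD`.
4. **Chunking** — maximal runs of food tokens become chunks; runs without a
   head are dropped and boundary connectors trimmed.
5. **Tag assignment** — a chunk receives the union of its tokens' lexicon
   tags, filtered by the fallback ladder *AG tags → else AE/AF tags → else*
   `AG.01[Food]`, followed by token-triggered correction rules (e.g. the
   spurious `AG.01.af[Tea manufacture]` is removed whenever `mixture` occurs).

Evaluation cross-references predicted and gold spans: exact matches are true
positives, overlapping-but-unequal spans are *Partial (inconclusive)*, the
rest are false positives / false negatives. True negatives are not modelled.
With partials omitted,

```
P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R)
```

rounded half-up to four decimals for reporting.

## Worked example

```python
>>> import foodner as f
>>> lex = f.default_lexicon()
>>> recipe = f.Recipe(id="r1", category="Dinner",
...                   text="Grill the chicken. Serve with tortilla chips.")
>>> for chunk in f.annotate_recipe(recipe, lex):
...     print(chunk.surface, sorted(str(t) for t in chunk.tags))
chicken ['AG.01.d.06[Fowls]']
tortilla chips ['AG.01.n.11[Bread]', 'AG.01.n.12[Pancake/tortilla/oatcake]']
```

`chicken` is a food head with the Fowls tag; `tortilla chips` is one
two-token chunk whose tag set unions both tokens' tags. Scoring a counts
table reproduces published-style metrics:

```python
>>> f.metrics(f.ConfusionCounts(tp=11461, fp=258, fn=684, partial=359)).rounded()
Metrics(precision=0.978, recall=0.9437, f1=0.9605)
```

The same is available from the shell:

```sh
foodner make-fixtures --seed 7 --n 6 --out fx/          # synthetic recipes + gold BioC
foodner annotate --input fx/recipes.jsonl --output pred.bioc.xml
foodner evaluate --gold fx/gold.bioc.xml --pred pred.bioc.xml --report metrics.json
foodner stats --input fx/gold.bioc.xml --report stats.json
```

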