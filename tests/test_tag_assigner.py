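"""Tag assignment fallback ladder, correction rules and curation edits."""

import pytest

from foodner import (
    CorrectionRule,
    CurationEdit,
    EditKind,
    FALLBACK_TAG,
    FoodChunk,
    RuleAction,
    apply_curation,
    assign_tags,
    default_rules,
    parse_tag,
    post_process,
)
from foodner.exceptions import CurationError


def make_chunk(*token_surfaces):
    surface = " ".join(token_surfaces)
    return FoodChunk(
        start=0,
        end=len(surface),
        surface=surface,
        token_indices=tuple(range(len(token_surfaces))),
        token_surfaces=tuple(token_surfaces),
    )


@pytest.mark.parametrize(
    "tokens, expected_codes",
    [
        (("grilled", "chicken"), {"AG.01.t.07", "AG.01.d.06"}),
        (("tortilla", "chips"), {"AG.01.n.11", "AG.01.n.12"}),
        (
            ("dry", "ranch", "salad", "dressing", "mix"),
            {"AG.01.h.02", "AG.01.m", "AG.01.n.09"},
        ),
        (("cauliflower",), {"AG.01.h.02.d"}),
        (("snickers",), {"AG.01"}),  # unknown food: top-level fallback
        (("venison",), {"AE.07"}),  # no AG tags: animal/plant tags kept
    ],
)
def test_assign_tags_ladder(lexicon, tokens, expected_codes):
    tags = assign_tags(make_chunk(*tokens), lexicon)
    assert {t.code for t in tags} == expected_codes
    assert tags  # never empty


def test_ag_tags_exclude_ae_af(lexicon):
    # 'venison' contributes an AE tag, 'milk' an AG tag: AG filtering wins
    tags = assign_tags(make_chunk("venison", "milk"), lexicon)
    assert {t.category for t in tags} == {"AG"}


def test_post_process_mixture_rule():
    chunk = make_chunk("cheese", "mixture")
    tags = {parse_tag("AG.01.af[Tea manufacture]"), parse_tag("AG.01.e[Dairy products]")}
    result = post_process(chunk, tags, default_rules())
    assert {t.code for t in result} == {"AG.01.e"}


def test_post_process_mashed_rule():
    chunk = make_chunk("mashed", "potato")
    tags = {parse_tag("AG.01.ae.03[Brewing]"), parse_tag("AG.01.h.02[Vegetables]")}
    result = post_process(chunk, tags, default_rules())
    assert {t.code for t in result} == {"AG.01.h.02"}


def test_post_process_water_replacement():
    chunk = make_chunk("water")
    result = post_process(chunk, {parse_tag("AG.01[Food]")}, default_rules())
    assert {str(t) for t in result} == {"AG.01.z[Water]"}


def test_post_process_restores_fallback_when_emptied():
    rule = CorrectionRule(
        trigger="mixture",
        action=RuleAction.REMOVE_TAG,
        tag=parse_tag("AG.01.af[Tea manufacture]"),
    )
    result = post_process(make_chunk("mixture"), {rule.tag}, [rule])
    assert result == frozenset({FALLBACK_TAG})


def test_post_process_idempotent(lexicon):
    rules = default_rules()
    chunk = make_chunk("mashed", "potato", "water", "mixture")
    tags = assign_tags(chunk, lexicon)
    once = post_process(chunk, tags, rules)
    assert post_process(chunk, once, rules) == once


def test_load_rules_round_trip(tmp_path):
    from foodner import load_rules

    path = tmp_path / "rules.tsv"
    path.write_text(
        "mixture\tREMOVE_TAG\tAG.01.af[Tea manufacture]\n"
        "water\tREPLACE_TAG\tAG.01[Food]\tAG.01.z[Water]\n",
        encoding="utf-8",
    )
    rules = load_rules(path)
    assert rules[0].action is RuleAction.REMOVE_TAG
    assert rules[1].replacement == parse_tag("AG.01.z[Water]")


# --- curation -------------------------------------------------------------------


def test_apply_curation_empty_edit_list_is_identity(gold_corpus):
    assert apply_curation(gold_corpus, []) == gold_corpus


def test_exclude_fp_removes_annotation(gold_corpus):
    doc = gold_corpus.documents[0]
    ann = doc.passages[0].annotations[0]
    before = len(doc.passages[0].annotations)
    edited = apply_curation(
        gold_corpus,
        [CurationEdit(kind=EditKind.EXCLUDE_FP, recipe_id=doc.id,
                      start=ann.offset, end=ann.end, text=ann.text)],
    )
    assert len(edited.documents[0].passages[0].annotations) == before - 1


def test_include_fn_inserts_annotation_and_round_trips(gold_corpus):
    from foodner import reads_bioc, writes_bioc

    doc = gold_corpus.documents[0]
    text = doc.passages[0].text
    # annotate the first word of the passage as a missed entity ('kefir'-style)
    end = text.index(" ")
    edit = CurationEdit(
        kind=EditKind.INCLUDE_FN,
        recipe_id=doc.id,
        start=0,
        end=end,
        text=text[:end],
        tags=frozenset({parse_tag("AG.01.e[Dairy products]")}),
    )
    edited = apply_curation(gold_corpus, [edit])
    new = edited.documents[0].passages[0].annotations[0]
    assert (new.offset, new.end, new.text) == (0, end, text[:end])
    assert reads_bioc(writes_bioc(edited)) == edited


def test_include_fn_text_mismatch_is_error(gold_corpus):
    doc = gold_corpus.documents[0]
    edit = CurationEdit(
        kind=EditKind.INCLUDE_FN, recipe_id=doc.id, start=0, end=5,
        text="WRONG", tags=frozenset({FALLBACK_TAG}),
    )
    with pytest.raises(CurationError):
        apply_curation(gold_corpus, [edit])


def test_edit_on_unknown_recipe_is_error(gold_corpus):
    edit = CurationEdit(
        kind=EditKind.EXCLUDE_FP, recipe_id="nope", start=0, end=1, text="x"
    )
    with pytest.raises(CurationError, match="nope"):
        apply_curation(gold_corpus, [edit])


def test_remove_tag_never_leaves_annotation_untagged(gold_corpus):
    doc = gold_corpus.documents[0]
    ann = doc.passages[0].annotations[0]
    edit = CurationEdit(
        kind=EditKind.REMOVE_TAG, recipe_id=doc.id,
        start=ann.offset, end=ann.end, text=ann.text, tags=ann.tags,
    )
    edited = apply_curation(gold_corpus, [edit])
    assert edited.documents[0].passages[0].annotations[0].tags == frozenset({FALLBACK_TAG})
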