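"""Filter semantics and ledger conservation."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reviewfactors import (
    DataError,
    GeneratorConfig,
    apply_bot_filter,
    consistency_filter,
    deduplicate,
    generate_corpus,
    inject_contamination,
    preprocess,
    tokenize_and_clean,
)
from reviewfactors.preprocessing import (
    LexiconSentiment,
    load_stopwords,
    load_synonym_map,
)


def make_table(rows):
    base = {
        "review_id": None, "app_id": "a1", "country": "US",
        "rating": 5, "text": "fine app", "sentiment": "positive",
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec.update(row)
        rec["review_id"] = rec["review_id"] or f"r{i}"
        recs.append(rec)
    return pd.DataFrame(recs)


# --- deduplicate -----------------------------------------------------------


def test_deduplicate_identity_without_duplicates():
    t = make_table([{"text": "good"}, {"text": "bad", "rating": 1,
                                       "sentiment": "negative"}])
    out, removed = deduplicate(t)
    assert removed == 0 and len(out) == 2


def test_deduplicate_collapses_rows_differing_only_in_id():
    t = make_table([{"text": "Nice  app"}, {"text": "nice app"}])
    out, removed = deduplicate(t)
    assert removed == 1
    assert out["review_id"].tolist() == ["r0"]  # first occurrence survives


def test_deduplicate_removes_exactly_the_injected_duplicates():
    table, _ = generate_corpus(GeneratorConfig(n_apps=10, reviews_per_app=100,
                                               seed=21))
    out = inject_contamination(table, {"duplicate": 0.1}, seed=5)
    _, removed = deduplicate(out)
    assert removed == 100


# --- consistency filter ----------------------------------------------------

CONSISTENT = {(1, "negative"), (2, "negative"), (3, "neutral"),
              (4, "positive"), (5, "positive")}


@pytest.mark.parametrize("rating", [1, 2, 3, 4, 5])
@pytest.mark.parametrize("sentiment", ["negative", "neutral", "positive"])
def test_consistency_matrix_cells(rating, sentiment):
    t = make_table([{"rating": rating, "sentiment": sentiment}])
    out, removed = consistency_filter(t)
    if (rating, sentiment) in CONSISTENT:
        assert removed == 0 and len(out) == 1
    else:
        assert removed == 1 and len(out) == 0


def test_consistency_filter_is_idempotent():
    table, _ = generate_corpus(GeneratorConfig(n_apps=6, reviews_per_app=50,
                                               seed=22))
    table = inject_contamination(table, {"contradiction": 0.1}, seed=6)
    once, r1 = consistency_filter(table)
    twice, r2 = consistency_filter(once)
    assert r2 == 0
    pd.testing.assert_frame_equal(once, twice)


def test_consistency_filter_requires_sentiment():
    t = make_table([{}]).drop(columns=["sentiment"])
    with pytest.raises(DataError):
        consistency_filter(t)


# --- tokenization ----------------------------------------------------------


def test_stopword_only_text_is_dropped_and_counted():
    t = make_table([{"text": "the of and"}, {"text": "great tracker"}])
    out, dropped = tokenize_and_clean(t, stopwords={"the", "of", "and"})
    assert dropped == 1
    assert out["tokens"].tolist() == [["great", "tracker"]]


def test_synonym_map_applied_tokenwise():
    t = make_table([{"text": "bp log"}])
    out, _ = tokenize_and_clean(t, synonym_map={"bp": "blood_pressure"})
    assert out["tokens"].iloc[0] == ["blood_pressure", "log"]


def test_numeric_and_punctuation_tokens_removed():
    t = make_table([{"text": "Great 123 !!! app-2 ..."}])
    out, _ = tokenize_and_clean(t)
    assert out["tokens"].iloc[0] == ["great", "app-2"]


def test_injected_empty_texts_are_dropped_by_no_text_step():
    table, _ = generate_corpus(GeneratorConfig(n_apps=10, reviews_per_app=100,
                                               seed=23))
    table = inject_contamination(table, {"empty": 0.05}, seed=7)
    clean, ledger = preprocess(table)
    assert ledger.removed["no_text"] == 50
    assert (clean["provenance"] == "clean").all()


# --- bot filter ------------------------------------------------------------


def test_default_bot_predicate_without_flag_column_keeps_all():
    t = make_table([{}, {}]).drop(columns=["country"])
    t2 = t.drop(columns=[c for c in ["bot_flag"] if c in t.columns])
    out, removed = apply_bot_filter(t2)
    assert removed == 0 and len(out) == 2


def test_flagged_bots_are_removed():
    table, _ = generate_corpus(GeneratorConfig(n_apps=6, reviews_per_app=100,
                                               seed=24))
    table = inject_contamination(table, {"bot": 0.05}, seed=8)
    out, removed = apply_bot_filter(table)
    assert removed == 30
    assert not out["bot_flag"].any()


def test_false_predicate_is_identity():
    t = make_table([{}, {}])
    out, removed = apply_bot_filter(t, predicate=lambda row: False)
    assert removed == 0 and len(out) == 2


# --- ledger ----------------------------------------------------------------


def test_ledger_conservation_on_contaminated_corpus():
    cfg = GeneratorConfig(
        n_apps=10, reviews_per_app=80, seed=25,
        contamination_rates={"duplicate": 0.05, "bot": 0.05,
                             "contradiction": 0.05, "empty": 0.05},
    )
    table, _ = generate_corpus(cfg)
    clean, ledger = preprocess(table)
    ledger.check()
    assert ledger.n_in == len(table)
    assert ledger.n_out == len(clean)
    assert ledger.n_out == ledger.n_in - sum(ledger.removed.values())


def test_filter_order_is_stable():
    cfg = GeneratorConfig(
        n_apps=8, reviews_per_app=60, seed=26,
        contamination_rates={"duplicate": 0.1, "contradiction": 0.05},
    )
    table, _ = generate_corpus(cfg)
    _, l1 = preprocess(table)
    _, l2 = preprocess(table.copy())
    assert l1.removed == l2.removed and l1.n_out == l2.n_out


@given(
    ratings=st.lists(st.integers(min_value=1, max_value=5), min_size=1,
                     max_size=40),
    flips=st.lists(st.booleans(), min_size=1, max_size=40),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_ledger_conservation_property(ratings, flips):
    """n_in = n_out + sum(removals) for arbitrary small tables."""
    from reviewfactors.synthetic import sentiment_from_rating

    rows = []
    for i, r in enumerate(ratings):
        flip = flips[i % len(flips)]
        sent = sentiment_from_rating(r)
        if flip:
            sent = "positive" if sent == "negative" else "negative"
        rows.append({"rating": r, "sentiment": sent, "text": f"tok{i % 7}"})
    table = make_table(rows)
    _, ledger = preprocess(table)
    ledger.check()


# --- sentiment & file loaders ---------------------------------------------


def test_lexicon_sentiment_polarity():
    score = LexiconSentiment()
    assert score("really easy and useful") == "positive"
    assert score("it crashes terrible") == "negative"
    assert score("opens a window") == "neutral"


def test_stopword_and_synonym_loaders(tmp_path):
    sw = tmp_path / "stop.txt"
    sw.write_text("the\nand\n\n", encoding="utf-8")
    assert load_stopwords(sw) == {"the", "and"}
    syn = tmp_path / "syn.tsv"
    syn.write_text("bp\tblood_pressure\n", encoding="utf-8")
    assert load_synonym_map(syn) == {"bp": "blood_pressure"}
    with pytest.raises(DataError):
        load_stopwords(tmp_path / "missing.txt")
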