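"""Corpus funnel: JSONL round trip, inclusion filter, dedup, deidentify, DTM."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from hrqolsm.corpus import (
    KeywordLexicon,
    Post,
    build_dtm,
    deduplicate,
    deidentify,
    filter_posts,
    read_corpus,
    tokenize_posts,
    write_corpus,
)
from hrqolsm.errors import CorpusError, LexiconError


def make_post(post_id, text, alias="alice", date=dt.date(2015, 6, 1), source="forum"):
    return Post(post_id, source, f"https://{source}.example/{post_id}", date, alias, text)


# ---------------------------------------------------------------------------
# JSON Lines round trip
# ---------------------------------------------------------------------------


def test_corpus_round_trip_is_lossless(tmp_path):
    posts = [make_post("p1", "première ligne — avec accents"), make_post("p2", "deuxième")]
    path = tmp_path / "corpus.jsonl"
    write_corpus(posts, path)
    assert read_corpus(path) == posts


def test_empty_corpus_round_trips_to_an_empty_list(tmp_path):
    path = tmp_path / "empty.jsonl"
    write_corpus([], path)
    assert path.read_text() == ""
    assert read_corpus(path) == []


def test_truncated_record_errors_with_its_line_number(tmp_path):
    path = tmp_path / "bad.jsonl"
    path.write_text(make_post("p1", "ok").to_json() + "\n" + '{"post_id": "p2", "trunc\n')
    with pytest.raises(CorpusError, match=r"bad\.jsonl:2"):
        read_corpus(path)


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------


def test_keyword_hit_is_retained_with_its_matching_keyword():
    posts = [make_post("p1", "sous nivolumab depuis 3 mois")]
    kept, matched = filter_posts(posts)
    assert [p.post_id for p in kept] == ["p1"]
    assert matched == {"p1": "nivolumab"}


def test_post_without_any_ici_keyword_is_excluded():
    kept, matched = filter_posts([make_post("p1", "une chimiothérapie classique")])
    assert kept == [] and matched == {}


def test_keyword_matching_is_accent_and_case_insensitive_with_word_boundaries():
    kept, matched = filter_posts([make_post("p1", "début d'IMMUNOTHÉRAPIE lundi")])
    assert matched["p1"].lower().startswith("immunoth")
    # substring inside a longer word does not count
    kept, _ = filter_posts([make_post("p2", "le nivolumabesque n'existe pas")])
    assert kept == []


def test_study_window_is_half_open():
    inside = make_post("in", "nivolumab", date=dt.date(2018, 8, 31))
    outside = make_post("out", "nivolumab", date=dt.date(2018, 9, 1))
    before = make_post("before", "nivolumab", date=dt.date(2010, 12, 31))
    kept, _ = filter_posts([inside, outside, before])
    assert [p.post_id for p in kept] == ["in"]


def test_empty_synonym_entry_is_rejected():
    with pytest.raises(LexiconError):
        KeywordLexicon({"nivolumab": ["nivolumab", "  "]})


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def test_identical_text_same_alias_keeps_only_the_earliest():
    a = make_post("p1", "même texte, nivolumab", date=dt.date(2015, 1, 1), source="forum-a")
    b = make_post("p2", "même texte, nivolumab", date=dt.date(2015, 2, 1), source="forum-b")
    kept, log = deduplicate([b, a])
    assert [p.post_id for p in kept] == ["p1"]
    assert log[0].removed_id == "p2" and log[0].kept_id == "p1" and log[0].similarity == 1.0


def test_identical_text_different_aliases_are_both_kept():
    a = make_post("p1", "même texte", alias="alice")
    b = make_post("p2", "même texte", alias="bob")
    kept, log = deduplicate([a, b])
    assert len(kept) == 2 and log == []


def test_near_duplicates_above_the_jaccard_threshold_are_merged():
    base = "fatigue douleur fievre toux migraine thyroide cheveux espoir detresse peur"
    near = base + " diarrhee"  # 10/11 overlap > 0.9
    far = "un texte totalement different qui parle d autre chose entierement"
    kept, log = deduplicate(
        [make_post("p1", base), make_post("p2", near), make_post("p3", far)]
    )
    assert [p.post_id for p in kept] == ["p1", "p3"]
    assert log[0].removed_id == "p2" and log[0].similarity >= 0.9


def test_deduplicate_is_idempotent():
    posts = [
        make_post("p1", "texte un nivolumab"),
        make_post("p2", "texte un nivolumab", date=dt.date(2016, 1, 1)),
        make_post("p3", "texte deux", alias="bob"),
    ]
    once, _ = deduplicate(posts)
    twice, log = deduplicate(once)
    assert twice == once and log == []


# ---------------------------------------------------------------------------
# Deidentification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,cls,fragment",
    [
        ("joignez-moi au 06 12 34 56 78 svp", "phone", "06 12 34 56 78"),
        ("appel au +33 6 12 34 56 78 possible", "phone", "+33 6 12 34 56 78"),
        ("tel: 0612345678.", "phone", "0612345678"),
        ("j'habite a lyon 69005 depuis peu", "postal", "69005"),
        ("ecrivez a jean.dupont@exemple.fr merci", "email", "jean.dupont@exemple.fr"),
        ("mon oncologue le Dr Rousseau est top", "name", "Rousseau"),
        ("merci a Madame Verte pour tout", "name", "Verte"),
    ],
)
def test_each_pii_class_is_redacted(text, cls, fragment):
    redacted, spans = deidentify(text)
    assert [s.cls for s in spans] == [cls]
    assert spans[0].text == fragment
    assert fragment not in redacted
    assert f"<{cls.upper()}>" in redacted


def test_empty_text_has_no_spans():
    assert deidentify("") == ("", [])


def test_postal_code_is_not_extracted_from_inside_a_phone_number():
    redacted, spans = deidentify("rappelez le 0612345678 ou code 75013")
    assert sorted(s.cls for s in spans) == ["phone", "postal"]
    assert {s.text for s in spans} == {"0612345678", "75013"}


@settings(max_examples=60, derandomize=True)
@given(
    st.text(
        alphabet="abcDEF 0123456789@.+-éà\n",
        max_size=60,
    )
)
def test_deidentify_is_idempotent(text):
    once, _ = deidentify(text)
    twice, spans = deidentify(once)
    assert twice == once and spans == []


def test_redaction_does_not_touch_trigger_phrases():
    text = "depuis peu je remarque fatigue. joignez moi au 06 12 34 56 78"
    redacted, _ = deidentify(text)
    assert "fatigue" in redacted


# ---------------------------------------------------------------------------
# Document-term matrix
# ---------------------------------------------------------------------------


def _tokenized(texts):
    posts = [make_post(f"p{i}", t) for i, t in enumerate(texts)]
    return tokenize_posts(posts, stopwords=frozenset(), stemmer=lambda t: t)


def test_raw_count_matrix_equals_a_hand_count():
    tps = _tokenized(["alpha beta alpha", "beta gamma"])
    dtm = build_dtm(tps, min_token_freq=1, weighting="count")
    assert dtm.vocabulary == ("alpha", "beta", "gamma")
    assert dtm.matrix.toarray().tolist() == [[2.0, 1.0, 0.0], [0.0, 1.0, 1.0]]


def test_rare_tokens_fall_below_the_frequency_threshold():
    tps = _tokenized(["alpha beta", "alpha gamma"])
    dtm = build_dtm(tps, min_token_freq=2, weighting="count")
    assert dtm.vocabulary == ("alpha",)


def test_exclusion_list_removes_ambiguous_tokens():
    tps = _tokenized(["alpha beta alpha beta"])
    dtm = build_dtm(tps, min_token_freq=1, weighting="count", exclude={"beta"})
    assert dtm.vocabulary == ("alpha",)


def test_count_row_sums_conserve_post_token_counts_after_rarity_filtering():
    tps = _tokenized(["alpha beta alpha", "beta gamma beta", "gamma alpha"])
    dtm = build_dtm(tps, min_token_freq=2, weighting="count")
    rows = dtm.matrix.sum(axis=1).A1.tolist()
    expected = [
        sum(1 for tok in tp.tokens if tok in set(dtm.vocabulary)) for tp in tps
    ]
    assert rows == expected


def test_tfidf_weighting_produces_unit_rows_and_no_zero_columns():
    tps = _tokenized(["alpha beta alpha", "beta gamma beta", "gamma alpha"])
    dtm = build_dtm(tps, min_token_freq=2, weighting="tfidf")
    col_sums = dtm.matrix.power(2).sum(axis=0).A1
    assert (col_sums > 0).all()
    row_norms = dtm.matrix.power(2).sum(axis=1).A1
    assert row_norms == pytest.approx([1.0, 1.0, 1.0])


def test_empty_corpus_cannot_be_matrixified(tmp_path):
    with pytest.raises(CorpusError):
        build_dtm([], weighting="count")


def test_dtm_export_round_trips_through_matrix_market(tmp_path):
    import scipy.io

    tps = _tokenized(["alpha beta alpha", "beta gamma"])
    dtm = build_dtm(tps, min_token_freq=1, weighting="count")
    dtm.save(tmp_path)
    loaded = scipy.io.mmread(tmp_path / "dtm.mtx")
    assert (loaded.toarray() == dtm.matrix.toarray()).all()
    assert (tmp_path / "vocabulary.csv").read_text().splitlines()[1:] == list(dtm.vocabulary)


# ---------------------------------------------------------------------------
# Stage-order property
# ---------------------------------------------------------------------------


def test_filter_then_dedup_equals_dedup_then_filter_on_generator_corpora(planted_corpus):
    posts, _truth = planted_corpus
    filtered_first, _ = deduplicate(filter_posts(posts)[0])
    deduped_first, _ = filter_posts(deduplicate(posts)[0])
    assert {p.post_id for p in filtered_first} == {p.post_id for p in deduped_first}
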