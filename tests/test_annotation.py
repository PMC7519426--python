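"""Lexicon annotation: detection, patient aggregation, global-health polarity."""

import datetime as dt

import pytest

from hrqolsm.annotate import (
    PatientRecord,
    PolarityLexicon,
    SubdomainLexicon,
    aggregate_patients,
    classify_global_health,
    detect_mentions,
    occurrence_table,
)
from hrqolsm.corpus import Post
from hrqolsm.errors import AnnotationError, LexiconError
from hrqolsm.pipeline import annotate_posts
from hrqolsm.textprep import preprocess


def make_post(post_id, text, alias="alice"):
    return Post(post_id, "forum", "https://x/p", dt.date(2015, 1, 1), alias, text)


@pytest.fixture(scope="module")
def processed_lexicon():
    return SubdomainLexicon.default().processed()


def test_direct_trigger_hit_yields_one_detection(processed_lexicon):
    tokens = preprocess("je ressens une grande fatigue ce soir")
    assert detect_mentions(tokens, processed_lexicon) == [
        ("fatigue-tiredness", "fatigu")
    ]


def test_text_without_triggers_yields_nothing(processed_lexicon):
    assert detect_mentions(preprocess("le protocole continue sans rien"), processed_lexicon) == []


def test_multiword_triggers_must_be_contiguous(processed_lexicon):
    hit = preprocess("mon etat general se maintient")
    miss = preprocess("mon etat de forme general se maintient")
    assert [s for s, _ in detect_mentions(hit, processed_lexicon)] == ["global-health-state"]
    assert detect_mentions(miss, processed_lexicon) == []


def test_repeats_within_one_post_collapse_to_one_detection(processed_lexicon):
    tokens = preprocess("fatigue le matin fatigue le soir")
    assert len(detect_mentions(tokens, processed_lexicon)) == 1


def test_closed_world_posts_yield_exactly_their_planted_subdomains(
    planted_corpus, planted_result
):
    posts, truth = planted_corpus
    processed = SubdomainLexicon.default().processed()
    surviving = {tp.post_id: tp for tp in planted_result.tokenized}
    for post_id, tp in surviving.items():
        detected = {s for s, _ in detect_mentions(tp.tokens, processed)}
        assert detected == set(truth.post_mentions[post_id])


def test_within_patient_repeats_collapse_to_one_mention_with_all_evidence():
    lexicon = SubdomainLexicon({"fatigue-tiredness": ["fatigue"]}).processed()
    posts = [make_post(f"p{i}", "encore cette fatigue") for i in range(3)]
    detections = [detect_mentions(preprocess(p.text), lexicon) for p in posts]
    alias_map = {"alice": PatientRecord("pt1", "alice")}
    sub_index = {
        "fatigue-tiredness": __import__("hrqolsm.taxonomy", fromlist=["Subdomain"]).Subdomain(
            "fatigue-tiredness", "Fatigue/Tiredness", "Symptoms", 34
        )
    }
    patients, mentions = aggregate_patients(zip(posts, detections), alias_map, sub_index)
    assert len(patients) == 1 and len(mentions) == 1
    assert len(mentions[0].evidence) == 3
    assert occurrence_table(mentions) == {"fatigue-tiredness": 1}


def test_two_patients_with_the_same_subdomain_count_twice(subdomains):
    lexicon = SubdomainLexicon.default().processed()
    posts = [make_post("p1", "fatigue", "alice"), make_post("p2", "fatigue", "bob")]
    detections = [detect_mentions(preprocess(p.text), lexicon) for p in posts]
    alias_map = {
        "alice": PatientRecord("pt1", "alice"),
        "bob": PatientRecord("pt2", "bob"),
    }
    _patients, mentions = aggregate_patients(
        zip(posts, detections), alias_map, {s.id: s for s in subdomains}
    )
    assert occurrence_table(mentions) == {"fatigue-tiredness": 2}


def test_unmapped_alias_fails_hard(subdomains):
    posts = [make_post("p1", "fatigue", "ghost")]
    with pytest.raises(AnnotationError, match="ghost"):
        aggregate_patients(
            zip(posts, [[("fatigue-tiredness", "fatigu")]]),
            {},
            {s.id: s for s in subdomains},
        )


def test_annotation_is_invariant_under_post_order(planted_corpus, subdomains):
    posts, truth = planted_corpus
    subset = posts[:80]
    lexicon = SubdomainLexicon.default()
    forward = annotate_posts(subset, lexicon, truth.alias_map, subdomains)
    backward = annotate_posts(list(reversed(subset)), lexicon, truth.alias_map, subdomains)
    assert forward[0] == backward[0]
    assert forward[1] == backward[1]


def test_full_closed_world_recovery_is_exact(planted_result, planted_corpus):
    """Precision = recall = 1.0 at the (patient, subdomain) level."""
    _posts, truth = planted_corpus
    detected = {
        (m.patient_id, m.subdomain_id) for m in planted_result.mentions
    }
    planted = {
        (pid, sub) for pid, pairs in truth.mentions.items() for _dom, sub in pairs
    }
    assert detected == planted


def test_count_conservation(planted_result):
    patients_with_domain = {m.patient_id for m in planted_result.mentions}
    assert len(patients_with_domain) <= len(planted_result.patients)
    for domain in {m.domain for m in planted_result.mentions}:
        count = len({m.patient_id for m in planted_result.mentions if m.domain == domain})
        assert count <= len(patients_with_domain)


# ---------------------------------------------------------------------------
# Global-health polarity
# ---------------------------------------------------------------------------


def test_deteriorated_phrase_votes_poor():
    state, confident = classify_global_health(["franchement sa santé se dégrade vite"])
    assert (state, confident) == ("poor", True)


def test_tie_breaks_by_fixed_priority_poor_over_good():
    texts = ["sa sante se degrade", "il va beaucoup mieux"]
    state, confident = classify_global_health(texts)
    assert (state, confident) == ("poor", True)


def test_no_polarity_phrase_defaults_to_stable_with_low_confidence():
    state, confident = classify_global_health(["aucun indice ici"])
    assert (state, confident) == ("stable", False)


def test_global_health_states_partition_the_global_mentioners(planted_result, planted_corpus):
    _posts, truth = planted_corpus
    recovered = {
        p.patient_id: p.global_health_state
        for p in planted_result.patients
        if p.global_health_state
    }
    planted = {
        pid: rec.global_health_state
        for pid, rec in truth.patients.items()
        if rec.global_health_state
    }
    assert recovered == planted
    gh_mentioners = {
        m.patient_id for m in planted_result.mentions if m.domain == "Global health"
    }
    assert set(recovered) == gh_mentioners  # states set iff Global health mentioned


def test_polarity_phrasebook_must_cover_all_three_states():
    with pytest.raises(LexiconError):
        PolarityLexicon({"poor": ["x"], "stable": ["y"]})
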