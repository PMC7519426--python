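"""End-to-end orchestration: raw posts -> coverage report.

Chains the corpus funnel (inclusion filter, dedup, deidentification,
tokenisation), the lexicon annotator and the coverage statistics, logging
one structured record per stage so the corpus-creation funnel is auditable.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .annotate import (
    MentionRecord,
    PatientRecord,
    PolarityLexicon,
    SubdomainLexicon,
    aggregate_patients,
    classify_global_health,
    detect_mentions,
    occurrence_table,
)
from .corpus import (
    STUDY_WINDOW,
    DuplicateRemoval,
    KeywordLexicon,
    Post,
    RedactionSpan,
    TokenizedPost,
    deduplicate,
    deidentify,
    filter_posts,
    tokenize_posts,
)
from .coverage import CoverageReport, coverage_report
from .taxonomy import ConceptMap, Subdomain, load_taxonomy

__all__ = ["PipelineResult", "run_pipeline", "annotate_posts"]

logger = logging.getLogger(__name__)

_GLOBAL_HEALTH_DOMAIN = "Global health"


@dataclass
class PipelineResult:
    posts: list[Post]  # retained, deduplicated, deidentified posts
    matched_keywords: dict[str, str]
    removals: list[DuplicateRemoval]
    redactions: dict[str, list[RedactionSpan]]
    tokenized: list[TokenizedPost]
    patients: list[PatientRecord]
    mentions: list[MentionRecord]
    occurrences: dict[str, int]
    report: CoverageReport


def annotate_posts(
    posts: Sequence[Post],
    lexicon: SubdomainLexicon,
    alias_map: Mapping[str, PatientRecord],
    subdomains: Sequence[Subdomain],
    matched_keywords: Mapping[str, str] | None = None,
    polarity: PolarityLexicon | None = None,
    stopwords=None,
    stemmer=None,
) -> tuple[list[PatientRecord], list[MentionRecord], list[TokenizedPost]]:
    """Detect subdomain mentions and aggregate them to patient level.

    Patients with a Global-health mention additionally receive the polarity
    classification of their global-health evidence texts.
    """
    tokenized = tokenize_posts(posts, dict(matched_keywords or {}), stopwords, stemmer)
    processed = lexicon.processed(stopwords=stopwords, stemmer=stemmer)
    detections = [detect_mentions(tp.tokens, processed) for tp in tokenized]
    patients, mentions = aggregate_patients(
        zip(posts, detections), alias_map, {s.id: s for s in subdomains}
    )
    text_of = {p.post_id: p.text for p in posts}
    classified: list[PatientRecord] = []
    for rec in patients:
        gh_evidence = [
            text_of[post_id]
            for m in mentions
            if m.patient_id == rec.patient_id and m.domain == _GLOBAL_HEALTH_DOMAIN
            for post_id, _phrase in m.evidence
        ]
        if gh_evidence:
            state, _confident = classify_global_health(gh_evidence, polarity)
            classified.append(replace(rec, global_health_state=state))
        else:
            classified.append(replace(rec, global_health_state=None))
    return classified, mentions, tokenized


def run_pipeline(
    raw_posts: Sequence[Post],
    alias_map: Mapping[str, PatientRecord],
    keywords: KeywordLexicon | None = None,
    lexicon: SubdomainLexicon | None = None,
    polarity: PolarityLexicon | None = None,
    subdomains: Sequence[Subdomain] | None = None,
    concept_map: ConceptMap | None = None,
    window: tuple[dt.date, dt.date] = STUDY_WINDOW,
    dedup_threshold: float = 0.9,
    stopwords=None,
    stemmer=None,
) -> PipelineResult:
    """Run filter -> dedup -> deidentify -> annotate -> coverage."""
    if subdomains is None or concept_map is None:
        subdomains, concept_map = load_taxonomy()
    keywords = keywords or KeywordLexicon.default()
    lexicon = lexicon or SubdomainLexicon.default()

    kept, matched = filter_posts(raw_posts, keywords, window)
    logger.info("stage=filter in=%d out=%d", len(raw_posts), len(kept))
    deduped, removals = deduplicate(kept, threshold=dedup_threshold)
    logger.info("stage=dedup in=%d out=%d removed=%d", len(kept), len(deduped), len(removals))
    redactions: dict[str, list[RedactionSpan]] = {}
    clean_posts: list[Post] = []
    for post in deduped:
        redacted, spans = deidentify(post.text)
        redactions[post.post_id] = spans
        clean_posts.append(replace(post, text=redacted))
    logger.info(
        "stage=deidentify posts=%d redactions=%d",
        len(clean_posts),
        sum(len(s) for s in redactions.values()),
    )
    patients, mentions, tokenized = annotate_posts(
        clean_posts, lexicon, alias_map, subdomains, matched, polarity, stopwords, stemmer
    )
    logger.info("stage=annotate patients=%d mentions=%d", len(patients), len(mentions))
    occurrences = occurrence_table(mentions)
    report = coverage_report(occurrences, concept_map, subdomains)
    return PipelineResult(
        posts=clean_posts,
        matched_keywords=matched,
        removals=removals,
        redactions=redactions,
        tokenized=tokenized,
        patients=patients,
        mentions=mentions,
        occurrences=occurrences,
        report=report,
    )
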