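"""Lexicon-based HRQoL subdomain annotation and patient-level aggregation.

The source analysis coded subdomain mentions manually; this module
operationalises that step with a trigger-phrase lexicon.  A subdomain is
detected in a post iff one of its phrases — run through the identical
cleaning pipeline as the post — occurs as a contiguous stem sequence.

The unit of analysis is the patient: a (patient, subdomain) pair counts once
no matter how many posts repeat it, which is the only reading consistent
with the published occurrence arithmetic (e.g. the Global-health partition
63 + 32 + 20 = 115 patients).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import AnnotationError, LexiconError
from .taxonomy import Subdomain
from .textprep import normalize, preprocess_phrase

__all__ = [
    "SubdomainLexicon",
    "MentionRecord",
    "PatientRecord",
    "detect_mentions",
    "aggregate_patients",
    "occurrence_table",
    "PolarityLexicon",
    "classify_global_health",
    "GLOBAL_HEALTH_PRIORITY",
]

logger = logging.getLogger(__name__)

#: Tie-break priority for the global-health polarity vote.
GLOBAL_HEALTH_PRIORITY: tuple[str, ...] = ("poor", "stable", "good")


class SubdomainLexicon:
    """subdomain id -> trigger phrases (stored raw, matched preprocessed)."""

    def __init__(self, phrases: Mapping[str, Sequence[str]]):
        if not phrases:
            raise LexiconError("trigger lexicon is empty")
        for sub, plist in phrases.items():
            if not plist or any(not p or not str(p).strip() for p in plist):
                raise LexiconError(f"subdomain {sub!r} has no usable trigger phrase")
        self.phrases: dict[str, tuple[str, ...]] = {
            sub: tuple(str(p) for p in plist) for sub, plist in phrases.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubdomainLexicon":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise LexiconError(f"{path}: expected a mapping subdomain -> phrase list")
        return cls(data)

    @classmethod
    def default(cls) -> "SubdomainLexicon":
        ref = resources.files("hrqolsm.data").joinpath("lexicon_fr.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def validate_against(self, subdomains: Iterable[Subdomain]) -> None:
        known = {sub.id for sub in subdomains}
        unknown = set(self.phrases) - known
        if unknown:
            raise LexiconError(f"lexicon references unknown subdomain id(s): {sorted(unknown)}")

    def processed(self, stopwords=None, stemmer=None) -> dict[str, list[tuple[str, ...]]]:
        """Phrases as matchable stem sequences (empty sequences dropped)."""
        out: dict[str, list[tuple[str, ...]]] = {}
        for sub, plist in self.phrases.items():
            seqs = []
            for phrase in plist:
                seq = preprocess_phrase(phrase, stopwords=stopwords, stemmer=stemmer)
                if seq and seq not in seqs:
                    seqs.append(seq)
            if not seqs:
                raise LexiconError(
                    f"subdomain {sub!r}: every trigger phrase vanished during preprocessing"
                )
            out[sub] = seqs
        return out


def _contains_contiguous(tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    first = phrase[0]
    for i in range(len(tokens) - k + 1):
        if tokens[i] == first and tuple(tokens[i : i + k]) == tuple(phrase):
            return True
    return False


def detect_mentions(
    tokens: Sequence[str],
    processed_lexicon: Mapping[str, Sequence[tuple[str, ...]]],
) -> list[tuple[str, str]]:
    """Detect subdomains in one tokenized post.

    Returns sorted, deduplicated (subdomain id, matched phrase) pairs; the
    matched phrase is reported as the joined stem sequence.
    """
    hits: list[tuple[str, str]] = []
    for sub_id in sorted(processed_lexicon):
        for seq in processed_lexicon[sub_id]:
            if _contains_contiguous(tokens, seq):
                hits.append((sub_id, " ".join(seq)))
                break
    return hits


@dataclass(frozen=True)
class PatientRecord:
    """The per-user unit of analysis with its reported characteristics."""

    patient_id: str
    alias: str
    reporter: str = "unspecified"  # patient | relative | unspecified
    gender: str = "undetermined"  # woman | man | undetermined
    cancer: str = "undetermined"
    drug: str = "undetermined"
    global_health_state: str | None = None  # poor | stable | good


@dataclass
class MentionRecord:
    """One (patient, subdomain) mention with its supporting posts."""

    patient_id: str
    domain: str
    subdomain_id: str
    evidence: list[tuple[str, str]] = field(default_factory=list)  # (post_id, phrase)


def aggregate_patients(
    post_detections: Iterable[tuple["object", list[tuple[str, str]]]],
    alias_map: Mapping[str, PatientRecord],
    subdomain_index: Mapping[str, Subdomain],
) -> tuple[list[PatientRecord], list[MentionRecord]]:
    """Collapse post-level detections to patient-level mention records.

    ``post_detections`` iterates (post, detections) pairs; every alias must
    map to a PatientRecord, otherwise aggregation fails hard.  A (patient,
    subdomain) pair yields exactly one MentionRecord whose evidence lists all
    contributing posts.  The result is invariant under post order.
    """
    mentions: dict[tuple[str, str], MentionRecord] = {}
    seen_patients: dict[str, PatientRecord] = {}
    for post, detections in post_detections:
        record = alias_map.get(post.alias)
        if record is None:
            raise AnnotationError(f"post {post.post_id!r}: alias {post.alias!r} maps to no patient")
        seen_patients[record.patient_id] = record
        for sub_id, phrase in detections:
            sub = subdomain_index.get(sub_id)
            if sub is None:
                raise AnnotationError(f"detected unknown subdomain id {sub_id!r}")
            key = (record.patient_id, sub_id)
            if key not in mentions:
                mentions[key] = MentionRecord(record.patient_id, sub.domain, sub_id)
            mentions[key].evidence.append((post.post_id, phrase))
    for rec in mentions.values():
        rec.evidence.sort()
    patients = [seen_patients[pid] for pid in sorted(seen_patients)]
    return patients, [mentions[k] for k in sorted(mentions)]


def occurrence_table(mentions: Iterable[MentionRecord]) -> dict[str, int]:
    """Subdomain id -> number of distinct patients mentioning it."""
    counts: dict[str, int] = {}
    for rec in mentions:
        counts[rec.subdomain_id] = counts.get(rec.subdomain_id, 0) + 1
    return counts


class PolarityLexicon:
    """Phrasebook for the global-health state vote: state -> phrases."""

    def __init__(self, phrases: Mapping[str, Sequence[str]]):
        missing = set(GLOBAL_HEALTH_PRIORITY) - set(phrases)
        if missing:
            raise LexiconError(f"polarity phrasebook lacks state(s): {sorted(missing)}")
        self.phrases = {state: tuple(phrases[state]) for state in GLOBAL_HEALTH_PRIORITY}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PolarityLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "PolarityLexicon":
        ref = resources.files("hrqolsm.data").joinpath("polarity_fr.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def classify_global_health(
    evidence_texts: Iterable[str],
    phrasebook: PolarityLexicon | None = None,
) -> tuple[str, bool]:
    """Keyword-polarity vote over a patient's global-health evidence texts.

    Returns (state, confident).  Counts accent/case-folded phrase hits per
    state; the majority wins, ties break by the fixed priority
    poor > stable > good.  With no polarity phrase at all the state defaults
    to "stable" and ``confident`` is False (also logged).
    """
    phrasebook = phrasebook or PolarityLexicon.default()
    folded = [normalize(t) for t in evidence_texts]
    votes = {
        state: sum(text.count(normalize(p)) for text in folded for p in phrasebook.phrases[state])
        for state in GLOBAL_HEALTH_PRIORITY
    }
    total = sum(votes.values())
    if total == 0:
        logger.warning("global-health evidence carries no polarity phrase; defaulting to 'stable'")
        return "stable", False
    best = max(votes.values())
    for state in GLOBAL_HEALTH_PRIORITY:  # fixed priority resolves ties
        if votes[state] == best:
            return state, True
    raise AssertionError("unreachable")
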