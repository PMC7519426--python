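"""Corpus construction: inclusion filter, deduplication, deidentification, DTM.

Mirrors the funnel used to build the analysis corpus from raw posts:

1. keep posts inside the study window that mention an immune-checkpoint-
   inhibitor keyword (accent/case-insensitive),
2. drop near-duplicate posts re-published by the same user on another source,
3. redact personal identifiers (names, phone numbers, postal codes, emails),
4. clean and tokenize the text, and
5. assemble a document-term matrix with a rarity threshold and optional
   tf-idf weighting.

Every stage is a pure function of its inputs.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml
from sklearn.feature_extraction.text import TfidfTransformer

from .errors import CorpusError, LexiconError
from .textprep import normalize, preprocess

__all__ = [
    "Post",
    "read_corpus",
    "write_corpus",
    "KeywordLexicon",
    "filter_posts",
    "deduplicate",
    "DuplicateRemoval",
    "deidentify",
    "RedactionSpan",
    "TokenizedPost",
    "tokenize_posts",
    "DocumentTermMatrix",
    "build_dtm",
    "STUDY_WINDOW",
]

#: Default study window, half-open [start, end): marketing authorisation of
#: the first ICI in France through the last day of corpus collection.
STUDY_WINDOW: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2018, 9, 1))


@dataclass(frozen=True)
class Post:
    """One social-media message with its source metadata."""

    post_id: str
    source: str
    url: str
    date: dt.date
    alias: str
    text: str
    language: str = "fr"

    def to_json(self) -> str:
        record = asdict(self)
        record["date"] = self.date.isoformat()
        return json.dumps(record, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_dict(cls, record: dict) -> "Post":
        record = dict(record)
        record["date"] = dt.date.fromisoformat(record["date"])
        return cls(**record)


def write_corpus(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts as JSON Lines (UTF-8, one record per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(post.to_json() + "\n")


def read_corpus(path: str | Path) -> list[Post]:
    """Read a JSON Lines corpus; malformed records fail with their line number."""
    posts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                posts.append(Post.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusError(f"{path}:{lineno}: malformed post record ({exc})") from exc
    return posts


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------


class KeywordLexicon:
    """ICI keyword lexicon: drug (or class term) -> list of synonyms."""

    def __init__(self, synonyms: dict[str, list[str]]):
        if not synonyms:
            raise LexiconError("keyword lexicon is empty")
        for drug, syns in synonyms.items():
            if not syns or any(not s or not s.strip() for s in syns):
                raise LexiconError(f"drug {drug!r} has an empty synonym list or blank synonym")
        self.synonyms = {drug: list(syns) for drug, syns in synonyms.items()}
        # normalized synonym -> canonical keyword string, insertion-ordered
        self._patterns: list[tuple[re.Pattern, str]] = []
        for drug, syns in self.synonyms.items():
            for syn in syns:
                folded = normalize(syn)
                pattern = re.compile(
                    r"(?<![a-z0-9])" + re.escape(folded).replace(r"\ ", r"[\s\-]+") + r"(?![a-z0-9])"
                )
                self._patterns.append((pattern, syn))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KeywordLexicon":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise LexiconError(f"{path}: expected a mapping drug -> synonym list")
        return cls(data)

    @classmethod
    def default(cls) -> "KeywordLexicon":
        ref = resources.files("hrqolsm.data").joinpath("keywords_fr.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def first_match(self, text: str) -> str | None:
        """Earliest-position matching synonym (ties broken by lexicon order)."""
        folded = normalize(text)
        best: tuple[int, int, str] | None = None
        for order, (pattern, syn) in enumerate(self._patterns):
            m = pattern.search(folded)
            if m and (best is None or (m.start(), order) < best[:2]):
                best = (m.start(), order, syn)
        return best[2] if best else None

    def synonyms_for(self, drug: str) -> list[str]:
        return self.synonyms[drug]


def filter_posts(
    posts: Iterable[Post],
    lexicon: KeywordLexicon | None = None,
    window: tuple[dt.date, dt.date] = STUDY_WINDOW,
) -> tuple[list[Post], dict[str, str]]:
    """Apply the inclusion rules; returns (kept posts, post_id -> matched keyword).

    A post is retained iff its date falls in the half-open window and its
    text contains at least one keyword synonym (accent/case-insensitive,
    word-boundary).  An empty result is valid.
    """
    start, end = window
    if start > end:
        raise CorpusError(f"study window start {start} is after end {end}")
    lexicon = lexicon or KeywordLexicon.default()
    kept: list[Post] = []
    matched: dict[str, str] = {}
    for post in posts:
        if not (start <= post.date < end):
            continue
        keyword = lexicon.first_match(post.text)
        if keyword is None:
            continue
        kept.append(post)
        matched[post.post_id] = keyword
    return kept, matched


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicateRemoval:
    removed_id: str
    kept_id: str
    similarity: float


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def deduplicate(
    posts: Sequence[Post],
    threshold: float = 0.9,
) -> tuple[list[Post], list[DuplicateRemoval]]:
    """Remove similar re-posts by the same alias, keeping the earliest-dated.

    Similarity is Jaccard overlap of the preprocessed token sets, with an
    exact match on normalized text as a fast path.  The rule is scoped to a
    single alias: identical text under different aliases is kept.  Idempotent.
    """
    by_alias: dict[str, list[Post]] = {}
    for post in posts:
        by_alias.setdefault(post.alias, []).append(post)

    removed: dict[str, DuplicateRemoval] = {}
    for alias_posts in by_alias.values():
        ordered = sorted(alias_posts, key=lambda p: (p.date, p.post_id))
        kept_reps: list[tuple[Post, str, frozenset[str]]] = []
        for post in ordered:
            norm = normalize(post.text)
            tokens = frozenset(preprocess(post.text))
            duplicate_of = None
            similarity = 0.0
            for rep, rep_norm, rep_tokens in kept_reps:
                if norm == rep_norm:
                    duplicate_of, similarity = rep, 1.0
                    break
                sim = _jaccard(tokens, rep_tokens)
                if sim >= threshold:
                    duplicate_of, similarity = rep, sim
                    break
            if duplicate_of is None:
                kept_reps.append((post, norm, tokens))
            else:
                removed[post.post_id] = DuplicateRemoval(
                    post.post_id, duplicate_of.post_id, round(similarity, 6)
                )

    kept = [p for p in posts if p.post_id not in removed]
    log = [removed[p.post_id] for p in posts if p.post_id in removed]
    return kept, log


# ---------------------------------------------------------------------------
# Deidentification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RedactionSpan:
    cls: str  # name | phone | postal | email
    start: int
    end: int
    text: str


_PLACEHOLDERS = {"name": "<NAME>", "phone": "<PHONE>", "postal": "<POSTAL>", "email": "<EMAIL>"}

_EMAIL_RE = re.compile(r"[A-Za-z0-9.%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}")
# French numbers: ten digits starting 0 (optional space/dot/dash separators)
# or the international +33 form.
_PHONE_RE = re.compile(r"(?<!\d)(?:\+33[ .\-]?|0)[1-9](?:[ .\-]?\d{2}){4}(?!\d)")
_POSTAL_RE = re.compile(r"(?<!\d)\d{5}(?!\d)")
_HONORIFIC_RE = re.compile(
    r"\b(?:M\.|Mr|Mme|Mlle|Dr|Pr|Monsieur|Madame|Mademoiselle|Docteur|Professeur)"
    r"\s+([A-ZÀ-Þ][a-zà-ÿA-ZÀ-Þ'\-]+)"
)


def _default_name_dictionary() -> tuple[str, ...]:
    ref = resources.files("hrqolsm.data").joinpath("names_fr.txt")
    names = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            names.append(entry)
    return tuple(names)


def deidentify(
    text: str,
    name_dictionary: Iterable[str] | None = None,
) -> tuple[str, list[RedactionSpan]]:
    """Replace personal identifiers with class placeholders.

    Four pattern classes are detected, in priority order email > phone >
    postal code > proper name; names combine a configurable dictionary
    (capitalized, word-boundary) with a capitalized-token heuristic after
    honorifics.  Spans refer to the original text.  Idempotent: placeholders
    match none of the patterns.
    """
    names = tuple(name_dictionary) if name_dictionary is not None else _default_name_dictionary()
    name_res: list[re.Pattern] = []
    if names:
        name_res.append(re.compile(r"\b(?:" + "|".join(map(re.escape, names)) + r")\b"))

    candidates: list[RedactionSpan] = []

    def claim(cls: str, start: int, end: int) -> None:
        for span in candidates:
            if start < span.end and span.start < end:
                return
        candidates.append(RedactionSpan(cls, start, end, text[start:end]))

    for m in _EMAIL_RE.finditer(text):
        claim("email", m.start(), m.end())
    for m in _PHONE_RE.finditer(text):
        claim("phone", m.start(), m.end())
    for m in _POSTAL_RE.finditer(text):
        claim("postal", m.start(), m.end())
    for m in _HONORIFIC_RE.finditer(text):
        claim("name", m.start(1), m.end(1))
    for name_re in name_res:
        for m in name_re.finditer(text):
            claim("name", m.start(), m.end())

    candidates.sort(key=lambda s: s.start)
    pieces, cursor = [], 0
    for span in candidates:
        pieces.append(text[cursor:span.start])
        pieces.append(_PLACEHOLDERS[span.cls])
        cursor = span.end
    pieces.append(text[cursor:])
    return "".join(pieces), candidates


# ---------------------------------------------------------------------------
# Tokenisation + document-term matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TokenizedPost:
    post_id: str
    tokens: tuple[str, ...]
    matched_keyword: str | None = None


def tokenize_posts(
    posts: Iterable[Post],
    matched_keywords: dict[str, str] | None = None,
    stopwords=None,
    stemmer=None,
) -> list[TokenizedPost]:
    """Run the cleaning pipeline over each post."""
    matched_keywords = matched_keywords or {}
    return [
        TokenizedPost(
            post.post_id,
            tuple(preprocess(post.text, stopwords=stopwords, stemmer=stemmer)),
            matched_keywords.get(post.post_id),
        )
        for post in posts
    ]


@dataclass
class DocumentTermMatrix:
    matrix: sp.csr_matrix
    post_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    weighting: str  # "count" | "tfidf"

    def save(self, directory: str | Path) -> None:
        """Export as Matrix Market + vocabulary/post-id CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "dtm.mtx"), self.matrix)
        (directory / "vocabulary.csv").write_text(
            "token\n" + "\n".join(self.vocabulary) + "\n", encoding="utf-8"
        )
        (directory / "post_ids.csv").write_text(
            "post_id\n" + "\n".join(self.post_ids) + "\n", encoding="utf-8"
        )


def build_dtm(
    tokenized_posts: Sequence[TokenizedPost],
    min_token_freq: int = 2,
    weighting: str = "tfidf",
    exclude: Iterable[str] = (),
) -> DocumentTermMatrix:
    """Assemble the posts × tokens matrix.

    The vocabulary keeps tokens whose total corpus frequency reaches
    ``min_token_freq`` and that are not on the explicit exclusion list (the
    hook for ambiguous/misspelled words; empty by default).  Weighting is
    raw counts or tf-idf (sklearn's smoothed variant, L2-normalised rows).
    """
    if not tokenized_posts:
        raise CorpusError("cannot build a document-term matrix from an empty corpus")
    if weighting not in ("count", "tfidf"):
        raise CorpusError(f"unknown weighting {weighting!r} (expected 'count' or 'tfidf')")
    excluded = set(exclude)

    totals: dict[str, int] = {}
    for tp in tokenized_posts:
        for tok in tp.tokens:
            totals[tok] = totals.get(tok, 0) + 1
    vocabulary = tuple(
        sorted(t for t, n in totals.items() if n >= min_token_freq and t not in excluded)
    )
    index = {t: j for j, t in enumerate(vocabulary)}

    rows, cols, vals = [], [], []
    for i, tp in enumerate(tokenized_posts):
        counts: dict[int, int] = {}
        for tok in tp.tokens:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, n in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(n)
    matrix = sp.csr_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)),
        shape=(len(tokenized_posts), len(vocabulary)),
    )
    if weighting == "tfidf":
        matrix = TfidfTransformer().fit_transform(matrix)
    return DocumentTermMatrix(
        matrix=matrix,
        post_ids=tuple(tp.post_id for tp in tokenized_posts),
        vocabulary=vocabulary,
        weighting=weighting,
    )
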