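"""Corpus cleaning: accent folding, tokenisation, stop words, stemming.

The pipeline order is fixed and deterministic:

1. fold accents (NFKD, drop combining marks, œ→oe)
2. lowercase
3. strip punctuation (every non-alphanumeric character becomes a space)
4. whitespace tokenisation
5. stop-word removal (on the folded, unstemmed tokens)
6. stemming (French Porter-family stemmer)
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterable

from .stemming import FrenchStemmer

__all__ = [
    "fold_accents",
    "normalize",
    "tokenize",
    "preprocess",
    "load_stopwords",
    "default_stopwords",
]

_PUNCT = re.compile(r"[^a-z0-9]+")


def fold_accents(text: str) -> str:
    """Remove diacritics and decompose ligatures; case is preserved."""
    text = text.replace("œ", "oe").replace("Œ", "OE").replace("æ", "ae").replace("Æ", "AE")
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize(text: str) -> str:
    """Accent-fold, lowercase and collapse punctuation/whitespace to single spaces."""
    return _PUNCT.sub(" ", fold_accents(text).lower()).strip()


def tokenize(text: str) -> list[str]:
    norm = normalize(text)
    return norm.split() if norm else []


def load_stopwords(path) -> frozenset[str]:
    """Read one stop word per line; blank lines and ``#`` comments ignored.

    Entries are accent-folded and lowercased so the list matches the pipeline
    no matter how it was typed.
    """
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip()
            if word:
                words.add(normalize(word))
    return frozenset(words)


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    ref = resources.files("hrqolsm.data").joinpath("stopwords_fr.txt")
    with resources.as_file(ref) as path:
        return load_stopwords(path)


def preprocess(
    text: str,
    stopwords: Iterable[str] | None = None,
    stemmer: Callable[[str], str] | None = None,
) -> list[str]:
    """Run the full cleaning pipeline on one document.

    Parameters
    ----------
    text:
        Raw document text.
    stopwords:
        Stop-word set applied to the folded lowercase tokens; defaults to the
        packaged French list.
    stemmer:
        Token → stem callable; defaults to the packaged French stemmer.
    """
    stop = default_stopwords() if stopwords is None else frozenset(stopwords)
    do_stem = FrenchStemmer().stem if stemmer is None else stemmer
    return [do_stem(tok) for tok in tokenize(text) if tok not in stop]


def preprocess_phrase(phrase: str, stopwords=None, stemmer=None) -> tuple[str, ...]:
    """Preprocess a lexicon trigger phrase into its matchable stem sequence."""
    return tuple(preprocess(phrase, stopwords=stopwords, stemmer=stemmer))
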