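"""French Porter-family (Snowball) stemmer operating on accent-folded text.

The corpus cleaning pipeline removes French accents *before* stemming, so the
suffix tables below are expressed in accent-folded form: ``é/è/ê → e``,
``î → i`` and so on.  Rules of the published French Snowball algorithm that
exist solely to distinguish accented suffixes collapse into their folded
counterparts; suffixes whose folded form would collide with common nominal
endings (``-ât``, ``-âmes``, ``-îtes`` …) are dropped rather than allowed to
overstem.  The region logic (RV/R1/R2), longest-match semantics, the marking
of ``u``/``i``/``y`` as non-vowels between vowels, and the step structure all
follow the standard algorithm.

Input tokens are expected to be lowercase ASCII (the output of
:func:`hrqolsm.textprep.fold_accents` + lowercasing); anything else is folded
defensively.
"""

from __future__ import annotations

import unicodedata

__all__ = ["FrenchStemmer", "stem"]

_VOWELS = frozenset("aeiouy")


def _fold(word: str) -> str:
    word = word.replace("œ", "oe").replace("æ", "ae")
    decomposed = unicodedata.normalize("NFKD", word.lower())
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def _mark_consonant_vowels(word: str) -> str:
    """Upper-case u/i between vowels, y next to a vowel and u after q.

    Upper-case letters act as consonants in every subsequent test; they are
    lowered again at the very end of stemming.
    """
    ch = list(word)
    n = len(ch)
    i = 0
    while i < n:
        c = ch[i]
        if c in _VOWELS and i + 1 < n:
            nxt = ch[i + 1]
            if nxt in ("u", "i") and i + 2 < n and ch[i + 2] in _VOWELS:
                ch[i + 1] = nxt.upper()
                i += 2
                continue
            if nxt == "y":
                ch[i + 1] = "Y"
                i += 2
                continue
        if c == "y" and i + 1 < n and ch[i + 1] in _VOWELS:
            ch[i] = "Y"
        elif c == "q" and i + 1 < n and ch[i + 1] == "u":
            ch[i + 1] = "U"
            i += 1
        i += 1
    return "".join(ch)


def _rv_start(word: str) -> int:
    n = len(word)
    if n >= 3 and word[0] in _VOWELS and word[1] in _VOWELS:
        return 3
    if word[:3] in ("par", "col", "tap"):
        return 3
    for j in range(1, n):
        if word[j] in _VOWELS:
            return j + 1
    return n


def _region_after_first_nonvowel_following_vowel(word: str, start: int) -> int:
    for j in range(start, len(word) - 1):
        if word[j] in _VOWELS and word[j + 1] not in _VOWELS:
            return j + 2
    return len(word)


# ---------------------------------------------------------------------------
# Step 1 suffix table: (suffix, rule id), consulted longest-first.
# ---------------------------------------------------------------------------
_STEP1_SUFFIXES = sorted(
    [
        ("issements", "issement"), ("issement", "issement"),
        ("atrices", "ateur"), ("atrice", "ateur"),
        ("ateurs", "ateur"), ("ateur", "ateur"),
        ("ations", "ateur"), ("ation", "ateur"),
        ("logies", "logie"), ("logie", "logie"),
        ("usions", "usion"), ("usion", "usion"),
        ("utions", "usion"), ("ution", "usion"),
        ("ences", "ence"), ("ence", "ence"),
        ("ements", "ement"), ("ement", "ement"),
        ("ites", "ite"), ("ite", "ite"),
        ("ives", "if"), ("ive", "if"), ("ifs", "if"), ("if", "if"),
        ("eaux", "eaux"), ("aux", "aux"),
        ("euses", "euse"), ("euse", "euse"),
        ("amment", "amment"), ("emment", "emment"),
        ("ments", "ment"), ("ment", "ment"),
        ("ances", "del_r2"), ("ance", "del_r2"),
        ("iqUes", "del_r2"), ("iqUe", "del_r2"),
        ("ismes", "del_r2"), ("isme", "del_r2"),
        ("ables", "del_r2"), ("able", "del_r2"),
        ("istes", "del_r2"), ("iste", "del_r2"),
        ("eux", "del_r2"),
    ],
    key=lambda t: -len(t[0]),
)

_STEP2A_SUFFIXES = sorted(
    [
        "iraIent", "issaIent", "issantes", "issante", "issants", "issant",
        "issions", "issons", "issiez", "issent", "issais", "issait", "isses",
        "issez", "isse", "irions", "irais", "irait", "irent", "irons",
        "iront", "irez", "iriez", "irai", "iras", "ira", "ies", "ie", "ir",
        "is", "it", "i",
    ],
    key=len,
    reverse=True,
)

_STEP2B_E_GROUP = [
    "eraIent", "erions", "erent", "erons", "eront", "erais", "erait",
    "eriez", "erai", "eras", "erez", "ees", "era", "iez", "ee", "er", "ez",
]
_STEP2B_A_GROUP = [
    "assions", "assiez", "assent", "asses", "aIent", "antes", "asse",
    "ante", "ants", "ant", "ais", "ait", "as", "ai", "a",
]
_STEP2B_SUFFIXES = sorted(
    [("ions", "ions")]
    + [(s, "e_group") for s in _STEP2B_E_GROUP]
    + [(s, "a_group") for s in _STEP2B_A_GROUP],
    key=lambda t: -len(t[0]),
)


class FrenchStemmer:
    """Stemmer for accent-folded French tokens.

    >>> FrenchStemmer().stem("fatiguee")
    'fatigu'
    """

    def stem(self, token: str) -> str:
        word = _fold(token)
        if len(word) <= 2 or not word.isalpha():
            return word
        word = _mark_consonant_vowels(word)
        rv = _rv_start(word)
        r1 = _region_after_first_nonvowel_following_vowel(word, 0)
        r2 = _region_after_first_nonvowel_following_vowel(word, r1)

        word, did1, ment_like = self._step1(word, rv, r1, r2)
        did2a = did2b = False
        if (not did1) or ment_like:
            word, did2a = self._step2a(word, rv)
            if not did2a:
                word, did2b = self._step2b(word, rv, r2)
        if did1 or did2a or did2b:
            word = self._step3(word)
        else:
            word = self._step4(word, rv, r2)
        word = self._step5(word)
        return word.lower()

    # -- step 1 -------------------------------------------------------------

    def _step1(self, w: str, rv: int, r1: int, r2: int):
        for suffix, rule in _STEP1_SUFFIXES:
            if not w.endswith(suffix):
                continue
            p = len(w) - len(suffix)
            in_rv, in_r1, in_r2 = p >= rv, p >= r1, p >= r2

            if rule == "del_r2":
                return (w[:p], True, False) if in_r2 else (w, False, False)
            if rule == "ateur":
                if not in_r2:
                    return w, False, False
                w = w[:p]
                if w.endswith("ic"):
                    w = w[:-2] if len(w) - 2 >= r2 else w[:-2] + "iqU"
                return w, True, False
            if rule == "logie":
                return (w[:p] + "log", True, False) if in_r2 else (w, False, False)
            if rule == "usion":
                return (w[:p] + "u", True, False) if in_r2 else (w, False, False)
            if rule == "ence":
                return (w[:p] + "ent", True, False) if in_r2 else (w, False, False)
            if rule == "ement":
                if not in_rv:
                    return w, False, False
                w = w[:p]
                if w.endswith("iv") and len(w) - 2 >= r2:
                    w = w[:-2]
                    if w.endswith("at") and len(w) - 2 >= r2:
                        w = w[:-2]
                elif w.endswith("eus"):
                    if len(w) - 3 >= r2:
                        w = w[:-3]
                    elif len(w) - 3 >= r1:
                        w = w[:-3] + "eux"
                elif w.endswith("abl") and len(w) - 3 >= r2:
                    w = w[:-3]
                elif w.endswith("iqU") and len(w) - 3 >= r2:
                    w = w[:-3]
                elif (w.endswith("ier") or w.endswith("Ier")) and len(w) - 3 >= rv:
                    w = w[:-3] + "i"
                return w, True, False
            if rule == "ite":
                if not in_r2:
                    return w, False, False
                w = w[:p]
                if w.endswith("abil"):
                    w = w[:-4] if len(w) - 4 >= r2 else w[:-4] + "abl"
                elif w.endswith("ic"):
                    w = w[:-2] if len(w) - 2 >= r2 else w[:-2] + "iqU"
                elif w.endswith("iv") and len(w) - 2 >= r2:
                    w = w[:-2]
                return w, True, False
            if rule == "if":
                if not in_r2:
                    return w, False, False
                w = w[:p]
                if w.endswith("at") and len(w) - 2 >= r2:
                    w = w[:-2]
                    if w.endswith("ic"):
                        w = w[:-2] if len(w) - 2 >= r2 else w[:-2] + "iqU"
                return w, True, False
            if rule == "eaux":
                return w[:p] + "eau", True, False
            if rule == "aux":
                return (w[:p] + "al", True, False) if in_r1 else (w, False, False)
            if rule == "euse":
                if in_r2:
                    return w[:p], True, False
                if in_r1:
                    return w[:p] + "eux", True, False
                return w, False, False
            if rule == "issement":
                if in_r1 and p > 0 and w[p - 1] not in _VOWELS:
                    return w[:p], True, False
                return w, False, False
            if rule == "amment":
                return (w[:p] + "ant", True, True) if in_rv else (w, False, False)
            if rule == "emment":
                return (w[:p] + "ent", True, True) if in_rv else (w, False, False)
            if rule == "ment":
                if p - 1 >= rv and w[p - 1] in _VOWELS:
                    return w[:p], True, True
                return w, False, False
        return w, False, False

    # -- steps 2a / 2b ------------------------------------------------------

    def _step2a(self, w: str, rv: int):
        for suffix in _STEP2A_SUFFIXES:
            if not w.endswith(suffix):
                continue
            p = len(w) - len(suffix)
            if p - 1 >= rv and w[p - 1] not in _VOWELS and w[p - 1] != "H":
                return w[:p], True
            return w, False
        return w, False

    def _step2b(self, w: str, rv: int, r2: int):
        for suffix, group in _STEP2B_SUFFIXES:
            if not w.endswith(suffix):
                continue
            p = len(w) - len(suffix)
            if p < rv:
                continue
            if group == "ions":
                return (w[:p], True) if p >= r2 else (w, False)
            if group == "e_group":
                return w[:p], True
            # a_group: delete, plus a preceding e inside RV
            w = w[:p]
            if w.endswith("e") and len(w) - 1 >= rv:
                w = w[:-1]
            return w, True
        return w, False

    # -- steps 3 / 4 / 5 ----------------------------------------------------

    @staticmethod
    def _step3(w: str) -> str:
        if w.endswith("Y"):
            return w[:-1] + "i"
        if w.endswith("ç"):  # folded text should never carry ç, kept for safety
            return w[:-1] + "c"
        return w

    @staticmethod
    def _step4(w: str, rv: int, r2: int) -> str:
        if w.endswith("s") and (len(w) < 2 or w[-2] not in "aious"):
            w = w[:-1]
        for suffix in ("iere", "Iere", "ion", "ier", "Ier", "e"):
            if not w.endswith(suffix):
                continue
            p = len(w) - len(suffix)
            if p < rv:
                break
            if suffix == "ion":
                if p >= r2 and p - 1 >= rv and w[p - 1] in "st":
                    w = w[:p]
                break
            if suffix == "e":
                w = w[:p]
                break
            w = w[:p] + "i"
            break
        return w

    @staticmethod
    def _step5(w: str) -> str:
        for ending in ("enn", "onn", "ett", "ell", "eill"):
            if w.endswith(ending):
                return w[:-1]
        return w


_DEFAULT = FrenchStemmer()


def stem(token: str) -> str:
    """Stem a single accent-folded lowercase token."""
    return _DEFAULT.stem(token)
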