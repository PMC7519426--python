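"""Synthetic social-media corpus generator with planted ground truth.

Emulates the statistical structure of the study cohort — 150 posters, a
posts-per-patient distribution with median 2 and maximum 11, a 59.3/40.7
patient/relative reporter split, the published gender/cancer/drug margins,
and per-subdomain mention prevalences scaled from the published occurrence
counts — while planting fully known ground truth: per-patient attributes and
subdomain mentions, injected personal identifiers, cross-source duplicate
re-posts and non-ICI decoy posts.

Posts are French-flavoured template text with slot-filled trigger phrases;
linguistic realism is explicitly not a goal, only the lexical signal
structure matters.  A deterministic assignment mode plants an exact
user-supplied occurrence vector, which makes occurrence-table-shaped corpora
exactly reproducible end to end.  Everything is a pure function of the
config (including its seed).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotate import GLOBAL_HEALTH_PRIORITY, PatientRecord, PolarityLexicon, SubdomainLexicon
from .corpus import STUDY_WINDOW, KeywordLexicon, Post
from .errors import GeneratorError
from .taxonomy import Subdomain, load_taxonomy

__all__ = ["GeneratorConfig", "GroundTruth", "generate_corpus"]

_GLOBAL_HEALTH_DOMAIN = "Global health"

_SOURCES = (
    "doctissimo",
    "la-ligue-contre-le-cancer",
    "facebook",
    "youtube",
    "instagram",
    "forum-cancer-generaliste",
    "forum-sante-generaliste",
)

_NICKS = ("lavande", "mouette", "papillon", "horizon", "mistral", "capucine", "verveine", "colibri")

_OPENERS = (
    "bonjour a tous voici quelques nouvelles du traitement",
    "bonsoir je passe sur le forum pour raconter la suite",
    "coucou tout le monde petit passage pour donner des nouvelles",
    "bonjour je continue mon recit apres la derniere perfusion",
    "salut le groupe voici le point sur ces dernieres semaines",
)

_CONNECTORS = (
    "depuis peu je remarque",
    "ces derniers jours il y a",
    "je voulais aussi signaler",
    "autre chose a noter",
    "par moments je ressens",
)

_DECOY_BODIES = (
    "bonjour ici on parle du parcours avec la chimiotherapie classique et les rayons",
    "bonsoir le protocole de radiotherapie se poursuit a l hopital sans changement",
    "coucou la cure de chimiotherapie standard continue comme prevu ce mois ci",
)

_CITIES = ("lyon", "nantes", "lille", "bordeaux", "toulouse")

#: drug category -> keyword lexicon entries used for the embedded ICI keyword
_DRUG_TO_KEYWORD_KEYS = {
    "nivolumab": ("nivolumab",),
    "ipilimumab": ("ipilimumab",),
    "pembrolizumab": ("pembrolizumab",),
    "other": ("atezolizumab", "durvalumab", "tremelimumab", "avelumab"),
    "undetermined": ("immunotherapy",),
}


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise GeneratorError(f"{name} must be a probability in [0, 1], got {p}")


def _check_categorical(name: str, probs: Mapping[str, float] | Sequence[float]) -> None:
    values = list(probs.values()) if isinstance(probs, Mapping) else list(probs)
    for p in values:
        _check_prob(f"{name} component", float(p))
    if abs(sum(values) - 1.0) > 1e-9:
        raise GeneratorError(f"{name} must sum to 1 (got {sum(values)!r})")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus.

    Defaults reproduce the published cohort margins; the posts-per-patient
    family (truncated geometric) is a modelling choice constrained by the
    published median 2 and maximum 11.
    """

    n_patients: int = 150
    posts_per_patient_p: float = 0.38  # geometric success prob, truncated to [1, max]
    posts_per_patient_max: int = 11
    reporter_split: float = 0.593  # P(reporter == patient), else relative
    gender_split: tuple[float, float, float] = (0.547, 0.400, 0.053)  # woman/man/undet.
    cancer_mix: dict[str, float] = field(
        default_factory=lambda: {
            "lung": 0.307, "melanoma": 0.273, "other": 0.240, "undetermined": 0.180,
        }
    )
    drug_mix: dict[str, float] = field(
        default_factory=lambda: {
            "nivolumab": 0.207, "ipilimumab": 0.133, "pembrolizumab": 0.107,
            "other": 0.073, "undetermined": 0.480,
        }
    )
    global_health_split: tuple[float, float, float] = (0.548, 0.278, 0.174)  # poor/stable/good
    subdomain_prevalence: dict[str, float] | None = None  # default: occurrences / 150
    occurrence_vector: dict[str, int] | None = None  # deterministic assignment mode
    deterministic_margins: bool = False  # exact largest-remainder margins instead of sampling
    pii_rate: float = 0.10
    duplicate_rate: float = 0.08
    decoy_rate: float = 0.10
    window: tuple[dt.date, dt.date] = STUDY_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise GeneratorError("n_patients must be positive")
        if not 0 < self.posts_per_patient_p < 1:
            raise GeneratorError("posts_per_patient_p must lie strictly in (0, 1)")
        if self.posts_per_patient_max < 1:
            raise GeneratorError("posts_per_patient_max must be >= 1")
        for name in ("reporter_split", "pii_rate", "duplicate_rate"):
            _check_prob(name, getattr(self, name))
        if not 0.0 <= self.decoy_rate < 1.0:
            raise GeneratorError("decoy_rate must lie in [0, 1)")
        _check_categorical("gender_split", self.gender_split)
        _check_categorical("cancer_mix", self.cancer_mix)
        _check_categorical("drug_mix", self.drug_mix)
        _check_categorical("global_health_split", self.global_health_split)
        if self.subdomain_prevalence is not None:
            for sub, p in self.subdomain_prevalence.items():
                _check_prob(f"subdomain_prevalence[{sub}]", p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "window" in data:
            data["window"] = tuple(dt.date.fromisoformat(d) for d in data["window"])
        for key in ("gender_split", "global_health_split"):
            if key in data:
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)


@dataclass
class GroundTruth:
    """Everything the generator planted, for closed-world validation."""

    patients: dict[str, PatientRecord]  # patient_id -> record (incl. planted GH state)
    mentions: dict[str, set[tuple[str, str]]]  # patient_id -> {(domain, subdomain_id)}
    post_mentions: dict[str, list[str]]  # post_id -> planted subdomain ids
    pii: dict[str, list[tuple[str, str]]]  # post_id -> [(class, text)]
    duplicates: dict[str, str]  # duplicate post_id -> original post_id
    decoys: set[str]

    @property
    def alias_map(self) -> dict[str, PatientRecord]:
        return {rec.alias: rec for rec in self.patients.values()}

    def occurrence_table(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pairs in self.mentions.values():
            for _domain, sub_id in pairs:
                counts[sub_id] = counts.get(sub_id, 0) + 1
        return counts

    def save(self, path: str | Path) -> None:
        payload = {
            "patients": {pid: asdict(rec) for pid, rec in sorted(self.patients.items())},
            "mentions": {
                pid: sorted(list(pair) for pair in pairs)
                for pid, pairs in sorted(self.mentions.items())
            },
            "post_mentions": dict(sorted(self.post_mentions.items())),
            "pii": {k: [list(t) for t in v] for k, v in sorted(self.pii.items())},
            "duplicates": dict(sorted(self.duplicates.items())),
            "decoys": sorted(self.decoys),
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, sort_keys=True, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            patients={pid: PatientRecord(**rec) for pid, rec in payload["patients"].items()},
            mentions={
                pid: {tuple(pair) for pair in pairs}
                for pid, pairs in payload["mentions"].items()
            },
            post_mentions=payload["post_mentions"],
            pii={k: [tuple(t) for t in v] for k, v in payload["pii"].items()},
            duplicates=payload["duplicates"],
            decoys=set(payload["decoys"]),
        )


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def _apportion(probs: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n units over categories."""
    quotas = [p * n for p in probs]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(probs)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _assign_categorical(
    rng: np.random.Generator, labels: Sequence[str], probs: Sequence[float],
    n: int, deterministic: bool,
) -> list[str]:
    if deterministic:
        pool: list[str] = []
        for label, count in zip(labels, _apportion(probs, n)):
            pool.extend([label] * count)
        arr = np.array(pool, dtype=object)
        rng.shuffle(arr)
        return list(arr)
    return list(rng.choice(np.array(labels, dtype=object), size=n, p=list(probs)))


def _sample_truncated_geometric(rng: np.random.Generator, p: float, kmax: int, n: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1)
    pmf = p * (1 - p) ** (ks - 1)
    pmf /= pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def _sample_date(rng: np.random.Generator, window: tuple[dt.date, dt.date]) -> dt.date:
    span = (window[1] - window[0]).days  # window is half-open
    return window[0] + dt.timedelta(days=int(rng.integers(0, span)))


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generate_corpus(
    config: GeneratorConfig,
    subdomains: Sequence[Subdomain] | None = None,
    lexicon: SubdomainLexicon | None = None,
    keywords: KeywordLexicon | None = None,
    polarity: PolarityLexicon | None = None,
) -> tuple[list[Post], GroundTruth]:
    """Generate a raw-post corpus plus its ground truth.

    Deterministic for a fixed config (the seed lives in the config): the
    same call twice yields byte-identical corpora.
    """
    if subdomains is None:
        subdomains, _ = load_taxonomy()
    lexicon = lexicon or SubdomainLexicon.default()
    keywords = keywords or KeywordLexicon.default()
    polarity = polarity or PolarityLexicon.default()

    sub_index = {sub.id: sub for sub in subdomains}
    missing = [sub.id for sub in subdomains if sub.id not in lexicon.phrases]
    if missing:
        raise GeneratorError(f"trigger lexicon lacks phrases for subdomain(s): {missing}")
    for category, keys in _DRUG_TO_KEYWORD_KEYS.items():
        for key in keys:
            if key not in keywords.synonyms:
                raise GeneratorError(f"keyword lexicon lacks entry {key!r} for drug mix {category!r}")
    if config.occurrence_vector is not None:
        unknown = set(config.occurrence_vector) - set(sub_index)
        if unknown:
            raise GeneratorError(f"occurrence vector names unknown subdomain(s): {sorted(unknown)}")
        too_big = {s: c for s, c in config.occurrence_vector.items() if c > config.n_patients}
        if too_big:
            raise GeneratorError(
                f"occurrence vector exceeds n_patients={config.n_patients}: {too_big}"
            )

    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # -- patients -----------------------------------------------------------
    reporter = _assign_categorical(
        rng, ("patient", "relative"),
        (config.reporter_split, 1 - config.reporter_split),
        n, config.deterministic_margins,
    )
    gender = _assign_categorical(
        rng, ("woman", "man", "undetermined"), config.gender_split,
        n, config.deterministic_margins,
    )
    cancer = _assign_categorical(
        rng, tuple(config.cancer_mix), tuple(config.cancer_mix.values()),
        n, config.deterministic_margins,
    )
    drug = _assign_categorical(
        rng, tuple(config.drug_mix), tuple(config.drug_mix.values()),
        n, config.deterministic_margins,
    )
    nick_choice = rng.choice(np.array(_NICKS, dtype=object), size=n)
    patients: dict[str, PatientRecord] = {}
    patient_ids = []
    for i in range(n):
        pid = f"pt{i + 1:04d}"
        patient_ids.append(pid)
        patients[pid] = PatientRecord(
            patient_id=pid,
            alias=f"{nick_choice[i]}_{i + 1:04d}",
            reporter=reporter[i],
            gender=gender[i],
            cancer=cancer[i],
            drug=drug[i],
        )

    # -- planted mentions ---------------------------------------------------
    mentions: dict[str, set[tuple[str, str]]] = {pid: set() for pid in patient_ids}
    if config.occurrence_vector is not None:
        for sub_id in sorted(config.occurrence_vector):
            count = config.occurrence_vector[sub_id]
            chosen = rng.choice(n, size=count, replace=False)
            for i in chosen:
                mentions[patient_ids[i]].add((sub_index[sub_id].domain, sub_id))
    else:
        prevalence = config.subdomain_prevalence or {
            sub.id: min(1.0, sub.occurrences / 150.0) for sub in subdomains
        }
        for sub_id in sorted(prevalence):
            if sub_id not in sub_index:
                raise GeneratorError(f"prevalence names unknown subdomain {sub_id!r}")
            hits = rng.random(n) < prevalence[sub_id]
            for i in np.flatnonzero(hits):
                mentions[patient_ids[i]].add((sub_index[sub_id].domain, sub_id))

    # -- global-health states ----------------------------------------------
    gh_patients = [
        pid for pid in patient_ids
        if any(domain == _GLOBAL_HEALTH_DOMAIN for domain, _ in mentions[pid])
    ]
    states = _assign_categorical(
        rng, GLOBAL_HEALTH_PRIORITY, config.global_health_split,
        len(gh_patients),
        config.deterministic_margins or config.occurrence_vector is not None,
    )
    gh_state = dict(zip(gh_patients, states))
    for pid, state in gh_state.items():
        patients[pid] = replace(patients[pid], global_health_state=state)

    # -- posts --------------------------------------------------------------
    posts: list[Post] = []
    post_mentions: dict[str, list[str]] = {}
    pii: dict[str, list[tuple[str, str]]] = {}
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"post{serial:06d}"

    n_posts_each = _sample_truncated_geometric(
        rng, config.posts_per_patient_p, config.posts_per_patient_max, n
    )
    names = _default_names()
    for i, pid in enumerate(patient_ids):
        rec = patients[pid]
        k = int(n_posts_each[i])
        dates = sorted(_sample_date(rng, config.window) for _ in range(k))
        planted = sorted(sub_id for _domain, sub_id in mentions[pid])
        keyword_pool = [
            syn
            for key in _DRUG_TO_KEYWORD_KEYS[rec.drug]
            for syn in keywords.synonyms_for(key)
        ]
        for j in range(k):
            post_id = next_id()
            subs_here = planted[j::k]
            sentences = [str(rng.choice(np.array(_OPENERS, dtype=object)))]
            kw = str(rng.choice(np.array(keyword_pool, dtype=object)))
            sentences.append(f"le traitement {kw} continue a la semaine numero {serial}.")
            for sub_id in subs_here:
                phrase = str(rng.choice(np.array(lexicon.phrases[sub_id], dtype=object)))
                connector = str(rng.choice(np.array(_CONNECTORS, dtype=object)))
                sentences.append(f"{connector} {phrase}.")
                if sub_index[sub_id].domain == _GLOBAL_HEALTH_DOMAIN:
                    pol = str(
                        rng.choice(np.array(polarity.phrases[gh_state[pid]], dtype=object))
                    )
                    sentences.append(f"pour tout dire {pol}.")
            if rng.random() < config.pii_rate:
                sentence, planted_pii = _make_pii(rng, rec.alias, names)
                sentences.append(sentence)
                pii[post_id] = [planted_pii]
            source = str(rng.choice(np.array(_SOURCES, dtype=object)))
            posts.append(
                Post(
                    post_id=post_id,
                    source=source,
                    url=f"https://{source}.example/fil/{rec.alias}/{post_id}",
                    date=dates[j],
                    alias=rec.alias,
                    text=" ".join(sentences),
                )
            )
            post_mentions[post_id] = subs_here

    # -- cross-source duplicates -------------------------------------------
    duplicates: dict[str, str] = {}
    max_date = config.window[1] - dt.timedelta(days=1)
    for orig in list(posts):
        if rng.random() < config.duplicate_rate:
            dup_id = next_id()
            other_sources = [s for s in _SOURCES if s != orig.source]
            source = str(rng.choice(np.array(other_sources, dtype=object)))
            date = min(orig.date + dt.timedelta(days=int(rng.integers(1, 31))), max_date)
            posts.append(
                Post(
                    post_id=dup_id,
                    source=source,
                    url=f"https://{source}.example/fil/{orig.alias}/{dup_id}",
                    date=date,
                    alias=orig.alias,
                    text=orig.text,
                )
            )
            duplicates[dup_id] = orig.post_id
            post_mentions[dup_id] = post_mentions[orig.post_id]

    # -- decoys (no ICI keyword) -------------------------------------------
    decoys: set[str] = set()
    n_base = len(posts)
    n_decoys = int(round(n_base * config.decoy_rate / (1.0 - config.decoy_rate)))
    for d in range(n_decoys):
        post_id = next_id()
        body = str(rng.choice(np.array(_DECOY_BODIES, dtype=object)))
        source = str(rng.choice(np.array(_SOURCES, dtype=object)))
        alias = f"visiteur_{d + 1:04d}"
        posts.append(
            Post(
                post_id=post_id,
                source=source,
                url=f"https://{source}.example/fil/{alias}/{post_id}",
                date=_sample_date(rng, config.window),
                alias=alias,
                text=f"{body} numero {serial}.",
            )
        )
        decoys.add(post_id)
        post_mentions[post_id] = []

    truth = GroundTruth(
        patients=patients,
        mentions=mentions,
        post_mentions=post_mentions,
        pii=pii,
        duplicates=duplicates,
        decoys=decoys,
    )
    return posts, truth


def _default_names() -> tuple[str, ...]:
    from .corpus import _default_name_dictionary

    return _default_name_dictionary()


def _make_pii(
    rng: np.random.Generator, alias: str, names: Sequence[str]
) -> tuple[str, tuple[str, str]]:
    cls = str(rng.choice(np.array(("phone", "postal", "email", "name"), dtype=object)))
    if cls == "phone":
        digits = rng.integers(0, 10, size=8)
        head = int(rng.choice([6, 7]))
        number = f"0{head} " + " ".join(
            f"{digits[k]}{digits[k + 1]}" for k in range(0, 8, 2)
        )
        return f"vous pouvez me joindre au {number}.", ("phone", number)
    if cls == "postal":
        code = f"{int(rng.integers(1, 96)):02d}{int(rng.integers(0, 1000)):03d}"
        city = str(rng.choice(np.array(_CITIES, dtype=object)))
        return f"nous habitons vers {city} {code}.", ("postal", code)
    if cls == "email":
        address = f"{alias.replace('_', '')}@exemple.fr"
        return f"mon adresse {address} pour echanger.", ("email", address)
    name = str(rng.choice(np.array(names, dtype=object)))
    return f"je remercie le Dr {name} pour son suivi.", ("name", name)
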