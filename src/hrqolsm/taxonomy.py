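"""HRQoL taxonomy, questionnaire structures and the concept-map fixture.

The taxonomy is a two-level classification induced from patient posts:
8 domains (Global health, Symptoms, Emotional state, Role, Physical activity,
Professional situation, Cognitive state, Social state) refined into 42
subdomains.  Each subdomain carries its occurrence count — the number of
distinct patients who mentioned it — and the concept map records, per
standard questionnaire (EORTC QLQ-C30, FACT-G), which items measure it; an
empty item set means the subdomain is not covered by that instrument.

Item identifiers are opaque strings exactly as printed on the instruments
("Q29", "GF7"); item wording and scoring are out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import TaxonomyError

__all__ = [
    "DOMAINS",
    "Subdomain",
    "Instrument",
    "ConceptMap",
    "QLQ_C30",
    "FACT_G",
    "INSTRUMENTS",
    "load_taxonomy",
    "save_taxonomy",
    "default_taxonomy_path",
    "load_table1_margins",
]

#: The eight HRQoL domains, in the presentation order of the coverage tables.
DOMAINS: tuple[str, ...] = (
    "Global health",
    "Symptoms",
    "Emotional state",
    "Role",
    "Physical activity",
    "Professional situation",
    "Cognitive state",
    "Social state",
)


@dataclass(frozen=True)
class Subdomain:
    """One taxonomy leaf: a patient-expressed HRQoL concept."""

    id: str
    label: str
    domain: str
    occurrences: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise TaxonomyError(f"unknown domain label {self.domain!r} for subdomain {self.id!r}")
        if self.occurrences < 0:
            raise TaxonomyError(f"negative occurrence count for subdomain {self.id!r}")


@dataclass(frozen=True)
class Instrument:
    """A standard HRQoL questionnaire: name plus its ordered item identifiers."""

    name: str
    items: tuple[str, ...]

    def __contains__(self, item: str) -> bool:
        return item in self.items


QLQ_C30 = Instrument("EORTC-QLQ-C30", tuple(f"Q{i}" for i in range(1, 31)))
FACT_G = Instrument(
    "FACT-G",
    tuple(f"GP{i}" for i in range(1, 8))
    + tuple(f"GS{i}" for i in range(1, 8))
    + tuple(f"GE{i}" for i in range(1, 7))
    + tuple(f"GF{i}" for i in range(1, 8)),
)
INSTRUMENTS: dict[str, Instrument] = {ins.name: ins for ins in (QLQ_C30, FACT_G)}


class ConceptMap:
    """subdomain id -> {instrument name -> frozenset of covering item ids}.

    Coverage is binary per (subdomain, instrument): covered iff the item set
    is non-empty.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Iterable[str]]]):
        self.entries: dict[str, dict[str, frozenset[str]]] = {
            sub: {ins: frozenset(items) for ins, items in per_ins.items()}
            for sub, per_ins in entries.items()
        }
        for sub, per_ins in self.entries.items():
            for ins_name, items in per_ins.items():
                if ins_name not in INSTRUMENTS:
                    raise TaxonomyError(f"unknown instrument {ins_name!r} in concept map")
                bad = items - set(INSTRUMENTS[ins_name].items)
                if bad:
                    raise TaxonomyError(
                        f"subdomain {sub!r}: items {sorted(bad)} do not exist in {ins_name}"
                    )

    def items_for(self, subdomain_id: str, instrument: str) -> frozenset[str]:
        return self.entries[subdomain_id][instrument]

    def covers(self, subdomain_id: str, instrument: str) -> bool:
        return bool(self.entries[subdomain_id][instrument])

    def __contains__(self, subdomain_id: str) -> bool:
        return subdomain_id in self.entries

    def __eq__(self, other) -> bool:
        return isinstance(other, ConceptMap) and self.entries == other.entries


_REQUIRED_COLUMNS = (
    "subdomain_id",
    "label",
    "domain",
    "occurrences",
    "qlq_c30_items",
    "fact_g_items",
)
_COLUMN_TO_INSTRUMENT = {"qlq_c30_items": QLQ_C30.name, "fact_g_items": FACT_G.name}


def default_taxonomy_path() -> Path:
    ref = resources.files("hrqolsm.data").joinpath("table3_conceptmap.csv")
    with resources.as_file(ref) as path:
        return Path(path)


def load_taxonomy(path: str | Path | None = None) -> tuple[list[Subdomain], ConceptMap]:
    """Load the subdomain table and concept map from a CSV fixture.

    One row per subdomain; item sets are semicolon-delimited and may be
    empty (= not covered).  Defaults to the packaged transcription of the
    published coverage table.
    """
    path = default_taxonomy_path() if path is None else Path(path)
    subdomains: list[Subdomain] = []
    entries: dict[str, dict[str, set[str]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise TaxonomyError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sub_id = (row["subdomain_id"] or "").strip()
            if not sub_id:
                raise TaxonomyError(f"{path}:{lineno}: empty subdomain id")
            if sub_id in entries:
                raise TaxonomyError(f"{path}:{lineno}: duplicate subdomain id {sub_id!r}")
            try:
                occurrences = int(row["occurrences"])
            except (TypeError, ValueError) as exc:
                raise TaxonomyError(
                    f"{path}:{lineno}: non-integer occurrence count {row['occurrences']!r}"
                ) from exc
            try:
                sub = Subdomain(sub_id, row["label"].strip(), row["domain"].strip(), occurrences)
            except TaxonomyError as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from exc
            subdomains.append(sub)
            entries[sub_id] = {
                ins: {it.strip() for it in (row[col] or "").split(";") if it.strip()}
                for col, ins in _COLUMN_TO_INSTRUMENT.items()
            }
    try:
        cmap = ConceptMap(entries)
    except TaxonomyError as exc:
        raise TaxonomyError(f"{path}: {exc}") from exc
    return subdomains, cmap


def save_taxonomy(subdomains: Iterable[Subdomain], concept_map: ConceptMap, path: str | Path) -> None:
    """Serialize to the same CSV schema that :func:`load_taxonomy` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for sub in subdomains:
            per_ins = concept_map.entries[sub.id]
            writer.writerow(
                [
                    sub.id,
                    sub.label,
                    sub.domain,
                    sub.occurrences,
                    ";".join(sorted(per_ins[QLQ_C30.name], key=_item_sort_key)),
                    ";".join(sorted(per_ins[FACT_G.name], key=_item_sort_key)),
                ]
            )


def _item_sort_key(item: str):
    head = item.rstrip("0123456789")
    tail = item[len(head):]
    return (head, int(tail) if tail else 0)


def occurrence_vector(subdomains: Iterable[Subdomain]) -> dict[str, int]:
    """Subdomain id -> occurrence count, as recorded in the fixture."""
    return {sub.id: sub.occurrences for sub in subdomains}


def load_table1_margins(path: str | Path | None = None) -> dict[str, dict[str, tuple[int, float]]]:
    """Cohort margins fixture: variable -> level -> (count, percent)."""
    if path is None:
        ref = resources.files("hrqolsm.data").joinpath("table1_margins.csv")
        with resources.as_file(ref) as p:
            path = Path(p)
    margins: dict[str, dict[str, tuple[int, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            margins.setdefault(row["variable"], {})[row["level"]] = (
                int(row["count"]),
                float(row["percent"]),
            )
    return margins
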