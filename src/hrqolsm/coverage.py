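"""Concept-mapping coverage statistics.

For a domain D and an instrument I, the occurrence-weighted coverage rate is

    rate(D, I) = sum of occurrences of D's subdomains covered by I
                 ----------------------------------------------------
                 total occurrences of D's subdomains

where "covered" means the concept map assigns the subdomain a non-empty item
set for I, and an occurrence is one distinct patient mentioning the
subdomain.  Rates are carried as exact integer fractions; percentages are
rounded (half-up, one decimal) only at presentation.

Global subdomain coverage per instrument is the plain count of covered
subdomains out of all taxonomy subdomains (k/42 on the packaged fixture).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CoverageError
from .taxonomy import DOMAINS, INSTRUMENTS, ConceptMap, Subdomain

__all__ = [
    "DomainCoverage",
    "CoverageReport",
    "compute_domain_coverage",
    "compute_subdomain_coverage",
    "coverage_report",
    "round_pct",
]


def round_pct(rate: Fraction) -> float:
    """Percentage with one decimal, ties rounded half-up (printed style)."""
    pct = Decimal(rate.numerator * 100) / Decimal(rate.denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DomainCoverage:
    domain: str
    instrument: str
    covered: int
    total: int

    @property
    def rate(self) -> Fraction:
        return Fraction(self.covered, self.total)

    @property
    def pct(self) -> float:
        return round_pct(self.rate)


def _check_inputs(
    occurrences: Mapping[str, int],
    concept_map: ConceptMap,
    subdomains: Sequence[Subdomain],
) -> None:
    known = {sub.id for sub in subdomains}
    stray = set(occurrences) - known
    if stray:
        raise CoverageError(f"occurrence table names unknown subdomain(s): {sorted(stray)}")
    unmapped = known - set(concept_map.entries)
    if unmapped:
        raise CoverageError(f"concept map lacks entries for subdomain(s): {sorted(unmapped)}")


def compute_domain_coverage(
    occurrences: Mapping[str, int],
    concept_map: ConceptMap,
    subdomains: Sequence[Subdomain],
    domain: str,
    instrument: str,
) -> DomainCoverage:
    """Occurrence-weighted coverage of one domain by one instrument."""
    if domain not in DOMAINS:
        raise CoverageError(f"unknown domain {domain!r}")
    if instrument not in INSTRUMENTS:
        raise CoverageError(f"unknown instrument {instrument!r}")
    _check_inputs(occurrences, concept_map, subdomains)
    covered = total = 0
    for sub in subdomains:
        if sub.domain != domain:
            continue
        n = int(occurrences.get(sub.id, 0))
        total += n
        if concept_map.covers(sub.id, instrument):
            covered += n
    if total == 0:
        raise CoverageError(f"domain {domain!r} has zero occurrences; its rate is undefined")
    return DomainCoverage(domain, instrument, covered, total)


def compute_subdomain_coverage(
    concept_map: ConceptMap,
    subdomains: Sequence[Subdomain],
    instrument: str,
) -> tuple[int, int]:
    """(covered subdomain count, total subdomain count) for one instrument."""
    if instrument not in INSTRUMENTS:
        raise CoverageError(f"unknown instrument {instrument!r}")
    covered = sum(1 for sub in subdomains if concept_map.covers(sub.id, instrument))
    return covered, len(list(subdomains))


@dataclass
class CoverageReport:
    """All domains × all instruments, plus per-instrument global coverage."""

    domains: list[DomainCoverage]
    subdomain_coverage: dict[str, tuple[int, int]]
    zero_occurrence_domains: list[str]

    def get(self, domain: str, instrument: str) -> DomainCoverage:
        for cov in self.domains:
            if cov.domain == domain and cov.instrument == instrument:
                return cov
        raise KeyError((domain, instrument))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain": c.domain,
                    "instrument": c.instrument,
                    "covered_occurrences": c.covered,
                    "total_occurrences": c.total,
                    "rate": f"{c.covered}/{c.total}",
                    "pct": c.pct,
                }
                for c in self.domains
            ]
        )

    def to_dict(self) -> dict:
        return {
            "domains": [
                {
                    "domain": c.domain,
                    "instrument": c.instrument,
                    "covered_occurrences": c.covered,
                    "total_occurrences": c.total,
                    "pct": c.pct,
                }
                for c in self.domains
            ],
            "subdomain_coverage": {
                ins: {"covered": k, "total": m}
                for ins, (k, m) in self.subdomain_coverage.items()
            },
            "zero_occurrence_domains": list(self.zero_occurrence_domains),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CoverageReport)
            and self.domains == other.domains
            and self.subdomain_coverage == other.subdomain_coverage
            and sorted(self.zero_occurrence_domains) == sorted(other.zero_occurrence_domains)
        )


def coverage_report(
    occurrences: Mapping[str, int],
    concept_map: ConceptMap,
    subdomains: Sequence[Subdomain],
    instruments: Iterable[str] = tuple(INSTRUMENTS),
) -> CoverageReport:
    """Full coverage report; zero-occurrence domains are flagged, not dropped."""
    _check_inputs(occurrences, concept_map, subdomains)
    present_domains = [d for d in DOMAINS if any(s.domain == d for s in subdomains)]
    totals = {
        d: sum(int(occurrences.get(s.id, 0)) for s in subdomains if s.domain == d)
        for d in present_domains
    }
    zero = [d for d in present_domains if totals[d] == 0]
    rows = [
        compute_domain_coverage(occurrences, concept_map, subdomains, d, ins)
        for d in present_domains
        if totals[d] > 0
        for ins in instruments
    ]
    sub_cov = {
        ins: compute_subdomain_coverage(concept_map, subdomains, ins) for ins in instruments
    }
    return CoverageReport(rows, sub_cov, zero)
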