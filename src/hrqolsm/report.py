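"""Frequentist cohort summaries and the domain co-occurrence (Venn) partition."""

from __future__ import annotations

import statistics
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import MentionRecord, PatientRecord
from .corpus import Post
from .coverage import round_pct
from .taxonomy import DOMAINS

from fractions import Fraction

__all__ = ["frequency_summary", "venn_partition", "venn_table", "plot_venn", "keyword_trend"]


def _split_pct(counter: Counter, total: int) -> dict[str, dict[str, float | int]]:
    return {
        level: {"n": n, "pct": round_pct(Fraction(n, total)) if total else 0.0}
        for level, n in sorted(counter.items())
    }


def frequency_summary(
    patients: Sequence[PatientRecord],
    posts: Sequence[Post],
    mentions: Sequence[MentionRecord],
    matched_keywords: Mapping[str, str] | None = None,
) -> dict:
    """Descriptive indicators of the analysis corpus.

    Per-domain percentages use, as denominator, the number of patients
    mentioning at least one domain (the presentation style of the source
    cohort description).
    """
    n_patients = len(patients)
    posts_per_patient = Counter(p.alias for p in posts)
    per_patient_counts = sorted(posts_per_patient.values())
    domain_patients: dict[str, set[str]] = {d: set() for d in DOMAINS}
    for m in mentions:
        domain_patients[m.domain].add(m.patient_id)
    mentioners = set().union(*domain_patients.values()) if mentions else set()
    denom = len(mentioners)

    summary = {
        "n_posts": len(posts),
        "n_patients": n_patients,
        "posts_per_patient": {
            "median": statistics.median(per_patient_counts) if per_patient_counts else 0,
            "min": per_patient_counts[0] if per_patient_counts else 0,
            "max": per_patient_counts[-1] if per_patient_counts else 0,
        },
        "reporter": _split_pct(Counter(p.reporter for p in patients), n_patients),
        "gender": _split_pct(Counter(p.gender for p in patients), n_patients),
        "cancer": _split_pct(Counter(p.cancer for p in patients), n_patients),
        "drug": _split_pct(Counter(p.drug for p in patients), n_patients),
        "sources": dict(sorted(Counter(p.source for p in posts).items())),
        "patients_with_domain": denom,
        "domains": {
            d: {
                "n": len(domain_patients[d]),
                "pct": round_pct(Fraction(len(domain_patients[d]), denom)) if denom else 0.0,
            }
            for d in DOMAINS
        },
        "global_health_state": dict(
            sorted(
                Counter(
                    p.global_health_state for p in patients if p.global_health_state
                ).items()
            )
        ),
    }
    if matched_keywords is not None:
        summary["keywords"] = dict(sorted(Counter(matched_keywords.values()).items()))
    return summary


def venn_partition(mentions: Iterable[MentionRecord]) -> dict[frozenset, int]:
    """Exact partition: domain subset -> number of patients mentioning exactly it.

    Only non-empty subsets appear; counts sum to the number of patients with
    at least one domain mention.
    """
    per_patient: dict[str, set[str]] = {}
    for m in mentions:
        per_patient.setdefault(m.patient_id, set()).add(m.domain)
    partition: Counter = Counter(frozenset(domains) for domains in per_patient.values())
    return dict(partition)


def venn_table(partition: Mapping[frozenset, int]) -> pd.DataFrame:
    rows = [
        {"domains": " & ".join(sorted(subset)), "size": len(subset), "patients": count}
        for subset, count in partition.items()
    ]
    return (
        pd.DataFrame(rows, columns=["domains", "size", "patients"])
        .sort_values(["size", "patients", "domains"], ascending=[True, False, True])
        .reset_index(drop=True)
    )


def plot_venn(partition: Mapping[frozenset, int], path: str | Path, max_sets: int = 3) -> pd.DataFrame:
    """Draw a circle diagram for the most frequent domains (≤3 sets).

    Domains beyond ``max_sets`` cannot be displayed faithfully as circles;
    they are collapsed into the returned remainder table (which always holds
    the complete partition).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    marginals: Counter = Counter()
    for subset, count in partition.items():
        for domain in subset:
            marginals[domain] += count
    top = [d for d, _ in sorted(marginals.items(), key=lambda kv: (-kv[1], kv[0]))[:max_sets]]

    region: Counter = Counter()
    for subset, count in partition.items():
        region[frozenset(subset & set(top))] += count

    centers = {1: [(0.5, 0.5)], 2: [(0.38, 0.5), (0.62, 0.5)], 3: [(0.38, 0.58), (0.62, 0.58), (0.5, 0.36)]}
    fig, ax = plt.subplots(figsize=(6, 6))
    pts = centers.get(len(top), [(0.5, 0.5)])
    for domain, (x, y) in zip(top, pts):
        ax.add_patch(Circle((x, y), 0.26, alpha=0.3))
        ax.annotate(domain, (x, y + 0.28), ha="center", fontsize=9)
    for subset, count in region.items():
        if not subset:
            continue
        xs = [pts[top.index(d)][0] for d in subset]
        ys = [pts[top.index(d)][1] for d in subset]
        ax.annotate(str(count), (sum(xs) / len(xs), sum(ys) / len(ys)), ha="center", fontsize=11)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, format=str(path).rsplit(".", 1)[-1])
    plt.close(fig)
    return venn_table(partition)


def keyword_trend(posts: Sequence[Post], matched_keywords: Mapping[str, str]) -> pd.DataFrame:
    """Per-year matched-keyword counts (descriptive; no reference values exist)."""
    rows = [
        {"year": p.date.year, "keyword": matched_keywords[p.post_id]}
        for p in posts
        if p.post_id in matched_keywords
    ]
    if not rows:
        return pd.DataFrame(columns=["year", "keyword", "posts"])
    df = pd.DataFrame(rows)
    return df.value_counts(["year", "keyword"]).rename("posts").reset_index().sort_values(
        ["year", "keyword"]
    ).reset_index(drop=True)
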