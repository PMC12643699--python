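"""Summary surfaces: demographics, yearly trends, rankings, overlaps.

These functions produce the tabular outputs a pharmacovigilance study
reports: per-drug clinical characteristics (sex/age/weight bins with
percentages, top indications and countries), yearly report counts, top-N
event rankings by report count, cross-drug overlap of qualifying PT
signals, and candidate-novel flagging against a user-supplied list of
labeled events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from phytovigil.etl import CaseReport

#: age bin edges and labels; 18 and 65 fall in "18-65", 85 in "65-85"
AGE_BINS = [
    ("<18", lambda a: a < 18),
    ("18-65", lambda a: 18 <= a <= 65),
    ("65-85", lambda a: 65 < a <= 85),
    (">85", lambda a: a > 85),
]

WEIGHT_BINS = [
    ("<50", lambda w: w < 50),
    ("50-69", lambda w: 50 <= w < 70),
    ("70-89", lambda w: 70 <= w < 90),
    (">=90", lambda w: w >= 90),
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, rounded half-up."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class DemographicSummary:
    drug: str
    total: int
    sex: dict[str, tuple[int, float]]
    age_bins: dict[str, tuple[int, float]]
    age_median: Optional[float]
    age_iqr: Optional[tuple[float, float]]
    weight_bins: dict[str, tuple[int, float]]
    top_indications: list[tuple[str, int, float]]
    top_countries: list[tuple[str, int, float]]
    yearly: dict[int, int] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "total": self.total,
            "sex": {k: list(v) for k, v in self.sex.items()},
            "age_bins": {k: list(v) for k, v in self.age_bins.items()},
            "age_median": self.age_median,
            "age_iqr": list(self.age_iqr) if self.age_iqr else None,
            "weight_bins": {k: list(v) for k, v in self.weight_bins.items()},
            "top_indications": [list(t) for t in self.top_indications],
            "top_countries": [list(t) for t in self.top_countries],
            "yearly": {str(k): v for k, v in sorted(self.yearly.items())},
            "metadata": self.metadata,
        }


def demographic_summary(
    reports: Sequence[CaseReport],
    drug: str,
    top_k: int = 5,
    sex_decimals: int = 1,
    age_decimals: int = 1,
    weight_decimals: int = 2,
) -> DemographicSummary:
    """Per-drug clinical characteristics table.

    ``drug`` must appear as a suspect drug in at least one report unless the
    drug universe declares it; an unknown drug (never seen at all) raises.
    Indication and country percentages use the drug's total report count as
    denominator, stated in the output metadata.
    """
    sub = [r for r in reports if drug in r.suspect_drugs()]
    if not sub and not any(
        drug in {d.standard_name for d in r.drugs} for r in reports
    ):
        raise ValueError(f"unknown drug {drug!r}")
    total = len(sub)

    sex_counts = {"F": 0, "M": 0, "missing": 0}
    for r in sub:
        sex_counts[r.sex if r.sex in ("F", "M") else "missing"] += 1
    sex = {k: (v, percentage(v, total, sex_decimals)) for k, v in sex_counts.items()}

    ages = [r.age_years for r in sub if r.age_years is not None]
    age_counts = {label: 0 for label, _ in AGE_BINS}
    for a in ages:
        for label, pred in AGE_BINS:
            if pred(a):
                age_counts[label] += 1
                break
    age_counts["missing"] = total - len(ages)
    age_bins = {
        k: (v, percentage(v, total, age_decimals)) for k, v in age_counts.items()
    }
    if ages:
        q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
        age_median, age_iqr = float(med), (float(q1), float(q3))
    else:
        age_median, age_iqr = None, None

    weights = [r.weight_kg for r in sub if r.weight_kg is not None]
    weight_counts = {label: 0 for label, _ in WEIGHT_BINS}
    for w in weights:
        for label, pred in WEIGHT_BINS:
            if pred(w):
                weight_counts[label] += 1
                break
    weight_counts["missing"] = total - len(weights)
    weight_bins = {
        k: (v, percentage(v, total, weight_decimals)) for k, v in weight_counts.items()
    }

    def top_of(values: Iterable[str]) -> list[tuple[str, int, float]]:
        counts: dict[str, int] = {}
        for v in values:
            if v:
                counts[v] = counts.get(v, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        return [(k, n, percentage(n, total, sex_decimals)) for k, n in ranked]

    top_ind = top_of(ind for r in sub for ind in r.indications)
    top_cty = top_of(r.country for r in sub)

    return DemographicSummary(
        drug=drug,
        total=total,
        sex=sex,
        age_bins=age_bins,
        age_median=age_median,
        age_iqr=age_iqr,
        weight_bins=weight_bins,
        top_indications=top_ind,
        top_countries=top_cty,
        yearly=yearly_counts(reports, drug),
        metadata={
            "age_bin_rule": "18 and 65 -> '18-65'; 85 -> '65-85'",
            "percent_denominator": "per-drug total report count",
            "rounding": "half-up",
        },
    )


def yearly_counts(reports: Sequence[CaseReport], drug: str) -> dict[int, int]:
    """Report counts per FDA receipt year, zero-filled over the seen range."""
    years = [
        r.report_year
        for r in reports
        if drug in r.suspect_drugs() and r.report_year is not None
    ]
    if not years:
        return {}
    out = {y: 0 for y in range(min(years), max(years) + 1)}
    for y in years:
        out[y] += 1
    return out


def top_events(scores: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Top-n rows by report count a (descending), ties alphabetical by event."""
    ranked = scores.sort_values(
        ["a", "event"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)


@dataclass
class OverlapResult:
    qualifying: dict[str, set[str]]
    intersections: dict[str, int]  # "drugA&drugB[&drugC]" -> count
    union_count: int

    def to_dict(self) -> dict:
        return {
            "qualifying": {k: sorted(v) for k, v in self.qualifying.items()},
            "intersections": dict(sorted(self.intersections.items())),
            "union_count": self.union_count,
        }


def overlap_sets(
    per_drug_scores: Mapping[str, pd.DataFrame], min_count: int = 100
) -> OverlapResult:
    """Cross-drug overlap of PTs passing the ROR rule with >= min_count reports."""
    qualifying = {
        drug: set(df[(df["ror_pos"]) & (df["a"] >= min_count)]["event"])
        for drug, df in per_drug_scores.items()
    }
    inter: dict[str, int] = {}
    names = sorted(qualifying)
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            common = set.intersection(*(qualifying[d] for d in combo))
            inter["&".join(combo)] = len(common)
    union = set().union(*qualifying.values()) if qualifying else set()
    return OverlapResult(qualifying, inter, len(union))


def flag_candidate_novel(
    scores: pd.DataFrame, known_terms: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Mark signal-positive events absent from a known (labeled) term list.

    Without a list the flag column is emitted empty: novelty cannot be
    assessed against nothing.
    """
    out = scores.copy()
    if known_terms is None:
        out["candidate_novel"] = ""
        return out
    known = set(known_terms)
    out["candidate_novel"] = out["any_of_four"] & ~out["event"].isin(known)
    return out
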