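"""2x2 contingency tables for (drug, event) pairs.

Each deduplicated report is one statistical unit.  For a drug D and event
E at PT or SOC granularity:

    a = reports with D (suspect role) and E       b = with D, without E
    c = with E, without D                         d = with neither
    N = a + b + c + d = total reports

A report contributes at most once per pair: repeated PTs within a report,
or several PTs rolling up to one SOC, still count a single occurrence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from phytovigil.etl import CaseReport, MeddraDictionary, SUSPECT_ROLES


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    event: str
    granularity: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total


def build_pair_tables(
    reports: Sequence[CaseReport],
    target_drugs: Optional[Iterable[str]] = None,
    granularity: str = "PT",
    meddra: Optional[MeddraDictionary] = None,
    roles: frozenset[str] = SUSPECT_ROLES,
    exclude_drugs: Optional[Iterable[str]] = None,
    min_events: int = 0,
) -> list[ContingencyTable]:
    """Build one table per (drug, event) pair observed in ``reports``.

    Parameters
    ----------
    reports
        Deduplicated case reports.
    target_drugs
        Restrict the drug axis to these standardized names (default: every
        suspect drug seen).
    granularity
        "PT" scores preferred terms; "SOC" rolls each PT up to its primary
        SOC via ``meddra`` (required in that case).
    roles
        Drug roles counted as exposure (default primary + secondary
        suspect).
    exclude_drugs
        Reports whose suspect set intersects this list are removed from the
        comparator universe entirely.
    min_events
        Drop pairs with a < min_events after counting.
    """
    if granularity not in ("PT", "SOC"):
        raise ValueError(f"granularity must be PT or SOC, got {granularity!r}")
    if granularity == "SOC" and meddra is None:
        raise ValueError("SOC granularity requires a MedDRA dictionary")
    if not reports:
        raise ValueError("no reports")

    excluded = set(exclude_drugs) if exclude_drugs else set()
    pair_count: Counter[tuple[str, str]] = Counter()
    drug_count: Counter[str] = Counter()
    event_count: Counter[str] = Counter()
    n_total = 0
    for rep in reports:
        drugs = rep.suspect_drugs(roles)
        if excluded and drugs & excluded:
            continue
        n_total += 1
        if granularity == "PT":
            events = rep.reactions
        else:
            events = {meddra.soc_of(pt) for pt in rep.reactions}
        for d in drugs:
            drug_count[d] += 1
        for e in events:
            event_count[e] += 1
        for d in drugs:
            for e in events:
                pair_count[(d, e)] += 1

    if target_drugs is None:
        drug_axis = sorted(drug_count)
    else:
        drug_axis = list(target_drugs)

    tables: list[ContingencyTable] = []
    for d in drug_axis:
        nd = drug_count.get(d, 0)
        for e in sorted(event_count):
            a = pair_count.get((d, e), 0)
            if a < min_events:
                continue
            b = nd - a
            c = event_count[e] - a
            tables.append(
                ContingencyTable(
                    drug=d, event=e, granularity=granularity,
                    a=a, b=b, c=c, d=n_total - a - b - c,
                )
            )
    return tables


def tables_to_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    """Long-format frame: drug,event,granularity,a,b,c,d,N."""
    return pd.DataFrame(
        {
            "drug": [t.drug for t in tables],
            "event": [t.event for t in tables],
            "granularity": [t.granularity for t in tables],
            "a": [t.a for t in tables],
            "b": [t.b for t in tables],
            "c": [t.c for t in tables],
            "d": [t.d for t in tables],
            "N": [t.n_total for t in tables],
        }
    )


def frame_to_tables(frame: pd.DataFrame) -> list[ContingencyTable]:
    """Inverse of :func:`tables_to_frame`."""
    return [
        ContingencyTable(
            drug=row.drug, event=row.event, granularity=row.granularity,
            a=int(row.a), b=int(row.b), c=int(row.c), d=int(row.d),
        )
        for row in frame.itertuples(index=False)
    ]
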