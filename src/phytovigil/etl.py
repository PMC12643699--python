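"""FAERS quarterly ASCII ingestion: parsing, dedup, normalization, coding.

The FAERS public release ships dollar-delimited text tables.  This module
reads the five consumed here (DEMO, DRUG, REAC, THER, INDI), removes
duplicate versions of the same case (same ``caseid``), normalizes drug
names through a user-supplied synonym map, harmonizes age/weight units,
parses dates that may carry only year or year-month precision, and attaches
MedDRA primary SOCs to reaction PTs, yielding one :class:`CaseReport` per
unique case.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = {
    "DEMO": ["primaryid", "caseid"],
    "DRUG": ["primaryid", "drugname", "role_cod"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid"],
    "INDI": ["primaryid"],
}

#: conversion factors to years, keyed by FAERS age unit code
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.453592, "GMS": 1.0 / 1000.0}

SUSPECT_ROLES = frozenset({"PS", "SS"})


class SchemaError(ValueError):
    """A mandatory column is missing from a FAERS table."""


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known only to year or year-month precision."""

    year: int
    month: Optional[int] = None


@dataclass
class DrugEntry:
    raw_name: str
    standard_name: str
    role: str
    therapy_start: Optional[datetime.date] = None
    therapy_start_partial: Optional[PartialDate] = None


@dataclass
class CaseReport:
    """One deduplicated spontaneous report."""

    primaryid: str
    caseid: str
    sex: str  # "F", "M" or "" (missing)
    age_years: Optional[float]
    weight_kg: Optional[float]
    country: str
    event_date: Optional[datetime.date]
    event_date_partial: Optional[PartialDate]
    report_year: Optional[int]
    indications: set[str] = field(default_factory=set)
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)

    def suspect_drugs(self, roles: frozenset[str] = SUSPECT_ROLES) -> set[str]:
        """Standardized names of this report's suspect drugs."""
        return {d.standard_name for d in self.drugs if d.role in roles}


@dataclass
class MeddraDictionary:
    """PT -> primary SOC map (each PT has exactly one primary SOC)."""

    pt_to_soc: dict[str, str]
    version: str = "unversioned"

    @classmethod
    def from_table(cls, path: str | Path, version: str = "unversioned",
                   sep: str = "\t") -> "MeddraDictionary":
        tbl = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        pt_col, soc_col = tbl.columns[:2]
        return cls(dict(zip(tbl[pt_col], tbl[soc_col])), version=version)

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(pt, "UNMAPPED")


def read_faers_tables(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read dollar-delimited FAERS tables, checking mandatory columns.

    Parameters
    ----------
    paths
        Map of table name (DEMO, DRUG, REAC, THER, INDI) to file path.

    Raises
    ------
    SchemaError
        If a mandatory column is absent, named as ``TABLE.column``.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        tbl = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
        for col in MANDATORY_COLUMNS.get(name.upper(), []):
            if col not in tbl.columns:
                raise SchemaError(f"{name.upper()}.{col}")
        logger.info("%s: %d rows", name, len(tbl))
        tables[name.upper()] = tbl
    return tables


def parse_faers_date(
    raw: str,
) -> tuple[Optional[datetime.date], Optional[PartialDate]]:
    """Parse a FAERS date string (YYYYMMDD, YYYYMM or YYYY).

    Returns ``(full_date, None)`` for day precision, ``(None, PartialDate)``
    for partial precision, and ``(None, None)`` for missing/invalid input.
    """
    raw = (raw or "").strip()
    if not raw.isdigit():
        return None, None
    try:
        if len(raw) == 8:
            return datetime.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8])), None
        if len(raw) == 6:
            d = PartialDate(int(raw[:4]), int(raw[4:6]))
            if 1 <= d.month <= 12:
                return None, d
        if len(raw) == 4:
            return None, PartialDate(int(raw))
    except ValueError:
        pass
    return None, None


def deduplicate_cases(demo: pd.DataFrame, date_col: str = "fda_dt") -> set[str]:
    """Keep one primaryid per caseid: latest ``date_col``, ties to the
    numerically largest primaryid.

    Spontaneous-report databases accumulate follow-up versions of the same
    case; the most recent version is retained as the most complete one.
    """
    if demo.empty:
        return set()
    work = demo[["primaryid", "caseid"]].copy()
    date = demo[date_col] if date_col in demo.columns else ""
    work["date_key"] = pd.Series(date, index=demo.index).fillna("").str.pad(
        8, side="right", fillchar="0"
    )
    work["pid_key"] = pd.to_numeric(work["primaryid"], errors="coerce").fillna(-1)
    work = work.sort_values(["caseid", "date_key", "pid_key"], kind="mergesort")
    kept = work.groupby("caseid", sort=False).tail(1)
    n_removed = len(demo) - len(kept)
    if n_removed:
        logger.info("deduplicate_cases: removed %d duplicate rows", n_removed)
    return set(kept["primaryid"])


def normalize_drug_name(
    raw: str,
    synonym_map: Mapping[str, str],
    counters: Optional[dict[str, int]] = None,
) -> str:
    """Case-fold and whitespace-collapse ``raw``, then look it up.

    Unmapped names pass through case-folded; the ``unmapped`` counter is
    incremented when ``counters`` is supplied.
    """
    key = " ".join(raw.casefold().split())
    if key in synonym_map:
        return synonym_map[key]
    if counters is not None:
        counters["unmapped"] = counters.get("unmapped", 0) + 1
    return key


def harmonize_age(
    value: float | str | None,
    unit: str,
    counters: Optional[dict[str, int]] = None,
) -> Optional[float]:
    """Convert an (age value, FAERS unit code) pair to years.

    Unknown units and out-of-range results (< 0 or >= 150 years) map to
    missing, with a warning counter incremented.
    """
    def warn(reason: str) -> None:
        if counters is not None:
            counters[reason] = counters.get(reason, 0) + 1

    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    unit = (unit or "").strip().upper()
    if unit not in AGE_UNIT_TO_YEARS:
        warn("age_unknown_unit")
        return None
    years = v * AGE_UNIT_TO_YEARS[unit]
    if years < 0 or years >= 150:
        warn("age_out_of_range")
        return None
    return years


def harmonize_weight(
    value: float | str | None,
    unit: str,
    counters: Optional[dict[str, int]] = None,
) -> Optional[float]:
    """Convert a (weight value, FAERS unit code) pair to kilograms."""
    def warn(reason: str) -> None:
        if counters is not None:
            counters[reason] = counters.get(reason, 0) + 1

    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    unit = (unit or "").strip().upper()
    if unit not in WEIGHT_UNIT_TO_KG:
        warn("weight_unknown_unit")
        return None
    kg = v * WEIGHT_UNIT_TO_KG[unit]
    if kg <= 0 or kg >= 500:
        warn("weight_out_of_range")
        return None
    return kg


def attach_meddra(
    reactions: Iterable[str],
    meddra: MeddraDictionary,
    counters: Optional[dict[str, int]] = None,
) -> set[tuple[str, str]]:
    """Tag each reaction PT with its primary SOC ("UNMAPPED" if unknown)."""
    out = set()
    for pt in reactions:
        soc = meddra.soc_of(pt)
        if soc == "UNMAPPED" and counters is not None:
            counters["unmapped_pt"] = counters.get("unmapped_pt", 0) + 1
        out.add((pt, soc))
    return out


def build_case_reports(
    raw_tables: Mapping[str, pd.DataFrame],
    synonym_map: Mapping[str, str],
    meddra: Optional[MeddraDictionary] = None,
    stats: Optional[dict[str, int]] = None,
) -> list[CaseReport]:
    """Assemble deduplicated :class:`CaseReport` records from raw tables.

    Cases are deduplicated first; DRUG/REAC/THER/INDI rows are then joined
    to the kept primaryids.  Child rows referencing unknown primaryids are
    dropped (counted in ``stats`` under ``*_orphan``).  ``meddra`` is not
    consulted here beyond validation -- SOC rollup happens at contingency
    time -- but passing it lets the unmapped-PT tally be collected early.
    """
    if stats is None:
        stats = {}
    demo = raw_tables["DEMO"]
    kept = deduplicate_cases(demo)
    stats["demo_rows"] = len(demo)
    stats["unique_cases"] = len(kept)

    demo_kept = demo[demo["primaryid"].isin(kept)]

    def grouped(name: str) -> dict[str, pd.DataFrame]:
        tbl = raw_tables.get(name)
        if tbl is None or tbl.empty:
            return {}
        mask = tbl["primaryid"].isin(kept)
        n_orphan = int((~tbl["primaryid"].isin(set(demo["primaryid"]))).sum())
        if n_orphan:
            stats[f"{name.lower()}_orphan"] = n_orphan
            logger.warning("%s: dropped %d rows with unknown primaryid",
                           name, n_orphan)
        return {pid: grp for pid, grp in tbl[mask].groupby("primaryid", sort=False)}

    drug_by_pid = grouped("DRUG")
    reac_by_pid = grouped("REAC")
    ther_by_pid = grouped("THER")
    indi_by_pid = grouped("INDI")

    reports: list[CaseReport] = []
    for row in demo_kept.itertuples(index=False):
        rowd = row._asdict()
        pid = rowd["primaryid"]
        sex = (rowd.get("sex") or "").strip().upper()
        if sex not in ("F", "M"):
            sex = ""
        age = harmonize_age(rowd.get("age"), rowd.get("age_cod", ""), stats) \
            if (rowd.get("age") or "").strip() else None
        weight = harmonize_weight(rowd.get("wt"), rowd.get("wt_cod", ""), stats) \
            if (rowd.get("wt") or "").strip() else None
        event_date, event_partial = parse_faers_date(rowd.get("event_dt", ""))
        fda_date, fda_partial = parse_faers_date(rowd.get("fda_dt", ""))
        report_year = fda_date.year if fda_date else (
            fda_partial.year if fda_partial else None
        )

        # therapy starts keyed by drug sequence number
        starts: dict[str, tuple[Optional[datetime.date], Optional[PartialDate]]] = {}
        ther = ther_by_pid.get(pid)
        if ther is not None and "dsg_drug_seq" in ther.columns:
            for trow in ther.itertuples(index=False):
                td = trow._asdict()
                full, part = parse_faers_date(td.get("start_dt", ""))
                seq = td["dsg_drug_seq"]
                prev = starts.get(seq)
                # earliest full-precision start wins per drug episode
                if prev is None or (prev[0] is None and full is not None) or (
                    full is not None and prev[0] is not None and full < prev[0]
                ):
                    starts[seq] = (full, part)

        drugs: list[DrugEntry] = []
        dtable = drug_by_pid.get(pid)
        if dtable is not None:
            for drow in dtable.itertuples(index=False):
                dd = drow._asdict()
                raw = dd.get("drugname", "")
                start_full, start_part = starts.get(dd.get("drug_seq", ""), (None, None))
                drugs.append(
                    DrugEntry(
                        raw_name=raw,
                        standard_name=normalize_drug_name(raw, synonym_map, stats),
                        role=(dd.get("role_cod") or "").strip().upper(),
                        therapy_start=start_full,
                        therapy_start_partial=start_part,
                    )
                )

        reactions: set[str] = set()
        rtable = reac_by_pid.get(pid)
        if rtable is not None:
            reactions = set(rtable["pt"])

        indications: set[str] = set()
        itable = indi_by_pid.get(pid)
        if itable is not None and "indi_pt" in itable.columns:
            indications = set(itable["indi_pt"])

        reports.append(
            CaseReport(
                primaryid=pid,
                caseid=rowd["caseid"],
                sex=sex,
                age_years=age,
                weight_kg=weight,
                country=(rowd.get("occr_country") or "").strip(),
                event_date=event_date,
                event_date_partial=event_partial,
                report_year=report_year,
                indications=indications,
                drugs=drugs,
                reactions=reactions,
            )
        )
    if meddra is not None:
        for rep in reports:
            attach_meddra(rep.reactions, meddra, stats)
    return reports
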