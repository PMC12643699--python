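"""Synthetic FAERS-style dataset generator with a ground-truth manifest.

Emulates the structure of spontaneous adverse-event reporting data: each
report carries a set of suspect drugs, a set of reaction preferred terms
(PTs) whose per-pair reporting rate is the event's background probability
times a planted relative rate, demographic fields with FAERS unit codes,
calendar dates with optional partial precision, duplicate case versions,
and Weibull-distributed onset times per drug.  The five quarterly ASCII
tables (DEMO, DRUG, REAC, THER, INDI) are produced in the dollar-delimited
dialect consumed by :mod:`phytovigil.etl`, alongside a manifest recording
every planted quantity so downstream estimates can be checked against
truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

_EPOCH = np.datetime64("1970-01-01")


class DrugSpec(BaseModel):
    """One drug in the simulated universe."""

    name: str
    exposure_prob: float = Field(gt=0.0, le=1.0)
    indications: dict[str, float] = Field(
        default_factory=lambda: {"Product used for unknown indication": 1.0}
    )

    @field_validator("indications")
    @classmethod
    def _positive_weights(cls, v: dict[str, float]) -> dict[str, float]:
        if not v or any(w <= 0 for w in v.values()):
            raise ValueError("indications: weights must be positive and non-empty")
        return v


class EventSpec(BaseModel):
    """One MedDRA preferred term with its primary SOC and background rate."""

    pt: str
    soc: str
    background_prob: float = Field(gt=0.0, le=1.0)


class PlantedSignal(BaseModel):
    """A (drug, PT) pair whose reporting rate is multiplied by relative_rate."""

    drug: str
    pt: str
    relative_rate: float = Field(ge=0.0)


class WeibullParams(BaseModel):
    """Two-parameter Weibull for a drug's time-to-onset, in days."""

    shape: float = Field(gt=0.0)  # beta
    scale: float = Field(gt=0.0)  # alpha, days


class DemographicMixtures(BaseModel):
    """Marginal distributions for the DEMO fields."""

    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.5, "M": 0.4, "": 0.1}
    )
    age_mean: float = 55.0
    age_sd: float = 18.0
    age_missing_prob: float = Field(default=0.2, ge=0.0, lt=1.0)
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    weight_missing_prob: float = Field(default=0.55, ge=0.0, lt=1.0)
    country_probs: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.4, "FR": 0.15, "JP": 0.1, "IT": 0.08, "": 0.27}
    )
    year_start: int = 2004
    year_end: int = 2024

    @field_validator("sex_probs", "country_probs")
    @classmethod
    def _valid_probs(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        return v


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic dataset."""

    n_reports: int = Field(gt=0)
    drugs: list[DrugSpec]
    events: list[EventSpec]
    planted_signals: list[PlantedSignal] = Field(default_factory=list)
    tto_params: dict[str, WeibullParams] = Field(default_factory=dict)
    demographics: DemographicMixtures = Field(default_factory=DemographicMixtures)
    duplicate_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    partial_date_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_references(self) -> "GeneratorConfig":
        drug_names = {d.name for d in self.drugs}
        event_pts = {e.pt for e in self.events}
        if len(drug_names) != len(self.drugs):
            raise ValueError("drugs: duplicate drug names")
        if len(event_pts) != len(self.events):
            raise ValueError("events: duplicate PT names")
        for sig in self.planted_signals:
            if sig.drug not in drug_names:
                raise ValueError(f"planted_signals: unknown drug {sig.drug!r}")
            if sig.pt not in event_pts:
                raise ValueError(f"planted_signals: unknown PT {sig.pt!r}")
        for name in self.tto_params:
            if name not in drug_names:
                raise ValueError(f"tto_params: unknown drug {name!r}")
        return self


class TruthManifest(BaseModel):
    """Ground truth for one generated dataset."""

    pair_relative_rates: dict[str, float]  # "drug||pt" -> relative rate
    drug_weibull: dict[str, tuple[float, float]]  # drug -> (shape, scale)
    duplicate_caseids: list[str]
    partial_date_counts: dict[str, int]
    n_unique_cases: int
    yearly_counts: dict[str, dict[int, int]]  # drug -> {report year -> count}

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=1, sort_keys=True)


_DEFAULT_TTO = WeibullParams(shape=1.0, scale=30.0)


def _format_dates(days: np.ndarray, partial_kind: np.ndarray) -> np.ndarray:
    """Render days-since-epoch as YYYYMMDD strings, truncated where partial.

    partial_kind: 0 = full, 1 = YYYYMM, 2 = YYYY.
    """
    dates = _EPOCH + days.astype("timedelta64[D]")
    full = (
        pd.Series(dates).dt.strftime("%Y%m%d").to_numpy(dtype=object)
    )
    out = full.copy()
    out[partial_kind == 1] = [s[:6] for s in full[partial_kind == 1]]
    out[partial_kind == 2] = [s[:4] for s in full[partial_kind == 2]]
    return out


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[dict[str, pd.DataFrame], TruthManifest]:
    """Generate the five FAERS-format tables plus a truth manifest.

    Returns a dict with keys DEMO, DRUG, REAC, THER, INDI (pandas frames of
    strings, one row per record) and the :class:`TruthManifest`.  The same
    config and seed always produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    demo_mix = config.demographics
    n_drugs = len(config.drugs)
    n_events = len(config.events)
    drug_names = [d.name for d in config.drugs]
    event_pts = [e.pt for e in config.events]

    # --- drug exposure: independent Bernoulli per drug, capped at 3/report
    probs = np.array([d.exposure_prob for d in config.drugs])
    exposed = rng.random((n, n_drugs)) < probs
    over = np.flatnonzero(exposed.sum(axis=1) > 3)
    for i in over:
        picked = np.flatnonzero(exposed[i])
        keep = rng.choice(picked, size=3, replace=False)
        exposed[i] = False
        exposed[i, keep] = True

    # --- reactions: per-report event rate = background * max planted rate
    bg = np.array([e.background_prob for e in config.events])
    rel = np.ones((n, n_events))
    seen = np.zeros((n, n_events), dtype=bool)
    for sig in config.planted_signals:
        di = drug_names.index(sig.drug)
        ei = event_pts.index(sig.pt)
        rows = exposed[:, di]
        prev = np.where(seen[rows, ei], rel[rows, ei], -np.inf)
        rel[rows, ei] = np.maximum(prev, sig.relative_rate)
        seen[rows, ei] = True
    event_p = np.clip(bg[None, :] * rel, 0.0, 1.0)
    reacted = rng.random((n, n_events)) < event_p

    # --- demographics
    sex_cats = list(demo_mix.sex_probs)
    sex = rng.choice(sex_cats, size=n, p=list(demo_mix.sex_probs.values()))
    age_years = np.clip(rng.normal(demo_mix.age_mean, demo_mix.age_sd, n), 0.5, 119.0)
    age_missing = rng.random(n) < demo_mix.age_missing_prob
    age_unit = rng.choice(["YR", "MON", "DEC"], size=n, p=[0.9, 0.05, 0.05])
    age_value = np.where(
        age_unit == "MON", age_years * 12.0,
        np.where(age_unit == "DEC", age_years / 10.0, age_years),
    )
    weight_kg = np.clip(
        rng.normal(demo_mix.weight_mean, demo_mix.weight_sd, n), 25.0, 250.0
    )
    weight_missing = rng.random(n) < demo_mix.weight_missing_prob
    weight_unit = rng.choice(["KG", "LBS"], size=n, p=[0.8, 0.2])
    weight_value = np.where(weight_unit == "LBS", weight_kg / 0.453592, weight_kg)
    country = rng.choice(
        list(demo_mix.country_probs), size=n, p=list(demo_mix.country_probs.values())
    )

    # --- dates: therapy start uniform over the study years, day precision
    d0 = (np.datetime64(f"{demo_mix.year_start}-01-01") - _EPOCH).astype(int)
    d1 = (np.datetime64(f"{demo_mix.year_end}-12-31") - _EPOCH).astype(int)
    start_days = rng.integers(d0, d1 + 1, size=n)

    # primary-suspect drug = first exposed drug (config order); its Weibull
    # onset sets the event date, so per-drug onset samples are exact draws
    # from that drug's distribution
    any_drug = exposed.any(axis=1)
    ps_idx = np.where(any_drug, exposed.argmax(axis=1), -1)
    onset = np.zeros(n)
    for di, name in enumerate(drug_names):
        par = config.tto_params.get(name, _DEFAULT_TTO)
        rows = ps_idx == di
        onset[rows] = par.scale * rng.weibull(par.shape, rows.sum())
    onset_days = np.maximum(np.floor(onset), 0).astype(int)
    event_days = start_days + onset_days
    fda_days = event_days + rng.integers(0, 181, size=n)

    # --- partial-precision date flags (0 full, 1 YYYYMM, 2 YYYY)
    def draw_partial(size: int) -> np.ndarray:
        kind = np.zeros(size, dtype=int)
        hit = rng.random(size) < config.partial_date_fraction
        kind[hit] = rng.integers(1, 3, size=hit.sum())
        return kind

    event_partial = draw_partial(n)
    primaryid = np.array([str(100000000 + i) for i in range(n)], dtype=object)
    caseid = np.array([str(200000000 + i) for i in range(n)], dtype=object)

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "fda_dt": _format_dates(fda_days, np.zeros(n, dtype=int)),
            "event_dt": _format_dates(event_days, event_partial),
            "sex": sex,
            "age": np.where(age_missing, "", np.char.mod("%.1f", age_value)),
            "age_cod": np.where(age_missing, "", age_unit),
            "wt": np.where(weight_missing, "", np.char.mod("%.1f", weight_value)),
            "wt_cod": np.where(weight_missing, "", weight_unit),
            "occr_country": country,
        }
    )

    # --- DRUG / THER / INDI rows, one per (report, exposed drug)
    rep_i, drug_i = np.nonzero(exposed)
    seq = np.concatenate(
        [np.arange(1, c + 1) for c in np.bincount(rep_i, minlength=n)]
    ) if len(rep_i) else np.array([], dtype=int)
    role = np.where(seq == 1, "PS", "SS")
    # secondary-suspect therapy starts back-computed from that drug's own
    # Weibull so every drug's onset sample follows its configured law
    ther_start = np.empty(len(rep_i), dtype=int)
    is_ps = seq == 1
    ther_start[is_ps] = start_days[rep_i[is_ps]]
    for di, name in enumerate(drug_names):
        rows = (~is_ps) & (drug_i == di)
        if rows.any():
            par = config.tto_params.get(name, _DEFAULT_TTO)
            draw = np.maximum(
                np.floor(par.scale * rng.weibull(par.shape, rows.sum())), 0
            ).astype(int)
            ther_start[rows] = event_days[rep_i[rows]] - draw

    drug_tbl = pd.DataFrame(
        {
            "primaryid": primaryid[rep_i],
            "drug_seq": seq.astype(str),
            "role_cod": role,
            "drugname": np.array(drug_names, dtype=object)[drug_i],
        }
    )
    ther_partial = draw_partial(len(rep_i))
    ther_tbl = pd.DataFrame(
        {
            "primaryid": primaryid[rep_i],
            "dsg_drug_seq": seq.astype(str),
            "start_dt": _format_dates(ther_start, ther_partial),
        }
    )
    indi_terms = np.empty(len(rep_i), dtype=object)
    for di, spec in enumerate(config.drugs):
        rows = np.flatnonzero(drug_i == di)
        terms = list(spec.indications)
        w = np.array(list(spec.indications.values()))
        indi_terms[rows] = rng.choice(terms, size=len(rows), p=w / w.sum())
    indi_tbl = pd.DataFrame(
        {
            "primaryid": primaryid[rep_i],
            "indi_drug_seq": seq.astype(str),
            "indi_pt": indi_terms,
        }
    )

    rrep, rev = np.nonzero(reacted)
    reac_tbl = pd.DataFrame(
        {
            "primaryid": primaryid[rrep],
            "pt": np.array(event_pts, dtype=object)[rev],
        }
    )

    # --- duplicate case versions: full re-emission under a new primaryid
    # with a later receipt date, so dedup (keep latest) retains a complete
    # record and the extra DEMO row is the one discarded downstream
    n_dup = int(round(config.duplicate_fraction * n))
    dup_caseids: list[str] = []
    kept_fda_days = fda_days.copy()  # receipt day of the case's kept version
    if n_dup > 0:
        dup_rows = rng.choice(n, size=n_dup, replace=False)
        dup_rows.sort()
        dup_caseids = [str(caseid[i]) for i in dup_rows]
        new_pid = np.array(
            [str(300000000 + i) for i in range(n_dup)], dtype=object
        )
        pid_map = dict(zip(primaryid[dup_rows], new_pid))
        demo_dup = demo.iloc[dup_rows].copy()
        demo_dup["primaryid"] = new_pid
        demo_dup["fda_dt"] = _format_dates(
            fda_days[dup_rows] + 30, np.zeros(n_dup, dtype=int)
        )
        kept_fda_days[dup_rows] += 30
        demo = pd.concat([demo, demo_dup], ignore_index=True)

        def dup_children(tbl: pd.DataFrame) -> pd.DataFrame:
            child = tbl[tbl["primaryid"].isin(pid_map)].copy()
            child["primaryid"] = child["primaryid"].map(pid_map)
            return pd.concat([tbl, child], ignore_index=True)

        drug_tbl = dup_children(drug_tbl)
        reac_tbl = dup_children(reac_tbl)
        ther_tbl = dup_children(ther_tbl)
        indi_tbl = dup_children(indi_tbl)

    # --- ground truth
    pair_rates = {}
    for sig in config.planted_signals:
        pair_rates[f"{sig.drug}||{sig.pt}"] = sig.relative_rate
    yearly: dict[str, dict[int, int]] = {}
    fda_years = pd.Series(
        _EPOCH + kept_fda_days.astype("timedelta64[D]")
    ).dt.year.to_numpy()
    for di, name in enumerate(drug_names):
        ys, cnt = np.unique(fda_years[exposed[:, di]], return_counts=True)
        yearly[name] = {int(y): int(c) for y, c in zip(ys, cnt)}
    truth = TruthManifest(
        pair_relative_rates=pair_rates,
        drug_weibull={
            name: (par.shape, par.scale) for name, par in config.tto_params.items()
        },
        duplicate_caseids=dup_caseids,
        partial_date_counts={
            "event_dt": int((event_partial > 0).sum()),
            "start_dt": int((ther_partial > 0).sum()) if len(rep_i) else 0,
        },
        n_unique_cases=n,
        yearly_counts=yearly,
    )
    tables = {
        "DEMO": demo,
        "DRUG": drug_tbl,
        "REAC": reac_tbl,
        "THER": ther_tbl,
        "INDI": indi_tbl,
    }
    return tables, truth


def write_dataset(
    tables: dict[str, pd.DataFrame],
    truth: Optional[TruthManifest],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write dollar-delimited FAERS tables (and the manifest) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, tbl in tables.items():
        path = outdir / f"{name}.txt"
        tbl.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    if truth is not None:
        path = outdir / "truth_manifest.json"
        path.write_text(truth.to_json())
        paths["truth"] = path
    return paths
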