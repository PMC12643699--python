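"""End-to-end pipeline: simulate -> etl -> contingency -> signals -> tto -> report.

Driven by one plain-dict (YAML-friendly) config.  Every output is a
deterministic text artifact; rerunning with the same config and seed
produces byte-identical files, recorded with SHA-256 checksums in
``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from phytovigil import __version__
from phytovigil.contingency import build_pair_tables, tables_to_frame
from phytovigil.defaults import (
    STUDY_DRUGS,
    default_meddra,
    default_study_config,
    default_synonyms,
)
from phytovigil.disproportionality import ScoreConfig, score_tables
from phytovigil.etl import (
    MeddraDictionary,
    build_case_reports,
    read_faers_tables,
)
from phytovigil.reporting import (
    demographic_summary,
    flag_candidate_novel,
    overlap_sets,
    top_events,
    yearly_counts,
)
from phytovigil.synthetic import GeneratorConfig, generate_dataset, write_dataset
from phytovigil.tto import compute_tto, fit_weibull, summarize_tto, tto_histogram

logger = logging.getLogger(__name__)

STAGES = ["simulate", "etl", "contingency", "signals", "tto", "report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage
        self.reason = reason


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_mapping(source: Any, default: Mapping[str, str]) -> dict[str, str]:
    if source is None:
        return dict(default)
    if isinstance(source, Mapping):
        return dict(source)
    tbl = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(tbl.iloc[:, 0], tbl.iloc[:, 1]))


def generator_config_from(cfg: Optional[Mapping[str, Any]],
                          seed: Optional[int]) -> GeneratorConfig:
    """Build a GeneratorConfig from the ``simulate`` config section."""
    cfg = dict(cfg or {})
    if seed is not None:
        cfg["seed"] = seed
    if "drugs" in cfg:
        return GeneratorConfig(**cfg)
    return default_study_config(
        n_reports=cfg.get("n_reports", 50_000), seed=cfg.get("seed", 0)
    )


def run_pipeline(
    config: Optional[Mapping[str, Any]] = None,
    outdir: str | Path = "phytovigil_out",
    seed: Optional[int] = None,
) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Config keys (all optional): ``simulate`` (generator config or
    ``{"n_reports": N}``), ``faers_dir`` (use existing tables instead of
    simulating), ``synonyms``/``meddra`` (path or inline mapping),
    ``target_drugs``, ``top_n``, ``min_count``, ``known_terms``.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    manifest: dict[str, Any] = {
        "versions": {
            "phytovigil": __version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        timings[name] = time.perf_counter()
        logger.info("stage %s ...", name)

    def done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.2fs", name, timings[name])

    # --- simulate -----------------------------------------------------
    stage("simulate")
    try:
        if "faers_dir" in config:
            faers_dir = Path(config["faers_dir"])
            paths = {
                name: faers_dir / f"{name}.txt"
                for name in ("DEMO", "DRUG", "REAC", "THER", "INDI")
            }
            gen_cfg = None
        else:
            gen_cfg = generator_config_from(config.get("simulate"), seed)
            tables, truth = generate_dataset(gen_cfg)
            written = write_dataset(tables, truth, outdir / "faers")
            paths = {k: v for k, v in written.items() if k != "truth"}
            counts["simulated_reports"] = gen_cfg.n_reports
    except (OSError, ValueError) as err:
        raise PipelineError("simulate", str(err)) from err
    done("simulate")

    # --- etl ----------------------------------------------------------
    stage("etl")
    try:
        synonyms = _load_mapping(config.get("synonyms"), default_synonyms())
        meddra = MeddraDictionary(
            _load_mapping(config.get("meddra"), default_meddra()),
            version="synthetic" if config.get("meddra") is None else "user",
        )
        raw = read_faers_tables(paths)
        etl_stats: dict[str, int] = {}
        reports = build_case_reports(raw, synonyms, meddra, stats=etl_stats)
        counts["demo_rows"] = etl_stats.get("demo_rows", 0)
        counts["unique_cases"] = len(reports)
    except (OSError, ValueError, KeyError) as err:
        raise PipelineError("etl", str(err)) from err
    done("etl")

    target_drugs = list(config.get("target_drugs", STUDY_DRUGS))

    # --- contingency ----------------------------------------------------
    stage("contingency")
    try:
        pt_tables = build_pair_tables(reports, granularity="PT", meddra=meddra)
        soc_tables = build_pair_tables(reports, granularity="SOC", meddra=meddra)
        counts["pt_pairs"] = len(pt_tables)
        counts["soc_pairs"] = len(soc_tables)
        tables_to_frame(pt_tables).to_csv(
            outdir / "tables_pt.csv", index=False, lineterminator="\n"
        )
    except ValueError as err:
        raise PipelineError("contingency", str(err)) from err
    done("contingency")

    # --- signals ---------------------------------------------------------
    stage("signals")
    try:
        score_cfg = ScoreConfig()
        pt_scores, pt_prior = score_tables(pt_tables, score_cfg)
        soc_scores, _ = score_tables(soc_tables, score_cfg)
        float_fmt = "%.6g"
        pt_target = pt_scores[pt_scores["drug"].isin(target_drugs)]
        pt_target = flag_candidate_novel(pt_target, config.get("known_terms"))
        pt_target.to_csv(outdir / "table3_pt.csv", index=False,
                         float_format=float_fmt, lineterminator="\n")
        soc_scores[soc_scores["drug"].isin(target_drugs)].to_csv(
            outdir / "table2_soc.csv", index=False,
            float_format=float_fmt, lineterminator="\n")
        counts["pt_signals_any_of_four"] = int(
            pt_target["any_of_four"].sum()
        )
    except ValueError as err:
        raise PipelineError("signals", str(err)) from err
    done("signals")

    # --- tto -------------------------------------------------------------
    stage("tto")
    tto_out: dict[str, Any] = {}
    try:
        hist_frames = []
        for drug in target_drugs:
            records, excluded = compute_tto(reports, drug)
            entry: dict[str, Any] = {"drug": drug, "excluded": excluded,
                                     "n": len(records)}
            if records:
                med, iqr, n = summarize_tto(records)
                entry.update({"median": med, "iqr": list(iqr)})
                try:
                    fit = fit_weibull(records)
                    entry.update(
                        {
                            "alpha": fit.scale_alpha,
                            "alpha_ci": list(fit.scale_ci),
                            "beta": fit.shape_beta,
                            "beta_ci": list(fit.shape_ci),
                            "failure_type": fit.failure_type,
                        }
                    )
                except ValueError as err:
                    entry["fit_error"] = str(err)
                hist = tto_histogram(records)
                hist.insert(0, "drug", drug)
                hist_frames.append(hist)
            tto_out[drug] = entry
        (outdir / "tto.json").write_text(
            json.dumps(tto_out, indent=1, sort_keys=True)
        )
        if hist_frames:
            pd.concat(hist_frames, ignore_index=True).to_csv(
                outdir / "tto_histogram.csv", index=False, lineterminator="\n"
            )
    except ValueError as err:
        raise PipelineError("tto", str(err)) from err
    done("tto")

    # --- report ----------------------------------------------------------
    stage("report")
    try:
        table1 = {
            drug: demographic_summary(reports, drug).to_dict()
            for drug in target_drugs
        }
        (outdir / "table1.json").write_text(
            json.dumps(table1, indent=1, sort_keys=True)
        )
        yearly_rows = []
        for drug in target_drugs:
            for year, cnt in sorted(yearly_counts(reports, drug).items()):
                yearly_rows.append({"drug": drug, "year": year, "count": cnt})
        pd.DataFrame(yearly_rows).to_csv(
            outdir / "yearly.csv", index=False, lineterminator="\n"
        )
        per_drug = {
            drug: pt_scores[pt_scores["drug"] == drug] for drug in target_drugs
        }
        overlap = overlap_sets(per_drug, min_count=config.get("min_count", 100))
        (outdir / "overlap.json").write_text(
            json.dumps(overlap.to_dict(), indent=1, sort_keys=True)
        )
        top_n = config.get("top_n", 20)
        tops = pd.concat(
            [top_events(df, top_n).assign(rank=lambda f: f.index + 1)
             for df in per_drug.values()],
            ignore_index=True,
        )
        tops.to_csv(outdir / "top_events.csv", index=False,
                    float_format="%.6g", lineterminator="\n")
    except ValueError as err:
        raise PipelineError("report", str(err)) from err
    done("report")

    manifest["row_counts"] = counts
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    for name, secs in timings.items():
        logger.info("timing %s: %.2fs", name, secs)
    return outdir
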