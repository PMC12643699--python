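import datetime

import pytest

from phytovigil.etl import CaseReport, DrugEntry
from phytovigil.synthetic import (
    DrugSpec,
    EventSpec,
    GeneratorConfig,
    PlantedSignal,
    WeibullParams,
    generate_dataset,
)


def make_report(
    pid,
    drugs=(),
    reactions=(),
    sex="F",
    age=None,
    weight=None,
    country="US",
    event_date=None,
    report_year=2020,
    indications=(),
):
    """Compact CaseReport builder: drugs as name or (name, role) tuples."""
    entries = []
    for d in drugs:
        name, role = d if isinstance(d, tuple) else (d, "PS")
        entries.append(DrugEntry(raw_name=name, standard_name=name, role=role))
    return CaseReport(
        primaryid=str(pid),
        caseid=f"c{pid}",
        sex=sex,
        age_years=age,
        weight_kg=weight,
        country=country,
        event_date=event_date,
        event_date_partial=None,
        report_year=report_year,
        indications=set(indications),
        drugs=entries,
        reactions=set(reactions),
    )


def tiny_config(**overrides):
    """Two drugs, three events, one planted pair; fast to generate."""
    base = dict(
        n_reports=2000,
        drugs=[
            DrugSpec(name="drugA", exposure_prob=0.2),
            DrugSpec(name="drugB", exposure_prob=0.3),
        ],
        events=[
            EventSpec(pt="PT_X", soc="SOC_1", background_prob=0.05),
            EventSpec(pt="PT_Y", soc="SOC_1", background_prob=0.08),
            EventSpec(pt="PT_Z", soc="SOC_2", background_prob=0.10),
        ],
        planted_signals=[PlantedSignal(drug="drugA", pt="PT_X", relative_rate=8.0)],
        tto_params={
            "drugA": WeibullParams(shape=0.8, scale=40.0),
            "drugB": WeibullParams(shape=1.2, scale=25.0),
        },
        duplicate_fraction=0.1,
        partial_date_fraction=0.1,
        seed=42,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    cfg = tiny_config()
    tables, truth = generate_dataset(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def tiny_dir(tiny_bundle, tmp_path_factory):
    from phytovigil.synthetic import write_dataset

    _, tables, truth = tiny_bundle
    d = tmp_path_factory.mktemp("faers")
    write_dataset(tables, truth, d)
    return d


D = datetime.date
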