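"""Default study configuration for the synthetic generator.

The defaults emulate a three-drug plant-alkaloid chemotherapy safety
study: paclitaxel, vincristine and irinotecan as suspect drugs inside a
universe of common comparator drugs, ~25 preferred terms spanning the
major toxicity SOCs (hematologic, gastrointestinal, neurologic, vascular,
respiratory, infection), planted relative reporting rates of the magnitude
observed for these drugs' hallmark toxicities, and per-drug Weibull onset
parameters matching the early-failure profile reported for this class
(shape well below 1, scale of a few weeks).
"""

from __future__ import annotations

from phytovigil.synthetic import (
    DrugSpec,
    EventSpec,
    GeneratorConfig,
    PlantedSignal,
    WeibullParams,
)

STUDY_DRUGS = ("paclitaxel", "vincristine", "irinotecan")

#: (pt, primary soc, background reporting probability)
_EVENTS = [
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.020),
    ("Erythema", "Skin and subcutaneous tissue disorders", 0.008),
    ("Neutropenia", "Blood and lymphatic system disorders", 0.006),
    ("Flushing", "Vascular disorders", 0.004),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.015),
    ("Anaemia", "Blood and lymphatic system disorders", 0.012),
    ("Neuropathy peripheral", "Nervous system disorders", 0.005),
    ("Febrile neutropenia", "Blood and lymphatic system disorders", 0.003),
    ("Diarrhoea", "Gastrointestinal disorders", 0.030),
    ("Nausea", "Gastrointestinal disorders", 0.040),
    ("Vomiting", "Gastrointestinal disorders", 0.025),
    ("Pyrexia", "General disorders and administration site conditions", 0.030),
    ("Thrombocytopenia", "Blood and lymphatic system disorders", 0.006),
    ("Sepsis", "Infections and infestations", 0.008),
    ("Leukopenia", "Blood and lymphatic system disorders", 0.003),
    ("Stomatitis", "Gastrointestinal disorders", 0.004),
    ("Mucosal inflammation",
     "General disorders and administration site conditions", 0.002),
    ("Abdominal pain", "Gastrointestinal disorders", 0.020),
    ("Hypotension", "Vascular disorders", 0.012),
    ("Death", "General disorders and administration site conditions", 0.030),
    ("Fatigue", "General disorders and administration site conditions", 0.050),
    ("Headache", "Nervous system disorders", 0.040),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.030),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.020),
    ("Dehydration", "Metabolism and nutrition disorders", 0.008),
    ("Pulmonary embolism", "Vascular disorders", 0.005),
]

#: hallmark-toxicity relative rates of the magnitude seen for this class
_PLANTED = [
    ("paclitaxel", "Dyspnoea", 3.4),
    ("paclitaxel", "Erythema", 5.0),
    ("paclitaxel", "Neutropenia", 6.9),
    ("paclitaxel", "Flushing", 8.8),
    ("paclitaxel", "Back pain", 3.4),
    ("paclitaxel", "Anaemia", 3.9),
    ("paclitaxel", "Neuropathy peripheral", 7.4),
    ("paclitaxel", "Febrile neutropenia", 7.8),
    ("paclitaxel", "Thrombocytopenia", 4.0),
    ("paclitaxel", "Hypotension", 2.7),
    ("vincristine", "Febrile neutropenia", 50.0),
    ("vincristine", "Neutropenia", 12.5),
    ("vincristine", "Neuropathy peripheral", 14.2),
    ("vincristine", "Sepsis", 7.3),
    ("vincristine", "Anaemia", 3.4),
    ("vincristine", "Thrombocytopenia", 5.4),
    ("vincristine", "Leukopenia", 7.6),
    ("vincristine", "Mucosal inflammation", 16.7),
    ("irinotecan", "Diarrhoea", 4.6),
    ("irinotecan", "Neutropenia", 10.7),
    ("irinotecan", "Vomiting", 2.85),
    ("irinotecan", "Pyrexia", 2.2),
    ("irinotecan", "Abdominal pain", 3.0),
    ("irinotecan", "Febrile neutropenia", 10.3),
    ("irinotecan", "Dehydration", 3.5),
    ("irinotecan", "Leukopenia", 8.4),
    ("irinotecan", "Stomatitis", 6.7),
    ("irinotecan", "Sepsis", 3.4),
]

#: early-failure onset profiles (shape < 1) for the study drugs,
#: exponential-like onsets for comparators
_TTO = {
    "paclitaxel": WeibullParams(shape=0.64, scale=61.23),
    "vincristine": WeibullParams(shape=0.54, scale=46.75),
    "irinotecan": WeibullParams(shape=0.72, scale=52.99),
}

_COMPARATORS = [
    ("cisplatin", 0.08),
    ("doxorubicin", 0.07),
    ("fluorouracil", 0.08),
    ("pembrolizumab", 0.05),
    ("metformin", 0.10),
    ("amoxicillin", 0.07),
    ("ibuprofen", 0.09),
    ("lisinopril", 0.07),
]

_INDICATIONS = {
    "paclitaxel": {
        "Product used for unknown indication": 0.45,
        "Breast cancer": 0.30,
        "Ovarian cancer": 0.15,
        "Pancreatic carcinoma": 0.10,
    },
    "vincristine": {
        "Acute lymphocytic leukaemia": 0.40,
        "Diffuse large B-cell lymphoma": 0.25,
        "Product used for unknown indication": 0.25,
        "Non-Hodgkin's lymphoma": 0.10,
    },
    "irinotecan": {
        "Colorectal cancer metastatic": 0.40,
        "Product used for unknown indication": 0.30,
        "Pancreatic carcinoma": 0.20,
        "Colon cancer": 0.10,
    },
}


def default_study_config(n_reports: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """Generator config emulating the three-drug study conditions."""
    drugs = [
        DrugSpec(name="paclitaxel", exposure_prob=0.062,
                 indications=_INDICATIONS["paclitaxel"]),
        DrugSpec(name="vincristine", exposure_prob=0.015,
                 indications=_INDICATIONS["vincristine"]),
        DrugSpec(name="irinotecan", exposure_prob=0.024,
                 indications=_INDICATIONS["irinotecan"]),
    ] + [DrugSpec(name=n, exposure_prob=p) for n, p in _COMPARATORS]
    return GeneratorConfig(
        n_reports=n_reports,
        drugs=drugs,
        events=[EventSpec(pt=p, soc=s, background_prob=b) for p, s, b in _EVENTS],
        planted_signals=[
            PlantedSignal(drug=d, pt=p, relative_rate=r) for d, p, r in _PLANTED
        ],
        tto_params=_TTO,
        duplicate_fraction=0.05,
        partial_date_fraction=0.08,
        seed=seed,
    )


def null_config(
    n_reports: int = 20_000, seed: int = 0, duplicate_fraction: float = 0.0
) -> GeneratorConfig:
    """Same universe with every relative rate at 1 (independence holds)."""
    cfg = default_study_config(n_reports=n_reports, seed=seed)
    return cfg.model_copy(
        update={
            "planted_signals": [],
            "duplicate_fraction": duplicate_fraction,
            "partial_date_fraction": 0.0,
        }
    )


def default_meddra() -> dict[str, str]:
    """PT -> primary SOC map covering the default event universe.

    A synthetic stand-in dictionary: covers only the PTs generated here,
    not the licensed MedDRA terminology.
    """
    return {pt: soc for pt, soc, _ in _EVENTS}


def default_synonyms() -> dict[str, str]:
    """Case-folded raw name -> standard name for the default drug universe."""
    names = [d for d, _ in _COMPARATORS] + list(STUDY_DRUGS)
    syn = {n.casefold(): n for n in names}
    syn.update({"taxol": "paclitaxel", "abraxane": "paclitaxel",
                "oncovin": "vincristine", "camptosar": "irinotecan",
                "irinotecan hcl": "irinotecan"})
    return syn
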