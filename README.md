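# phytovigil

Pharmacovigilance signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports, built around the standard
workflow used to profile the safety of plant-alkaloid chemotherapeutics
(paclitaxel, vincristine, irinotecan): quarterly-table ETL with case
deduplication and MedDRA PT→SOC coding, 2×2 disproportionality analysis
with four algorithm families, and Weibull modelling of onset times.
A bundled synthetic-report generator with a ground-truth manifest makes
every stage testable without downloading FAERS.

## Who it is for

Drug-safety analysts and biostatisticians who want a reproducible,
scriptable version of the classic spontaneous-report analysis: load the
dollar-delimited DEMO/DRUG/REAC/THER/INDI tables, get per-(drug, event)
signal scores and hazard-shape classifications out.

## The statistics

For each drug D and event E (MedDRA preferred term or system organ
class), reports are cross-classified into a 2×2 table — `a` with D and E,
`b` with D only, `c` with E only, `d` with neither, `N = a+b+c+d` — and
scored with:

- **ROR** = `ad/(bc)`, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`,
  Haldane–Anscombe 0.5 correction for zero cells;
- **PRR** = `[a/(a+b)] / [c/(c+d)]` with the Pearson χ² of the table;
- **BCPNN IC** = `log2((a+½)/(E+½))` with `E = (a+b)(a+c)/N` and the
  closed-form lower credibility bound
  `IC025 = IC − 3.3(a+½)^−½ − 2.4(a+½)^−1`;
- **MGPS EBGM**: DuMouchel's empirical Bayes — `a ~ Poisson(λE)` with a
  two-component gamma mixture prior on λ fitted by marginal
  (negative-binomial mixture) maximum likelihood across all pairs;
  EBGM = `2^E[log2 λ | a]`, EBGM05 = 5th posterior percentile.

A pair is signal-positive under the conventional rules (`a ≥ 3` and ROR
lower bound > 1; PRR ≥ 2 with χ² ≥ 4; IC025 > 0; EBGM05 ≥ 2), combined
with an any-of-four flag.

Time-to-onset (days from earliest full-precision therapy start to event
date) is summarized by median/IQR and fitted by complete-sample Weibull
maximum likelihood; a shape β with its whole 95% CI below 1 labels the
drug's hazard "early failure" (event incidence declining with time on
treatment).

## Worked example

```python
from phytovigil.pipeline import run_pipeline

out = run_pipeline({"simulate": {"n_reports": 50_000}}, "out", seed=17)
print((out / "tto.json").read_text())
```

The default synthetic configuration emulates a three-drug chemotherapy
study inside a universe of comparator drugs. The paclitaxel entry of
`tto.json` from the run above:

```json
"paclitaxel": {
 "alpha": 59.89576493529737,
 "beta": 0.6552605919072719,
 "beta_ci": [0.6359955257678264, 0.6751092199717942],
 "failure_type": "early",
 "median": 33.0,
 "n": 2617
}
```

meaning: 2,617 reports had usable onset dates, the median onset was 33
days, and the fitted Weibull (scale α ≈ 59.9 days, shape β ≈ 0.66 with CI
entirely below 1) classifies paclitaxel onsets as early-failure — close
to the shape/scale planted by the generator (α = 61.23, β = 0.64), so
the estimator recovers the truth up to sampling noise. `table3_pt.csv` in the same directory holds
the per-PT score table (ROR/PRR/χ²/IC/EBGM with interval bounds and
flags), `table2_soc.csv` its SOC-level analogue, `table1.json` the
demographic summary, and `overlap.json` the cross-drug overlap of
qualifying PT signals.

The same stages are available from the shell:

```bash
phytovigil simulate --out faers_sim --seed 17 --n-reports 50000
phytovigil etl --faers faers_sim --out clean.csv
phytovigil run --out results_dir --seed 17
```

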