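# Methods

This note records the models implemented in phytovigil, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Report model and counting rules

The statistical unit throughout is one deduplicated spontaneous report.
Deduplication keeps, per case ID, the version with the latest FDA receipt
date (`fda_dt`), breaking ties by the numerically largest primaryid —
the standard convention for FAERS follow-up versions; the receipt date is
used as the ordering field because it is always populated at day
precision. A drug counts as an exposure when its role code is PS or SS
(primary/secondary suspect); concomitant (C) and interacting (I) entries
are kept on the report but excluded from the suspect set. The comparator
universe for each (drug, event) pair is the full cleaned collection,
including reports of the other study drugs; an exclusion list is
available where a sensitivity analysis wants them removed.

At PT granularity a report contributes at most once per (drug, PT) pair;
at SOC granularity once per (drug, SOC) however many of its PTs map to
that SOC. Each PT resolves to exactly one primary SOC through a
user-supplied two-column dictionary; unmapped PTs are tagged `UNMAPPED`
and counted rather than dropped, so coding gaps are visible instead of
silently shrinking margins.

## Unit and date harmonization

Ages convert to years by unit code (DEC×10, YR×1, MON÷12, WK÷52.1775,
DY÷365.25, HR÷8766); results outside [0, 150) years become missing with a
tallied warning, as do unknown codes. Weights convert to kg (LBS×0.453592,
GMS÷1000) with a (0, 500) kg validity window. Dates may carry day
(YYYYMMDD), month (YYYYMM) or year (YYYY) precision; partial dates are
retained and flagged but only full dates enter day-difference arithmetic.

## Disproportionality statistics

All four families score the same 2×2 table; the expected count is
`E = (a+b)(a+c)/N` throughout.

**ROR.** `ad/(bc)` with a Wald CI on the log scale (z = 1.96 by default,
configurable via `ror_ci_z`). Zero cells get the Haldane–Anscombe 0.5
added to all four cells, for ROR only — PRR, IC and EBGM remain defined
without correction. Disabling the correction returns an
undefined-flagged result instead.

**PRR / χ².** The proportion ratio with the Pearson statistic
`N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`; Yates continuity correction is
available but off by default, matching common pharmacovigilance usage.

**BCPNN IC.** Default variant is the closed-form credibility-interval
approximation: `IC = log2((a+½)/(E+½))`,
`IC025 = IC − 3.3(a+½)^−½ − 2.4(a+½)^−1` — finite for all a ≥ 0. The
original beta/Dirichlet normal approximation (`bate_beta`) is provided
behind the `bcpnn_variant` switch; its posterior-moment expectation and
variance use the customary hyperparameters (marginal priors Beta(1,1),
joint γ₁₁ = 1 rescaled by the margins). Published study tables in this
field often print an IC that equals log2(EBGM) to two decimals,
suggesting an MGPS-derived IC; both computations are available here and
neither is presumed.

**MGPS / EBGM.** λ has the two-component gamma mixture prior
`w·Gamma(α₁, β₁) + (1−w)·Gamma(α₂, β₂)` (rate parameterization). The
marginal of `a` is a two-component negative-binomial mixture; the five
hyperparameters maximize the summed marginal log-likelihood over all
pairs with E > 0, via L-BFGS-B on (log α₁, log β₁, log α₂, log β₂,
logit w) with parameter/function tolerance 1e−8. Three starts are used:
the documented initial point (0.2, 0.1, 2.0, 4.0, 1/3) plus two
fixed-seed Gaussian perturbations (σ = 0.5); the best optimum wins.
Working parameters are clipped to ±30 on the log scale, where the
likelihood is already flat, to keep line searches finite. Fitting
requires at least 20 usable pairs and at least one nonzero count. The
prior is fitted once per granularity (PT-level fit scores PT tables,
SOC-level fit scores SOC tables), because the empirical prior must match
the cell universe it shrinks.

The posterior given (a, E) is the updated mixture with components
`Gamma(αⱼ + a, βⱼ + E)` and weights proportional to the component
marginals. `EBGM = exp(Σ Qⱼ(ψ(αⱼ+a) − ln(βⱼ+E)))`; EBGM05 solves the
mixture CDF = 0.05 by bracketed root-finding (Brent, xtol 1e−10). With
E = 0 no information accrues and the posterior reduces to the prior.

**Thresholds.** ROR-positive: a ≥ 3 and lower CI > 1 (strict); PRR: a ≥ 3,
PRR ≥ 2, χ² ≥ 4; BCPNN: IC025 > 0; MGPS: a ≥ 3 and EBGM05 ≥ 2. Any
undefined statistic makes that algorithm negative for the pair, never
positive. All cut-offs live in one `Thresholds` object.

A note on monotonicity: with b, c, d held fixed, ROR and PRR are
nondecreasing in a, but IC and EBGM are not — E grows superlinearly in a
under fixed b, c, d, so the shrunk observed/expected statistics
eventually turn over. The meaningful monotonicity for the Bayesian
statistics, and the one the tests assert, holds the expected count fixed
while the observed count grows.

## Weibull time-to-onset

TTO per report is `event_date − earliest full-precision therapy start`
for the drug of interest; negative differences and partial/missing dates
are excluded and tallied by reason. Zero-day onsets are real (infusion
reactions) but break the likelihood at β < 1, so t = 0 maps to 0.5 day
by default (`zero_policy="exclude"` drops them instead). No censoring
model is used: spontaneous reports only contain observed onsets, so the
fit is a complete-sample MLE.

The shape is found by Newton iteration on the profile score
`g(β) = 1/β + mean(ln t) − Σtᵝln t / Σtᵝ`, which is strictly decreasing,
inside a maintained bracket (so the iteration is globally convergent);
tolerance 1e−10 on β. The scale follows in closed form
`α̂ = (Σtᵝ̂/n)^{1/β̂}`. Times are pre-scaled by their geometric mean so the
profile sums stay in floating-point range at any intermediate β. Wald
95% CIs come from the analytic observed information on (ln α, ln β),
transformed back; fits require n ≥ 10 and a non-degenerate sample.
Hazard-shape labels: `early` when the entire shape CI is below 1,
`wear_out` when entirely above, `random` when the CI straddles 1,
`indeterminate` when the CI is undefined.

## Synthetic generator

Each report draws: a drug set (independent Bernoulli per declared drug
with its marginal exposure probability, truncated to 3 drugs when more
are drawn; a report may end up with no declared drug and then populates
the c/d cells), reactions (independent per event with probability
`min(1, background × r)`, where r is the largest planted relative rate
among the report's drugs, 1 if none), demographics (categorical sex and
country with explicit missing mass; normal age and weight re-encoded
into FAERS unit codes — e.g. an age drawn as 62 years may be emitted as
744 MON — so unit harmonization is exercised without distorting the
distribution), and dates (therapy start uniform over the study years;
onset days floored from the primary-suspect drug's Weibull; receipt date
= event date plus a 0–180 day reporting delay). Secondary-suspect
therapy starts are back-computed from the event date using that drug's
own Weibull, so every drug's onset sample follows its configured law
exactly. Duplicates re-emit the whole case (all five tables) under a new
primaryid with a 30-day-later receipt date, so the dedup rule retains a
complete record and discards the older version. Partial dates truncate
event or therapy-start fields to YYYYMM or YYYY. Identical config and
seed give byte-identical tables.

The truth manifest records planted relative rates, per-drug Weibull
parameters, injected duplicate case IDs, partial-date counts, and
per-drug yearly counts of the kept case versions.

The default configuration emulates a three-drug plant-alkaloid
chemotherapy study: paclitaxel/vincristine/irinotecan at exposure
probabilities 0.062/0.015/0.024 (preserving the relative report volumes
of such a study at a tractable scale) inside eight comparator drugs,
26 PTs across the major toxicity SOCs with background rates of
0.2–5%, hallmark-toxicity relative rates between 2.2 and 50, Weibull
onset parameters (α, β) = (61.23, 0.64), (46.75, 0.54), (52.99, 0.72)
for the three study drugs, 5% duplicate cases and 8% partial dates.

What the generator does **not** emulate: concomitant-medication
confounding, outcome/severity tables, country-specific reporting delays,
drug-name misspellings, within-report PT correlation, or secular trends
in reporting volume. Passing tests therefore demonstrate correctness of
the estimators and plumbing under a clean reporting model, not
robustness to the full messiness of real FAERS data.

## Reporting conventions

Percentages are rounded half-up at the precision of the printed block
(1 decimal for sex/age/countries, 2 for weight). Age bins are
[0, 18), [18, 65], (65, 85], (85, ∞): the 18 and 65 boundaries fall in
"18–65" and 85 in "65–85", and this rule is stamped into the output
metadata. Indication and country percentages use the drug's own report
total as denominator (also stated in metadata). Event rankings sort by
report count descending with alphabetical tie-breaks. Cross-drug overlap
sets take PTs that pass the ROR rule with at least 100 reports
(configurable), with all pairwise and higher intersections computed
exactly.

## Problem sizes used in the checks

The bundled acceptance checks run the formula oracles on 1,000 random
tables, prior recovery on 5,000 simulated cells, null calibration and
planted-signal sensitivity on 20,000-report datasets, Weibull recovery
at n = 5,000 with 100 replicates per shape, and the determinism check on
two full 50,000-report pipeline runs. These sizes give stable
Monte-Carlo behaviour for every property asserted while keeping the full
suite fast on a single CPU.

## Known limitations

- No stratified MGPS (age/sex strata) and no multiple-testing control
  beyond the threshold rules — matching standard practice in this study
  type, which applies none.
- No probabilistic record linkage beyond same-case-ID dedup.
- The BCPNN `bate_beta` variant uses the normal approximation to the
  posterior moments, not the exact Monte-Carlo credible interval.
- Weibull CIs are Wald-type on the log scale; for very small samples a
  likelihood-ratio interval would be preferable.
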