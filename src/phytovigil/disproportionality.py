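"""Disproportionality statistics for drug--event 2x2 tables.

Implements the four standard pharmacovigilance signal-detection families:

* **ROR** -- reporting odds ratio ``ad/(bc)`` with a Wald CI on the log
  scale; zero cells handled by the Haldane--Anscombe 0.5 correction.
* **PRR** -- proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with the
  Pearson chi-square of the 2x2 table (optional Yates correction).
* **BCPNN IC** -- the information component, a shrunk log2
  observed-to-expected ratio; two variants are provided, the closed-form
  credibility-interval approximation (default) and the original
  beta/Dirichlet normal approximation.
* **MGPS EBGM** -- DuMouchel's empirical-Bayes gamma--Poisson shrinker:
  counts a ~ Poisson(lambda * E) with a two-component gamma mixture prior
  on lambda fitted by marginal (negative-binomial mixture) maximum
  likelihood across all pairs; EBGM is the geometric mean of the posterior
  and EBGM05 its 5th percentile.

Undefined results (empty margins, disabled corrections) are flagged with a
reason instead of raising, so a full score table can always be produced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import gammaln, logsumexp

from phytovigil.contingency import ContingencyTable

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SignalScores:
    """Point estimates and interval bounds for one (drug, event) pair."""

    ror: Optional[float] = None
    ror_lo: Optional[float] = None
    ror_hi: Optional[float] = None
    prr: Optional[float] = None
    chi2: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    ebgm: Optional[float] = None
    ebgm05: Optional[float] = None
    undefined: dict[str, str] = field(default_factory=dict)


@dataclass
class Thresholds:
    """Signal-positivity rules, one per algorithm family.

    Defaults are the conventional published criteria: ROR positive when the
    lower 95% bound exceeds 1 with at least 3 reports; PRR >= 2 with
    chi-square >= 4 and a >= 3; BCPNN positive when IC025 > 0; MGPS positive
    when EBGM05 >= 2 with a >= 3.
    """

    ror_min_a: int = 3
    prr_min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    mgps_min_a: int = 3
    ebgm05_min: float = 2.0


@dataclass
class SignalDecision:
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool

    @property
    def any_of_four(self) -> bool:
        return self.ror_pos or self.prr_pos or self.bcpnn_pos or self.mgps_pos


@dataclass
class GammaMixturePrior:
    """Hyperparameters of the two-component gamma mixture prior on lambda."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    converged: bool = False
    marginal_loglik: float = float("nan")
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3)


def ror_score(
    t: ContingencyTable, ci_z: float = Z_95, continuity: bool = True
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Reporting odds ratio with Wald CI; 0.5 added to all cells when any
    cell is zero (Haldane--Anscombe), if ``continuity`` is enabled."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity:
            return None, None, None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-ci_z * se), ror * math.exp(ci_z * se)


def prr_chi2_score(
    t: ContingencyTable, yates: bool = False
) -> tuple[Optional[float], Optional[float]]:
    """Proportional reporting ratio and Pearson chi-square.

    Undefined (None) when a margin is empty or the comparator proportion is
    zero.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    prr = None
    if a + b > 0 and c + d > 0 and c > 0:
        prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = None
    if denom > 0:
        diff = abs(a * d - b * c)
        if yates:
            diff = max(diff - n / 2, 0.0)
        chi2 = n * diff * diff / denom
    return prr, chi2


def ic_score(
    t: ContingencyTable, variant: str = "noren_closed_form"
) -> tuple[float, float]:
    """BCPNN information component and its lower 95% credibility bound.

    ``noren_closed_form`` uses the shrunk observed/expected ratio
    IC = log2((a+1/2)/(E+1/2)) with the closed-form percentile
    approximation for IC025.  ``bate_beta`` is the original normal
    approximation to the beta/Dirichlet posterior moments.
    """
    a = float(t.a)
    n = float(t.n_total)
    e = t.expected
    if variant == "noren_closed_form":
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 / (a + 0.5)
        return ic, ic025
    if variant == "bate_beta":
        a1 = b1 = 1.0  # marginal beta priors
        al = be = 2.0
        g11 = 1.0
        row = a + float(t.b)
        col = a + float(t.c)
        g = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
        ic = math.log2(
            (a + g11) * (n + al) * (n + be) / ((n + g) * (row + a1) * (col + b1))
        )
        var = (
            (n - a + g - g11) / ((a + g11) * (1 + n + g))
            + (n - row + al - a1) / ((row + a1) * (1 + n + al))
            + (n - col + be - b1) / ((col + b1) * (1 + n + be))
        ) / math.log(2) ** 2
        return ic, ic - Z_95 * math.sqrt(var)
    raise ValueError(f"unknown BCPNN variant {variant!r}")


# ---------------------------------------------------------------------------
# MGPS: two-component gamma mixture prior, negative-binomial marginal


def _log_negbin(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Log marginal P(a | alpha, beta, E) for lambda ~ Gamma(alpha, rate beta)."""
    return (
        gammaln(alpha + a)
        - gammaln(alpha)
        - gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _mixture_loglik(
    theta: np.ndarray, a: np.ndarray, e: np.ndarray
) -> float:
    # clip the working parameters: beyond exp(+-30) the likelihood is flat
    # and raw exp overflows during line searches
    la1, lb1, la2, lb2, lw = np.clip(theta, -30.0, 30.0)
    alpha1, beta1 = math.exp(la1), math.exp(lb1)
    alpha2, beta2 = math.exp(la2), math.exp(lb2)
    logw = -np.logaddexp(0.0, -lw)  # log sigmoid
    log1mw = -np.logaddexp(0.0, lw)
    comp = np.stack(
        [
            logw + _log_negbin(a, e, alpha1, beta1),
            log1mw + _log_negbin(a, e, alpha2, beta2),
        ]
    )
    return float(logsumexp(comp, axis=0).sum())


def mixture_marginal_loglik(
    prior: GammaMixturePrior, a: np.ndarray, e: np.ndarray
) -> float:
    """Marginal log-likelihood of counts under a given prior (no fitting)."""
    theta = np.array(
        [
            math.log(prior.alpha1),
            math.log(prior.beta1),
            math.log(prior.alpha2),
            math.log(prior.beta2),
            math.log(prior.w) - math.log1p(-prior.w),
        ]
    )
    return _mixture_loglik(theta, np.asarray(a, float), np.asarray(e, float))


def fit_gamma_mixture(
    tables: Sequence[ContingencyTable],
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
    n_starts: int = 3,
    tol: float = 1e-8,
) -> GammaMixturePrior:
    """Fit the MGPS hyperparameters by marginal maximum likelihood.

    Quasi-Newton (L-BFGS-B) on log/logit-transformed parameters, with
    ``n_starts`` multi-starts (the documented initial point plus fixed-seed
    perturbations); the best optimum wins.

    Raises ``ValueError`` for fewer than 20 usable pairs or all-zero counts.
    """
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    usable = e > 0
    a, e = a[usable], e[usable]
    if len(a) < 20:
        raise ValueError("insufficient pairs (need >= 20 with E > 0)")
    if not np.any(a > 0):
        raise ValueError("degenerate counts (all a = 0)")

    theta0 = np.array(
        [
            math.log(init[0]),
            math.log(init[1]),
            math.log(init[2]),
            math.log(init[3]),
            math.log(init[4]) - math.log1p(-init[4]),
        ]
    )
    rng = np.random.default_rng(20240927)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 0.5, size=5) for _ in range(n_starts - 1)
    ]

    best = None
    for start in starts:
        res = optimize.minimize(
            lambda th: -_mixture_loglik(th, a, e),
            start,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    la1, lb1, la2, lb2, lw = best.x
    prior = GammaMixturePrior(
        alpha1=math.exp(la1),
        beta1=math.exp(lb1),
        alpha2=math.exp(la2),
        beta2=math.exp(lb2),
        w=1.0 / (1.0 + math.exp(-lw)),
        converged=bool(best.success),
        marginal_loglik=-float(best.fun),
        init=init,
    )
    init_ll = _mixture_loglik(theta0, a, e)
    if prior.marginal_loglik < init_ll - 1e-6:
        logger.warning("MGPS fit below initial point (%.3f < %.3f)",
                       prior.marginal_loglik, init_ll)
    return prior


def _posterior_mixture(
    a: float, e: float, prior: GammaMixturePrior
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior weights and Gamma(shape, rate) components given a, E.

    With E = 0 no information accrues and the posterior is the prior
    (shifted by a, which is necessarily 0 in that case).
    """
    if e == 0:
        return (
            np.array([prior.w, 1.0 - prior.w]),
            np.array([prior.alpha1 + a, prior.alpha2 + a]),
            np.array([prior.beta1, prior.beta2]),
        )
    a_arr = np.array([a])
    e_arr = np.array([e])
    lw1 = math.log(prior.w) + _log_negbin(a_arr, e_arr, prior.alpha1, prior.beta1)[0]
    lw2 = math.log1p(-prior.w) + _log_negbin(a_arr, e_arr, prior.alpha2, prior.beta2)[0]
    norm = np.logaddexp(lw1, lw2)
    q = np.exp(np.array([lw1, lw2]) - norm)
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    return q, shapes, rates


def ebgm_score(
    t: ContingencyTable, prior: GammaMixturePrior, percentile: float = 0.05
) -> tuple[Optional[float], Optional[float]]:
    """EBGM (posterior geometric mean of lambda) and EBGM05.

    The posterior is the updated gamma mixture; EBGM = exp(E[ln lambda])
    and EBGM05 solves posterior CDF = ``percentile`` by root-finding on the
    mixture CDF (absolute tolerance well below 1e-8).
    """
    e = t.expected
    q, shapes, rates = _posterior_mixture(float(t.a), e, prior)
    mean_log = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return float(np.sum(q * special.gammainc(shapes, rates * x))) - percentile

    hi = float(np.max((shapes + 10.0 * np.sqrt(shapes)) / rates))
    lo = 1e-12
    while cdf(hi) < 0:
        hi *= 2.0
    ebgm05 = optimize.brentq(cdf, lo, hi, xtol=1e-10)
    return ebgm, ebgm05


def classify_signal(
    s: SignalScores, t: ContingencyTable, thresholds: Optional[Thresholds] = None
) -> SignalDecision:
    """Apply the per-algorithm positivity rules; undefined scores are
    negative for that algorithm."""
    th = thresholds or Thresholds()
    ror_pos = (
        s.ror_lo is not None and t.a >= th.ror_min_a and s.ror_lo > 1.0
    )
    prr_pos = (
        s.prr is not None
        and s.chi2 is not None
        and t.a >= th.prr_min_a
        and s.prr >= th.prr_min
        and s.chi2 >= th.chi2_min
    )
    bcpnn_pos = s.ic025 is not None and s.ic025 > 0.0
    mgps_pos = (
        s.ebgm05 is not None and t.a >= th.mgps_min_a and s.ebgm05 >= th.ebgm05_min
    )
    return SignalDecision(ror_pos, prr_pos, bcpnn_pos, mgps_pos)


@dataclass
class ScoreConfig:
    """Switches for the configurable algorithm variants."""

    ror_ci_z: float = Z_95
    ror_continuity: bool = True
    prr_yates: bool = False
    bcpnn_variant: str = "noren_closed_form"
    mgps_init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3)
    thresholds: Thresholds = field(default_factory=Thresholds)


def score_table(
    t: ContingencyTable,
    prior: Optional[GammaMixturePrior],
    config: Optional[ScoreConfig] = None,
) -> SignalScores:
    """All four statistics for one table (EBGM skipped without a prior)."""
    cfg = config or ScoreConfig()
    s = SignalScores()
    s.ror, s.ror_lo, s.ror_hi = ror_score(t, cfg.ror_ci_z, cfg.ror_continuity)
    if s.ror is None:
        s.undefined["ror"] = "zero_cell_no_correction"
    s.prr, s.chi2 = prr_chi2_score(t, cfg.prr_yates)
    if s.prr is None:
        s.undefined["prr"] = "empty_margin_or_zero_comparator"
    if t.n_total > 0:
        s.ic, s.ic025 = ic_score(t, cfg.bcpnn_variant)
    else:
        s.undefined["ic"] = "empty_table"
    if prior is not None:
        s.ebgm, s.ebgm05 = ebgm_score(t, prior)
        if s.ebgm is None:
            s.undefined["ebgm"] = "zero_expected"
    else:
        s.undefined["ebgm"] = "no_prior"
    return s


def score_tables(
    tables: Sequence[ContingencyTable],
    config: Optional[ScoreConfig] = None,
    prior: Optional[GammaMixturePrior] = None,
) -> tuple[pd.DataFrame, Optional[GammaMixturePrior]]:
    """Score every table, fitting the MGPS prior across them if not given.

    Returns a frame with one row per pair (drug, event, a, the nine score
    columns, the four flags and ``any_of_four``) plus the fitted prior.
    The prior should be fitted on the same granularity it scores.
    """
    cfg = config or ScoreConfig()
    if prior is None:
        try:
            prior = fit_gamma_mixture(tables, init=cfg.mgps_init)
        except ValueError as err:
            logger.warning("MGPS prior not fitted: %s", err)
            prior = None
    rows = []
    for t in tables:
        s = score_table(t, prior, cfg)
        dec = classify_signal(s, t, cfg.thresholds)
        rows.append(
            {
                "drug": t.drug,
                "event": t.event,
                "granularity": t.granularity,
                "a": t.a,
                "expected": t.expected,
                "ror": s.ror,
                "ror_lo": s.ror_lo,
                "ror_hi": s.ror_hi,
                "prr": s.prr,
                "chi2": s.chi2,
                "ic": s.ic,
                "ic025": s.ic025,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "ror_pos": dec.ror_pos,
                "prr_pos": dec.prr_pos,
                "bcpnn_pos": dec.bcpnn_pos,
                "mgps_pos": dec.mgps_pos,
                "any_of_four": dec.any_of_four,
            }
        )
    return pd.DataFrame(rows), prior
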