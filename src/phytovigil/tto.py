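"""Time-to-onset (TTO) analysis with two-parameter Weibull modelling.

TTO for a report is the day count from the earliest full-precision therapy
start of the drug of interest to the event date.  The onset sample is
summarized (median, IQR) and fitted by complete-sample maximum likelihood
to Weibull(alpha, beta), log-likelihood

    l(alpha, beta) = n ln beta - n beta ln alpha + (beta - 1) sum ln t
                     - sum (t / alpha)^beta

with the scale profiled out in closed form and the shape found by Newton
iteration on the profile score (monotone, so globally convergent with a
bracket safeguard).  Wald 95% CIs come from the observed information on
(ln alpha, ln beta).  The shape decides the hazard regime: beta < 1 with
the whole CI below 1 is "early failure" (event incidence declining with
time on treatment), the textbook pattern for infusion-type reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from phytovigil.etl import CaseReport

PROFILE_TOL = 1e-10


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    drug: str
    days: int


@dataclass
class WeibullFit:
    shape_beta: float
    shape_ci: tuple[float, float]
    scale_alpha: float
    scale_ci: tuple[float, float]
    n: int
    loglik: float
    failure_type: str = "indeterminate"


def compute_tto(
    reports: Sequence[CaseReport], drug: str
) -> tuple[list[TTORecord], dict[str, int]]:
    """Onset days per report for one standardized drug name.

    Uses the earliest full-precision therapy start among the report's
    entries for ``drug``.  Reports lacking a full event date or start date,
    or with a negative difference, are excluded and tallied by reason
    (``partial_date``, ``missing``, ``negative``).
    """
    records: list[TTORecord] = []
    excluded = {"negative": 0, "partial_date": 0, "missing": 0}
    for rep in reports:
        entries = [d for d in rep.drugs if d.standard_name == drug]
        if not entries:
            continue
        starts = [d.therapy_start for d in entries if d.therapy_start is not None]
        if not starts:
            if any(d.therapy_start_partial is not None for d in entries):
                excluded["partial_date"] += 1
            else:
                excluded["missing"] += 1
            continue
        if rep.event_date is None:
            if rep.event_date_partial is not None:
                excluded["partial_date"] += 1
            else:
                excluded["missing"] += 1
            continue
        days = (rep.event_date - min(starts)).days
        if days < 0:
            excluded["negative"] += 1
            continue
        records.append(TTORecord(rep.primaryid, drug, days))
    return records, excluded


def summarize_tto(
    records: Sequence[TTORecord] | Sequence[float],
) -> tuple[float, tuple[float, float], int]:
    """Median and IQR of the onset sample (linear-interpolated quantiles)."""
    days = np.array(
        [r.days if isinstance(r, TTORecord) else float(r) for r in records],
        dtype=float,
    )
    if days.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75])
    return float(med), (float(q1), float(q3)), int(days.size)


def _prepare_values(
    records: Sequence[TTORecord] | Sequence[float], zero_policy: str
) -> np.ndarray:
    t = np.array(
        [r.days if isinstance(r, TTORecord) else float(r) for r in records],
        dtype=float,
    )
    if zero_policy == "half_day":
        t = np.where(t == 0.0, 0.5, t)
    elif zero_policy == "exclude":
        t = t[t > 0]
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return t


def weibull_loglik(t: np.ndarray, alpha: float, beta: float) -> float:
    n = len(t)
    return (
        n * math.log(beta)
        - n * beta * math.log(alpha)
        + (beta - 1.0) * float(np.sum(np.log(t)))
        - float(np.sum((t / alpha) ** beta))
    )


def fit_weibull(
    records: Sequence[TTORecord] | Sequence[float],
    zero_policy: str = "half_day",
    ci_level: float = 0.95,
) -> WeibullFit:
    """Complete-sample Weibull MLE with Wald CIs and hazard-shape label.

    Zero-day onsets are mapped to half a day by default (same-day onsets
    are real, and t = 0 breaks the likelihood for beta < 1); set
    ``zero_policy="exclude"`` to drop them instead.
    """
    t = _prepare_values(records, zero_policy)
    n = len(t)
    if n < 10:
        raise ValueError("insufficient sample (need >= 10 positive values)")
    logs = np.log(t)
    if np.ptp(t) == 0.0:
        raise ValueError("degenerate sample (all values identical)")

    # work on u = t / gm(t): same shape, scale recovered at the end
    mean_log = float(np.mean(logs))
    lu = logs - mean_log

    def profile_score(beta: float) -> tuple[float, float]:
        z = beta * lu
        w = np.exp(z - z.max())  # weights only enter as ratios
        s0 = float(np.sum(w))
        r1 = float(np.sum(w * lu)) / s0
        r2 = float(np.sum(w * lu * lu)) / s0
        g = 1.0 / beta + float(np.mean(lu)) - r1
        gprime = -1.0 / beta**2 - (r2 - r1 * r1)
        return g, gprime

    # moment start from the Gumbel relation sd(ln t) = pi / (beta sqrt(6))
    sd_log = float(np.std(lu))
    beta = math.pi / (math.sqrt(6.0) * sd_log) if sd_log > 0 else 1.0
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        g, gp = profile_score(beta)
        if g > 0:
            lo = beta
        else:
            hi = beta
        step = g / gp
        new = beta - step
        if not (lo < new < hi):
            new = 0.5 * (lo + hi)
        if abs(new - beta) < PROFILE_TOL:
            beta = new
            break
        beta = new

    w = np.exp(beta * lu)
    alpha_u = (float(np.sum(w)) / n) ** (1.0 / beta)
    alpha = alpha_u * math.exp(mean_log)

    # observed information on (ln alpha, ln beta)
    theta1 = math.log(alpha)
    m = logs - theta1
    wz = np.exp(beta * m)
    s0 = float(np.sum(wz))
    s1 = float(np.sum(wz * m))
    s2 = float(np.sum(wz * m * m))
    h11 = -(beta**2) * s0
    h12 = beta * (s0 - n) + beta**2 * s1
    score_beta = n / beta + float(np.sum(m)) - s1
    h22 = beta * (score_beta + beta * (-n / beta**2 - s2))
    hess = np.array([[h11, h12], [h12, h22]])
    cov = np.linalg.inv(-hess)
    z = abs(float(np.sqrt(2.0)) * _erfinv_level(ci_level))
    se_la, se_lb = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
    fit = WeibullFit(
        shape_beta=beta,
        shape_ci=(beta * math.exp(-z * se_lb), beta * math.exp(z * se_lb)),
        scale_alpha=alpha,
        scale_ci=(alpha * math.exp(-z * se_la), alpha * math.exp(z * se_la)),
        n=n,
        loglik=weibull_loglik(t, alpha, beta),
    )
    fit.failure_type = classify_failure_type(fit)
    return fit


def _erfinv_level(level: float) -> float:
    from scipy.special import erfinv

    return float(erfinv(level))


def classify_failure_type(fit: WeibullFit) -> str:
    """Hazard regime from the shape CI.

    early: whole CI below 1 (decreasing hazard); wear_out: whole CI above
    1 (increasing hazard); random: CI contains 1 (memoryless); otherwise
    indeterminate.
    """
    lo, hi = fit.shape_ci
    if not (math.isfinite(lo) and math.isfinite(hi)):
        return "indeterminate"
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear_out"
    return "random"


def weibull_median(alpha: float, beta: float) -> float:
    """Closed-form Weibull median alpha * (ln 2)^(1/beta)."""
    return alpha * math.log(2.0) ** (1.0 / beta)


def tto_histogram(
    records: Sequence[TTORecord], bin_days: int = 30, n_bins: Optional[int] = None
) -> "pd.DataFrame":
    """Counts of onsets in fixed-width day bins (default 30-day)."""
    import pandas as pd

    days = np.array([r.days for r in records])
    if n_bins is None:
        n_bins = int(days.max() // bin_days) + 1 if days.size else 1
    edges = np.arange(0, (n_bins + 1) * bin_days, bin_days)
    counts, _ = np.histogram(days, bins=edges)
    return pd.DataFrame(
        {
            "bin_start_day": edges[:-1],
            "bin_end_day": edges[1:],
            "count": counts,
        }
    )
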