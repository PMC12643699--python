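"""Score formulas vs independent oracles; MGPS posterior math; thresholds."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from phytovigil.contingency import ContingencyTable
from phytovigil.disproportionality import (
    GammaMixturePrior,
    SignalScores,
    Thresholds,
    classify_signal,
    ebgm_score,
    fit_gamma_mixture,
    ic_score,
    mixture_marginal_loglik,
    prr_chi2_score,
    ror_score,
    score_tables,
)


def table(a, b, c, d):
    return ContingencyTable("D", "E", "PT", a, b, c, d)


UNIT_PRIOR = GammaMixturePrior(1.0, 1.0, 1.0, 1.0, 0.5)


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_score(table(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_arithmetic(self):
        ror, _, _ = ror_score(table(20, 80, 100, 1900))
        assert ror == pytest.approx((20 * 1900) / (80 * 100))

    def test_continuity_correction_on_zero_cell(self):
        ror, lo, hi = ror_score(table(2, 1, 2, 0))
        expect = (2.5 * 0.5) / (1.5 * 2.5)
        se = math.sqrt(1 / 2.5 + 1 / 1.5 + 1 / 2.5 + 1 / 0.5)
        assert ror == pytest.approx(expect)
        assert lo == pytest.approx(expect * math.exp(-1.959963984540054 * se))

    def test_zero_cell_without_correction_is_undefined(self):
        assert ror_score(table(2, 1, 2, 0), continuity=False) == (None, None, None)


class TestPrrChi2:
    def test_independence(self):
        prr, chi2 = prr_chi2_score(table(10, 10, 10, 10))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        prr, chi2 = prr_chi2_score(table(20, 80, 100, 1900))
        assert prr == pytest.approx(4.0)
        assert chi2 == pytest.approx(39.77, abs=0.005)

    def test_chi2_matches_scipy(self):
        t = table(20, 80, 100, 1900)
        _, chi2 = prr_chi2_score(t)
        oracle = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        ).statistic
        assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_zero_comparator_undefined(self):
        prr, _ = prr_chi2_score(table(5, 5, 0, 10))
        assert prr is None


class TestIc:
    def test_zero_when_observed_equals_expected(self):
        # a = 10, margins chosen so E = (a+b)(a+c)/N = 10
        t = table(10, 10, 10, 10)
        ic, _ = ic_score(t)
        assert ic == pytest.approx(0.0)

    def test_closed_form_example(self):
        t = table(20, 80, 100, 1900)
        ic, ic025 = ic_score(t)
        e = 120 * 100 / 2100
        assert ic == pytest.approx(math.log2(20.5 / (e + 0.5)), rel=1e-12)
        assert ic == pytest.approx(1.722, abs=5e-4)
        assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(20.5) - 2.4 / 20.5)
        assert ic025 == pytest.approx(0.876, abs=5e-4)

    def test_negative_for_zero_count_with_large_expected(self):
        ic, _ = ic_score(table(0, 100, 100, 100))
        assert ic < 0

    def test_bate_variant_shrinks_toward_zero(self):
        t = table(20, 80, 100, 1900)
        ic_b, ic025_b = ic_score(t, variant="bate_beta")
        ic_n, _ = ic_score(t)
        assert 0 < ic_b < math.log2(20 / t.expected)
        assert ic025_b < ic_b
        assert ic_b == pytest.approx(ic_n, abs=0.3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ic_score(table(1, 1, 1, 1), variant="nope")


def random_tables(rng, n, hi=10_000):
    out = []
    for _ in range(n):
        a, b, c, d = (int(rng.integers(0, hi)) for _ in range(4))
        if a + b + c + d == 0:
            a = 1
        out.append(table(a, b, c, d))
    return out


def test_oracle_equivalence_on_random_tables():
    """ROR/PRR/chi2/IC match direct formula evaluation to rel 1e-10."""
    rng = np.random.default_rng(123)
    for t in random_tables(rng, 1000):
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
        n = a + b + c + d
        ror, lo, hi = ror_score(t)
        aa, bb, cc, dd = (a, b, c, d) if min(a, b, c, d) > 0 else (
            a + 0.5, b + 0.5, c + 0.5, d + 0.5
        )
        assert ror == pytest.approx(aa * dd / (bb * cc), rel=1e-10)
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        assert lo == pytest.approx(
            math.exp(math.log(aa * dd / (bb * cc)) - 1.959963984540054 * se),
            rel=1e-10,
        )
        prr, chi2 = prr_chi2_score(t)
        if a + b > 0 and c > 0:
            assert prr == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-10)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom > 0:
            assert chi2 == pytest.approx(
                n * (a * d - b * c) ** 2 / denom, rel=1e-10
            )
        ic, ic025 = ic_score(t)
        e = (a + b) * (a + c) / n
        assert ic == pytest.approx(math.log2((a + 0.5) / (e + 0.5)), rel=1e-10)
        assert ic025 == pytest.approx(
            ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.0, rel=1e-10
        )


def test_ror_prr_monotone_in_a_with_cells_fixed():
    """With b, c, d fixed, ROR and PRR are nondecreasing in a."""
    prev = None
    for a in [0, 1, 2, 5, 10, 50, 200, 1000]:
        t = table(a, 50, 80, 5000)
        ror, _, _ = ror_score(t)
        prr, _ = prr_chi2_score(t)
        prr = prr if prr is not None else 0.0
        if prev is not None:
            assert (ror, prr) >= prev
        prev = (ror, prr)


def test_ic_ebgm_monotone_in_a_with_expected_fixed():
    """Holding the expected count E, IC and EBGM grow with the observed a.

    (With b, c, d literally fixed, E itself grows superlinearly in a and
    the shrunk observed/expected statistics eventually turn over, so the
    meaningful monotonicity is at fixed E.)
    """
    prev = None
    for a in [0, 1, 2, 5, 10, 50, 200, 1000]:
        e = 5.0
        n_tot = 1_000_000
        c = 2000
        b = round(e * n_tot / (a + c)) - a
        t = table(a, b, c, n_tot - a - b - c)
        ic, _ = ic_score(t)
        ebgm, _ = ebgm_score(t, UNIT_PRIOR)
        if prev is not None:
            assert (ic, ebgm) >= prev
        prev = (ic, ebgm)


class TestEbgm:
    def test_degenerate_prior_digamma_closed_form(self):
        # unit-gamma components collapse the mixture: posterior is
        # Gamma(1 + a, rate 1 + E), EBGM = exp(psi(1 + a)) / (1 + E)
        t = table(20, 100, 80, 1900)  # E = 120*100/2100 = 5.7143
        e = t.expected
        assert e == pytest.approx(40.0 / 7.0)
        ebgm, _ = ebgm_score(t, UNIT_PRIOR)
        assert ebgm == pytest.approx(
            math.exp(special.digamma(21)) / (1 + e), abs=1e-8
        )
        assert ebgm == pytest.approx(3.054, abs=2e-3)

    def test_zero_count_small_expected(self):
        # a = 0 with E -> 0: posterior ~ Gamma(1,1), EBGM = exp(psi(1))
        t = table(0, 1, 0, 100_000)
        ebgm, _ = ebgm_score(t, UNIT_PRIOR)
        assert ebgm == pytest.approx(math.exp(special.digamma(1)), abs=1e-4)

    @pytest.mark.parametrize(
        "prior",
        [
            UNIT_PRIOR,
            GammaMixturePrior(0.3, 0.2, 3.0, 4.0, 0.25),
        ],
    )
    @pytest.mark.parametrize("cells", [(20, 100, 80, 1900), (3, 10, 40, 500)])
    def test_ebgm05_matches_quadrature(self, prior, cells):
        t = table(*cells)
        e = t.expected
        _, ebgm05 = ebgm_score(t, prior)

        def posterior_pdf(x):
            lw1 = math.log(prior.w) + stats.nbinom.logpmf(
                t.a, prior.alpha1, prior.beta1 / (prior.beta1 + e)
            )
            lw2 = math.log1p(-prior.w) + stats.nbinom.logpmf(
                t.a, prior.alpha2, prior.beta2 / (prior.beta2 + e)
            )
            m = max(lw1, lw2)
            q1 = math.exp(lw1 - m)
            q2 = math.exp(lw2 - m)
            q1, q2 = q1 / (q1 + q2), q2 / (q1 + q2)
            return q1 * stats.gamma.pdf(x, prior.alpha1 + t.a,
                                        scale=1 / (prior.beta1 + e)) + \
                q2 * stats.gamma.pdf(x, prior.alpha2 + t.a,
                                     scale=1 / (prior.beta2 + e))

        mass, _ = integrate.quad(posterior_pdf, 0, ebgm05, limit=200)
        assert mass == pytest.approx(0.05, abs=1e-6)

    def test_shrinkage_vanishes_for_large_counts(self):
        ratio = 4.0
        gaps = []
        for a in [10, 100, 10_000]:
            # margins arranged so a / E = ratio
            e = a / ratio
            c = 1000
            n_tot = 1_000_000
            b = round(e * n_tot / (a + c)) - a
            t = table(a, b, c, n_tot - a - b - c)
            assert t.expected == pytest.approx(e, rel=0.01)
            ebgm, ebgm05 = ebgm_score(t, UNIT_PRIOR)
            assert ebgm05 < ebgm
            gaps.append(abs(ebgm - t.a / t.expected))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] / ratio < 0.01


def test_large_count_ic_and_ebgm_converge_to_ratio():
    """For a >= 500 with a/E = r: IC -> log2 r and EBGM -> r within 5%."""
    for a, r in [(500, 2.0), (2000, 8.0)]:
        e = a / r
        n_tot = 2_000_000
        c = 5000
        b = round(e * n_tot / (a + c)) - a
        t = table(a, b, c, n_tot - a - b - c)
        ic, _ = ic_score(t)
        ebgm, _ = ebgm_score(t, UNIT_PRIOR)
        assert ic == pytest.approx(math.log2(t.a / t.expected), rel=0.05)
        assert ebgm == pytest.approx(t.a / t.expected, rel=0.05)


class TestGammaMixtureFit:
    def test_insufficient_pairs(self):
        with pytest.raises(ValueError, match="insufficient pairs"):
            fit_gamma_mixture([table(1, 2, 3, 4)] * 5)

    def test_degenerate_counts(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gamma_mixture([table(0, 5, 5, 100)] * 30)

    def test_init_recorded_in_metadata(self):
        rng = np.random.default_rng(5)
        tables = simulate_mixture_tables(rng, 200)
        prior = fit_gamma_mixture(tables)
        assert prior.init == (0.2, 0.1, 2.0, 4.0, 1 / 3)
        assert prior.converged

    def test_recovery_from_known_prior(self):
        rng = np.random.default_rng(2024)
        truth = GammaMixturePrior(0.5, 0.6, 4.0, 2.0, 0.4)
        tables = simulate_mixture_tables(rng, 5000, truth)
        fit = fit_gamma_mixture(tables)
        a = np.array([t.a for t in tables], float)
        e = np.array([t.expected for t in tables], float)
        ll_truth = mixture_marginal_loglik(truth, a, e)
        assert fit.marginal_loglik >= ll_truth - 2.0


def simulate_mixture_tables(rng, n_cells, prior=None):
    """Counts drawn from the gamma-mixture Poisson model, wrapped in tables
    whose margins reproduce the wanted E to high accuracy."""
    prior = prior or GammaMixturePrior(0.5, 0.6, 4.0, 2.0, 0.4)
    comp = rng.random(n_cells) < prior.w
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1 / prior.beta1, n_cells),
        rng.gamma(prior.alpha2, 1 / prior.beta2, n_cells),
    )
    e = np.exp(rng.uniform(np.log(0.5), np.log(50.0), n_cells))
    a = rng.poisson(lam * e)
    tables = []
    n_tot = 10_000_000
    for ai, ei in zip(a, e):
        c = 2000
        b = round(ei * n_tot / (ai + c)) - ai
        tables.append(table(int(ai), int(b), c, n_tot - int(ai) - int(b) - c))
    return tables


class TestClassify:
    def test_boundary_ror_lo_exactly_one_is_negative(self):
        s = SignalScores(ror=1.5, ror_lo=1.0, ror_hi=2.0)
        dec = classify_signal(s, table(10, 10, 10, 10))
        assert not dec.ror_pos

    def test_strong_ror_row_is_positive(self):
        # a = 2965 with lower CI 3.29 (dyspnoea-scale signal)
        s = SignalScores(ror=3.42, ror_lo=3.29, ror_hi=3.54)
        dec = classify_signal(s, table(2965, 28042, 100000, 800000))
        assert dec.ror_pos and dec.any_of_four

    def test_all_undefined_scores_flag_nothing(self):
        dec = classify_signal(SignalScores(), table(10, 10, 10, 10))
        assert not dec.any_of_four

    def test_thresholds_respected(self):
        s = SignalScores(prr=2.5, chi2=10.0)
        assert classify_signal(s, table(2, 8, 10, 80)).prr_pos is False  # a < 3
        assert classify_signal(s, table(3, 7, 10, 80)).prr_pos is True
        th = Thresholds(prr_min=3.0)
        assert classify_signal(s, table(3, 7, 10, 80), th).prr_pos is False


def test_score_tables_without_enough_pairs_skips_mgps():
    frame, prior = score_tables([table(5, 5, 5, 5)])
    assert prior is None
    assert frame["ebgm"].isna().all()
    assert not frame["mgps_pos"].any()
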