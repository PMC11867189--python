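import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mmcoal.measures import (
    BetaMeasure,
    ContinuousMeasure,
    DiscreteMeasure,
    KingmanMeasure,
    RateTable,
    StarMeasure,
    beta_measure,
    block_size_pmf,
    demo_discrete_measure,
    merger_rate,
    total_rate,
    total_rate_approx,
    truncated_normal_measure,
)
from scipy.stats import beta as beta_dist


def quadrature_rate(density, b, k):
    """Independent oracle: adaptive quadrature of x^(k-2)(1-x)^(b-k) density."""
    val, _ = quad(lambda x: x ** (k - 2) * (1 - x) ** (b - k) * density(x), 0, 1,
                  limit=200)
    return val


class TestMergerRate:
    def test_kingman_pair_rate_is_one(self):
        assert merger_rate(KingmanMeasure(), 7, 2) == 1.0
        for b in range(2, 101):
            assert merger_rate(KingmanMeasure(), b, 2) == 1.0

    def test_kingman_no_multiple_mergers(self):
        assert merger_rate(KingmanMeasure(), 7, 3) == 0.0

    def test_star_only_full_merger(self):
        assert merger_rate(StarMeasure(), 5, 5) == 1.0
        assert merger_rate(StarMeasure(), 5, 3) == 0.0

    def test_bolthausen_sznitman_small_cases(self):
        # oracle: quadrature against the Beta(1,1) = uniform density
        assert merger_rate(beta_measure(1.0), 3, 2) == pytest.approx(
            quadrature_rate(lambda x: 1.0, 3, 2), rel=1e-10
        )
        assert merger_rate(beta_measure(1.0), 3, 2) == pytest.approx(0.5)
        assert merger_rate(beta_measure(1.0), 4, 3) == pytest.approx(1 / 6)

    def test_bolthausen_sznitman_factorial_form(self):
        for b in range(2, 51):
            for k in range(2, b + 1):
                closed = (
                    math.factorial(k - 2) * math.factorial(b - k) / math.factorial(b - 1)
                )
                assert merger_rate(beta_measure(1.0), b, k) == pytest.approx(
                    closed, rel=1e-8
                )

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 1.5, 1.9])
    def test_beta_closed_form_matches_quadrature(self, alpha):
        # full integrand is x^{(k-alpha)-1} (1-x)^{(b-k+alpha)-1} / B(2-alpha, alpha);
        # the algebraic endpoint singularities go into the quadrature weight
        norm = beta_dist(2 - alpha, alpha).pdf(0.5)  # = 1 / B(2-alpha, alpha)
        for b in (2, 3, 7, 20, 50):
            for k in (2, 3, b // 2 + 1, b):
                if k < 2 or k > b:
                    continue
                oracle, _ = quad(
                    lambda x: norm,
                    0,
                    1,
                    weight="alg",
                    wvar=(k - alpha - 1, b - k + alpha - 1),
                    limit=200,
                )
                assert merger_rate(BetaMeasure(alpha), b, k) == pytest.approx(
                    oracle, rel=1e-8
                )

    def test_beta_alpha2_is_kingman(self):
        meas = beta_measure(2.0)
        assert merger_rate(meas, 10, 2) == 1.0
        assert merger_rate(meas, 10, 3) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            merger_rate(KingmanMeasure(), 1, 2)
        with pytest.raises(ValueError):
            merger_rate(KingmanMeasure(), 5, 1)
        with pytest.raises(ValueError):
            merger_rate(KingmanMeasure(), 5, 6)
        with pytest.raises(ValueError):
            BetaMeasure(0.0)
        with pytest.raises(ValueError):
            BetaMeasure(2.5)


class TestTotalRate:
    def test_kingman(self):
        assert total_rate(KingmanMeasure(), 10) == pytest.approx(45.0)

    def test_star(self):
        assert total_rate(StarMeasure(), 8) == pytest.approx(1.0)

    def test_bolthausen_sznitman_b4_brute_force(self):
        # 6 * lam(4,2) + 4 * lam(4,3) + 1 * lam(4,4), each from quadrature
        lam = [quadrature_rate(lambda x: 1.0, 4, k) for k in (2, 3, 4)]
        brute = 6 * lam[0] + 4 * lam[1] + 1 * lam[2]
        assert brute == pytest.approx(3.0, rel=1e-10)
        assert total_rate(beta_measure(1.0), 4) == pytest.approx(brute, rel=1e-10)

    def test_increasing_in_alpha(self):
        for b in (3, 10, 50):
            rates = [total_rate(beta_measure(a), b) for a in np.arange(0.5, 2.0, 0.1)]
            assert np.all(np.diff(rates) > 0)


class TestBlockSizePmf:
    def test_kingman_point_mass_at_2(self):
        pmf = block_size_pmf(KingmanMeasure(), 6)
        assert pmf[0] == pytest.approx(1.0)
        assert np.all(pmf[1:] == 0.0)

    def test_star_point_mass_at_b(self):
        pmf = block_size_pmf(StarMeasure(), 6)
        assert pmf[-1] == pytest.approx(1.0)

    def test_bolthausen_sznitman_b3(self):
        pmf = block_size_pmf(beta_measure(1.0), 3)
        assert pmf == pytest.approx([0.75, 0.25])

    def test_sums_to_one(self):
        for alpha in (0.3, 1.0, 1.7):
            for b in (2, 10, 100):
                assert block_size_pmf(beta_measure(alpha), b).sum() == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_kingman_limit_as_alpha_to_2(self):
        for b in (10, 100):
            pmf = block_size_pmf(beta_measure(1.999), b)
            assert pmf[0] >= 1 - 1e-3

    def test_mean_block_size_decreasing_in_alpha(self):
        for b in (10, 50):
            ks = np.arange(2, b + 1)
            means = [
                float(ks @ block_size_pmf(beta_measure(a), b))
                for a in np.arange(0.5, 1.95, 0.1)
            ]
            assert np.all(np.diff(means) < 0)


class TestTotalRateApprox:
    def test_kingman_limit_exact(self):
        assert total_rate_approx(2.0, 10) == pytest.approx(45.0)
        assert total_rate_approx(2.0, 10) == pytest.approx(
            total_rate(beta_measure(2.0), 10)
        )

    def test_bolthausen_sznitman_exact(self):
        assert total_rate_approx(1.0, 4) == pytest.approx(3.0)
        assert total_rate_approx(1.0, 4) == pytest.approx(
            total_rate(beta_measure(1.0), 4)
        )

    def test_relative_error_documented_regime(self):
        # observed relative error is ~6% at alpha=1.5, b=50
        exact = total_rate(beta_measure(1.5), 50)
        approx = total_rate_approx(1.5, 50)
        assert approx > 0
        assert abs(approx - exact) / exact < 0.10


class TestConsistency:
    """lambda_{b,k} = lambda_{b+1,k} + lambda_{b+1,k+1} across families."""

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 1.5, 1.9])
    def test_beta(self, alpha):
        RateTable(BetaMeasure(alpha), 50).check_consistency(rtol=1e-8)

    def test_kingman_star(self):
        RateTable(KingmanMeasure(), 50).check_consistency(rtol=1e-8)
        RateTable(StarMeasure(), 50).check_consistency(rtol=1e-8)

    def test_discrete_demo(self):
        RateTable(demo_discrete_measure(), 50).check_consistency(rtol=1e-8)

    def test_truncated_normal_continuous(self):
        RateTable(truncated_normal_measure(), 12).check_consistency(rtol=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(
        atoms=st.lists(
            st.tuples(
                st.floats(0.01, 0.99), st.floats(0.1, 5.0)
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_random_discrete_measures(self, atoms):
        RateTable(DiscreteMeasure(atoms), 15).check_consistency(rtol=1e-8)


class TestRateTable:
    def test_matches_direct_evaluation(self):
        meas = beta_measure(1.3)
        rt = RateTable(meas, 20)
        assert np.exp(rt.log_rate(17, 5)) == pytest.approx(merger_rate(meas, 17, 5))
        assert rt.total_rate(17) == pytest.approx(total_rate(meas, 17))
        assert rt.pmf(17) == pytest.approx(block_size_pmf(meas, 17))

    def test_continuous_matches_beta_family(self):
        # user-supplied density equal to Beta(0.5, 1.5) pdf must reproduce
        # the closed-form family rates
        alpha = 1.5
        density = beta_dist(2 - alpha, alpha).pdf
        cm = ContinuousMeasure(density)
        for b, k in [(2, 2), (5, 3), (8, 8)]:
            assert merger_rate(cm, b, k) == pytest.approx(
                merger_rate(BetaMeasure(alpha), b, k), rel=1e-7
            )
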