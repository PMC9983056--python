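"""Distribution core: exactness against naive enumeration, reductions,
association/dispersion directions, and sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from jointbin.extended_binomial import (
    BivBinomParams,
    ExtBinomParams,
    _mh_sample,
    biv_log_pmf,
    biv_moments,
    biv_normalizer,
    biv_pmf_table,
    biv_sample,
    uni_log_pmf,
    uni_normalizer,
    uni_pmf,
)
from oracles import naive_biv_moments, naive_biv_table, naive_uni_pmf


def random_params(rng) -> BivBinomParams:
    return BivBinomParams(
        m1=int(rng.integers(1, 11)),
        m2=int(rng.integers(1, 11)),
        p1=float(rng.uniform(0.05, 0.95)),
        p2=float(rng.uniform(0.05, 0.95)),
        theta1=float(rng.uniform(0.5, 2.0)),
        theta2=float(rng.uniform(0.5, 2.0)),
        phi=float(rng.uniform(0.5, 2.0)),
    )


class TestUnivariate:
    @pytest.mark.parametrize(
        "m,p,theta,expected",
        [
            (2, 0.5, 1.0, 1.0),    # theta=1 is the normalized binomial
            (2, 0.5, 2.0, 1.5),    # 0.25 + 0.5*2 + 0.25 by hand
            (1, 0.3, 7.0, 1.0),    # y*(m-y)=0 everywhere when m=1
        ],
    )
    def test_normalizer_closed_forms(self, m, p, theta, expected):
        assert uni_normalizer(ExtBinomParams(m, p, theta)) == pytest.approx(
            expected, abs=1e-14
        )

    def test_log_pmf_binomial_and_bernoulli_reductions(self):
        assert uni_log_pmf(ExtBinomParams(10, 0.5, 1.0), 5) == pytest.approx(
            math.log(math.comb(10, 5) / 1024), abs=1e-13
        )
        for theta in (0.3, 1.0, 5.0):
            assert uni_log_pmf(ExtBinomParams(1, 0.3, theta), 1) == pytest.approx(
                math.log(0.3), abs=1e-13
            )

    def test_log_pmf_matches_naive_enumeration(self):
        oracle = naive_uni_pmf(10, 0.4, 1.2)
        params = ExtBinomParams(10, 0.4, 1.2)
        for y in range(11):
            assert math.exp(uni_log_pmf(params, y)) == pytest.approx(
                oracle[y], abs=1e-14
            )

    def test_dispersion_direction_relative_to_binomial(self):
        """theta > 1 is under- and theta < 1 over-dispersed relative to the
        binomial with the same mean.

        At p = 0.5 the mean is fixed at m/2 and the comparison against
        m*p*(1-p) is direct; for asymmetric p the theta factor also shifts
        the mean, so the fair binomial reference is the one matching the
        realized mean (at fixed p the literal comparison can invert).
        """
        rng = np.random.default_rng(2718)
        for m in range(2, 11):
            for theta, cmp in [(1.6, np.less), (0.6, np.greater), (3.0, np.less)]:
                y = np.arange(m + 1)
                pmf = uni_pmf(ExtBinomParams(m, 0.5, theta))
                var = pmf @ (y - m / 2) ** 2
                assert cmp(var, m * 0.25)
        for _ in range(100):
            m = int(rng.integers(2, 11))
            p = float(rng.uniform(0.05, 0.95))
            theta = float(rng.uniform(0.3, 3.0))
            if abs(theta - 1.0) < 0.05:
                continue
            y = np.arange(m + 1)
            pmf = uni_pmf(ExtBinomParams(m, p, theta))
            mu = pmf @ y
            var = pmf @ (y - mu) ** 2
            pm = mu / m
            assert (var < m * pm * (1 - pm)) == (theta > 1)

    def test_domain_errors_name_offending_field(self):
        with pytest.raises(ValueError, match="p "):
            ExtBinomParams(2, 1.5, 1.0)
        with pytest.raises(ValueError, match="theta"):
            ExtBinomParams(2, 0.5, -1.0)
        with pytest.raises(ValueError, match="y="):
            uni_log_pmf(ExtBinomParams(2, 0.5, 1.0), 3)


class TestBivariate:
    def test_normalizer_independence_and_2x2_closed_forms(self):
        p = BivBinomParams(3, 4, 0.2, 0.7, 1.0, 1.0, 1.0)
        assert biv_normalizer(p) == pytest.approx(1.0, abs=1e-14)
        for p1, p2, phi in [(0.3, 0.6, 2.0), (0.5, 0.5, 0.4)]:
            p = BivBinomParams(1, 1, p1, p2, 1.0, 1.0, phi)
            # only the (1,1) cell carries phi
            assert biv_normalizer(p) == pytest.approx(
                1 + p1 * p2 * (phi - 1), abs=1e-14
            )

    def test_log_pmf_independence_factorization(self):
        p = BivBinomParams(5, 7, 0.3, 0.8, 1.0, 1.0, 1.0)
        for y1, y2 in [(0, 0), (2, 5), (5, 7)]:
            assert biv_log_pmf(p, y1, y2) == pytest.approx(
                uni_log_pmf(p.margin(1), y1) + uni_log_pmf(p.margin(2), y2),
                abs=1e-12,
            )

    def test_log_pmf_hand_worked_2x2(self):
        p = BivBinomParams(1, 1, 0.5, 0.5, 1.0, 1.0, 2.0)
        assert biv_log_pmf(p, 1, 1) == pytest.approx(math.log(0.5 / 1.25), abs=1e-14)

    def test_table_properties(self):
        p = BivBinomParams(6, 9, 0.35, 0.6, 1.4, 0.8, 1.2)
        tab = biv_pmf_table(p)
        assert tab.shape == (7, 10)
        assert np.all(tab >= 0)
        assert tab.sum() == pytest.approx(1.0, abs=1e-12)
        swapped = BivBinomParams(9, 6, 0.6, 0.35, 0.8, 1.4, 1.2)
        np.testing.assert_allclose(biv_pmf_table(swapped), tab.T, atol=1e-14)
        indep = BivBinomParams(6, 9, 0.35, 0.6, 1.0, 1.0, 1.0)
        outer = np.outer(
            uni_pmf(indep.margin(1)), uni_pmf(indep.margin(2))
        )
        np.testing.assert_allclose(biv_pmf_table(indep), outer, atol=1e-14)

    def test_moments_independent_case(self):
        p = BivBinomParams(8, 5, 0.25, 0.6, 1.0, 1.0, 1.0)
        m1, m2, v1, v2, corr = biv_moments(p)
        assert m1 == pytest.approx(8 * 0.25, abs=1e-12)
        assert m2 == pytest.approx(5 * 0.6, abs=1e-12)
        assert v1 == pytest.approx(8 * 0.25 * 0.75, abs=1e-12)
        assert corr == pytest.approx(0.0, abs=1e-12)

    def test_association_sign_follows_phi(self):
        base = dict(m1=10, m2=10, p1=0.5, p2=0.5, theta1=1.0, theta2=1.0)
        assert biv_moments(BivBinomParams(**base, phi=1.3))[4] > 0
        assert biv_moments(BivBinomParams(**base, phi=0.7))[4] < 0

    def test_correlation_strictly_increasing_in_phi(self):
        """Correlation rises with phi across the grid on a small support.

        On large supports the association factor eventually piles all
        mass onto a corner of the table and the correlation collapses
        back toward 0, so global monotonicity over a wide phi grid is a
        small-support property; near phi = 1 it holds for any support
        (checked separately via the sign test above).
        """
        corrs = [
            biv_moments(BivBinomParams(3, 3, 0.5, 0.4, 1.0, 1.0, phi))[4]
            for phi in (0.5, 0.8, 1.0, 1.3, 2.0)
        ]
        assert np.all(np.diff(corrs) > 0)
        neutral = biv_moments(BivBinomParams(10, 10, 0.5, 0.4, 1.0, 1.0, 1.0))[4]
        assert neutral == pytest.approx(0.0, abs=1e-12)
        # local monotonicity around phi = 1 on the full 0..10 support
        local = [
            biv_moments(BivBinomParams(10, 10, 0.5, 0.4, 1.0, 1.0, phi))[4]
            for phi in (0.9, 1.0, 1.1)
        ]
        assert np.all(np.diff(local) > 0)

    def test_oracle_equivalence_on_random_parameter_sets(self):
        """pmf tables, normalizers and moments agree with the literal
        double-loop oracle on >= 100 random parameter draws."""
        rng = np.random.default_rng(31415)
        for _ in range(120):
            p = random_params(rng)
            oracle_tab = naive_biv_table(
                p.m1, p.m2, p.p1, p.p2, p.theta1, p.theta2, p.phi
            )
            tab = biv_pmf_table(p)
            np.testing.assert_allclose(tab, oracle_tab, atol=1e-12, rtol=1e-12)
            assert tab.sum() == pytest.approx(1.0, abs=1e-12)
            om = naive_biv_moments(oracle_tab)
            mm = biv_moments(p)
            np.testing.assert_allclose(mm, om, atol=1e-12, rtol=1e-12)
            # a random cell through the scalar log-pmf path
            y1 = int(rng.integers(0, p.m1 + 1))
            y2 = int(rng.integers(0, p.m2 + 1))
            assert math.exp(biv_log_pmf(p, y1, y2)) == pytest.approx(
                oracle_tab[y1, y2], abs=1e-12, rel=1e-12
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        m1=st.integers(0, 10),
        m2=st.integers(0, 10),
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        t1=st.floats(0.2, 5.0),
        t2=st.floats(0.2, 5.0),
        phi=st.floats(0.2, 5.0),
    )
    def test_normalization_property(self, m1, m2, p1, p2, t1, t2, phi):
        p = BivBinomParams(m1, m2, p1, p2, t1, t2, phi)
        total = sum(
            math.exp(biv_log_pmf(p, a, b))
            for a in range(m1 + 1)
            for b in range(m2 + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestSampling:
    def test_empty_draw(self, rng):
        p = BivBinomParams(3, 3, 0.5, 0.5, 1.0, 1.0, 1.0)
        assert biv_sample(p, 0, rng).shape == (0, 2)

    def test_binomial_case_means(self, rng):
        p = BivBinomParams(10, 8, 0.3, 0.6, 1.0, 1.0, 1.0)
        draws = biv_sample(p, 20_000, rng)
        for j, (m, prob) in enumerate([(10, 0.3), (8, 0.6)]):
            se = math.sqrt(m * prob * (1 - prob) / 20_000)
            assert abs(draws[:, j].mean() - m * prob) < 4 * se

    def test_reproducible_under_fixed_seed(self):
        p = BivBinomParams(10, 10, 0.5, 0.4, 1.1, 0.9, 1.3)
        a = biv_sample(p, 50, np.random.default_rng(7))
        b = biv_sample(p, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_goodness_of_fit_and_mh_cross_check(self, rng):
        p = BivBinomParams(5, 5, 0.45, 0.55, 1.2, 0.85, 1.25)
        tab = biv_pmf_table(p)
        n = 10_000

        def gof(draws):
            counts = np.zeros_like(tab)
            np.add.at(counts, (draws[:, 0], draws[:, 1]), 1)
            keep = tab.ravel() * len(draws) >= 5
            obs = counts.ravel()[keep]
            exp = tab.ravel()[keep] * len(draws)
            obs = np.append(obs, len(draws) - obs.sum())
            exp = np.append(exp, len(draws) - exp.sum())
            if exp[-1] <= 0:
                obs, exp = obs[:-1], exp[:-1]
            return chisquare(obs, exp * obs.sum() / exp.sum()).pvalue

        assert gof(biv_sample(p, n, rng)) > 1e-3
        assert gof(_mh_sample(p, n, rng)) > 1e-3
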