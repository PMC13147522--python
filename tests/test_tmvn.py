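"""Truncated multivariate normal numerics against closed forms, a
rejection-sampling oracle and internal cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from thrlin import tmvn
from thrlin.tmvn import (
    TruncationRegion, TmvnError, bivariate_truncated_moments, bvn_rectangle,
    mvn_probability, tmvn_cov, tmvn_mean, tmvn_mc_oracle, tmvn_moments,
    univariate_batch, univariate_moments,
)

from conftest import make_spd


LAMBDA0 = norm.pdf(0) / norm.sf(0)  # inverse Mills ratio at zero


class TestMvnProbability:
    def test_total_mass(self):
        S = make_spd(3, np.random.default_rng(0))
        p = mvn_probability([-np.inf] * 3, [np.inf] * 3, np.zeros(3), S)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_univariate_symmetry(self):
        assert mvn_probability([0], [np.inf], [0], [[1.0]]) == pytest.approx(0.5)

    @pytest.mark.parametrize("rho", [-0.8, -0.3, 0.0, 0.5, 0.9])
    def test_orthant_closed_form(self, rho):
        # P(X>0, Y>0) = 1/4 + arcsin(rho) / (2 pi) for standard margins
        S = np.array([[1, rho], [rho, 1.0]])
        p = mvn_probability([0, 0], [np.inf, np.inf], [0, 0], S)
        assert p == pytest.approx(0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-12)

    def test_bvn_rectangle_matches_scipy(self):
        rng = np.random.default_rng(3)
        S = np.array([[1.3, 0.6], [0.6, 0.9]])
        s1, s2 = np.sqrt(np.diag(S))
        rho = S[0, 1] / (s1 * s2)
        for _ in range(20):
            lo = rng.normal(size=2) - 1.5
            hi = lo + rng.uniform(0.5, 3, size=2)
            mu = rng.normal(size=2)
            ours = bvn_rectangle(lo[0], hi[0], lo[1], hi[1], mu[0], mu[1],
                                 s1, s2, rho)
            ref = multivariate_normal.cdf(hi, mean=mu, cov=S, lower_limit=lo,
                                          abseps=1e-12, releps=0.0,
                                          rng=np.random.default_rng(0))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_partition_sums_to_one(self):
        # boxes partitioning R^2 must carry all the mass
        S = np.array([[1.0, 0.4], [0.4, 2.0]])
        cuts = [-np.inf, -0.5, 0.3, np.inf]
        total = sum(
            mvn_probability([cuts[i], cuts[j]], [cuts[i + 1], cuts[j + 1]],
                            [0.1, -0.2], S)
            for i in range(3) for j in range(3)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(TmvnError, match="empty"):
            mvn_probability([1.0], [0.0], [0], [[1.0]])

    def test_non_spd_rejected(self):
        with pytest.raises(TmvnError, match="positive definite"):
            mvn_probability([0, 0], [1, 1], [0, 0], [[1, 2], [2, 1.0]])


class TestClosedForms:
    def test_no_truncation_returns_mu_and_sigma(self):
        S = make_spd(2, np.random.default_rng(1))
        mu = np.array([0.3, -1.2])
        r = TruncationRegion([-np.inf, -np.inf], [np.inf, np.inf])
        assert np.allclose(tmvn_mean(r, mu, S), mu)
        assert np.allclose(tmvn_cov(r, mu, S), S)

    def test_half_normal_mean_and_variance(self):
        r = TruncationRegion([0], [np.inf])
        assert tmvn_mean(r, [0], [[1.0]])[0] == pytest.approx(0.7978846, abs=1e-7)
        assert tmvn_cov(r, [0], [[1.0]])[0, 0] == pytest.approx(
            1 - LAMBDA0 * LAMBDA0, abs=1e-7)

    def test_univariate_binary_upper_category(self):
        um = univariate_moments(2, [0.0], 0.0, 1.0)
        assert um.delta == pytest.approx(0.7978846, abs=1e-7)
        assert um.gamma == pytest.approx(0.6366198, abs=1e-7)
        assert um.ltilde == pytest.approx(0.7978846, abs=1e-7)

    def test_ltilde_inside_interval(self):
        um = univariate_moments(2, [0.0, 0.7], 1.5, 2.0)
        assert 0.0 < um.ltilde <= 0.7

    def test_category_out_of_range(self):
        with pytest.raises(TmvnError, match="category"):
            univariate_moments(4, [0.0, 0.7], 0.0, 1.0)

    @pytest.mark.parametrize("cat,mu,var", [
        (1, 0.0, 1.0), (2, 0.5, 1.3), (3, -0.8, 0.6),
    ])
    def test_closed_form_vs_generic_numeric_path(self, cat, mu, var):
        """The c=1 marginal-density machinery must reproduce the closed forms."""
        thr = [0.0, 0.9]
        um = univariate_moments(cat, thr, mu, var)
        t = np.concatenate(([-np.inf], thr, [np.inf]))
        r = TruncationRegion([t[cat - 1]], [t[cat]])
        mom = tmvn_moments(r, [mu], [[var]], method="generic")
        assert abs(um.delta - mom.delta[0]) < 1e-8
        assert abs(um.ltilde - mom.mean[0]) < 1e-8
        assert abs(um.gamma - mom.gamma[0, 0]) < 1e-6

    def test_univariate_batch_matches_scalar(self):
        rng = np.random.default_rng(8)
        mu = rng.normal(size=30)
        thr = [0.0, 0.9]
        t = np.concatenate(([-np.inf], thr, [np.inf]))
        cats = rng.integers(1, 4, size=30)
        P, delta, gamma, ltilde = univariate_batch(t[cats - 1], t[cats], mu, 1.4)
        for i in range(30):
            um = univariate_moments(int(cats[i]), thr, mu[i], 1.4)
            assert P[i] == pytest.approx(um.P, abs=1e-12)
            assert delta[i] == pytest.approx(um.delta, abs=1e-12)
            assert gamma[i] == pytest.approx(um.gamma, abs=1e-12)
            assert ltilde[i] == pytest.approx(um.ltilde, abs=1e-12)


def _random_case(c, rng):
    S = make_spd(c, rng, scale=0.5)
    mu = rng.normal(size=c)
    sd = np.sqrt(np.diag(S))
    lo = mu + sd * rng.uniform(-2.0, 0.3, size=c)
    hi = lo + sd * rng.uniform(0.8, 2.5, size=c)
    lo[rng.random(c) < 0.25] = -np.inf
    hi[rng.random(c) < 0.25] = np.inf
    return TruncationRegion(lo, hi), mu, S


class TestMomentsVsOracle:
    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_mean_cov_within_monte_carlo_error(self, c):
        rng = np.random.default_rng(100 + c)
        for rep in range(3):
            region, mu, S = _random_case(c, rng)
            mom = tmvn_moments(region, mu, S)
            orc = tmvn_mc_oracle(region, mu, S, n_draws=400000,
                                 seed=1000 * c + rep)
            assert np.all(np.abs(mom.mean - orc["mean"]) <
                          3 * orc["mean_se"] + 1e-9)
            assert np.all(np.abs(mom.cov - orc["cov"]) <
                          3 * orc["cov_se"] + 1e-9)
            assert abs(mom.prob - orc["prob"]) < 3 * orc["prob_se"] + 1e-9

    def test_mean_within_bounds(self):
        rng = np.random.default_rng(7)
        region, mu, S = _random_case(3, rng)
        m = tmvn_mean(region, mu, S)
        assert np.all(m >= region.lower) and np.all(m <= region.upper)

    def test_gamma_symmetric_psd(self):
        rng = np.random.default_rng(21)
        for c in (2, 3):
            region, mu, S = _random_case(c, rng)
            mom = tmvn_moments(region, mu, S)
            assert np.allclose(mom.gamma, mom.gamma.T, atol=1e-10)
            assert np.linalg.eigvalsh(mom.gamma).min() > -1e-9

    def test_gamma_is_negative_mu_jacobian_of_delta(self):
        """Cross-oracle: Gamma = -d Delta / d mu (finite differences)."""
        rng = np.random.default_rng(5)
        region, mu, S = _random_case(2, rng)
        mom = tmvn_moments(region, mu, S)
        h = 1e-5
        J = np.zeros((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            dp = tmvn_moments(region, mu + e, S).delta
            dm = tmvn_moments(region, mu - e, S).delta
            J[:, j] = (dp - dm) / (2 * h)
        assert np.allclose(-J, mom.gamma, atol=1e-5)

    def test_oracle_self_consistency(self):
        region = TruncationRegion([0.0], [np.inf])
        orc = tmvn_mc_oracle(region, [0.0], [[1.0]], n_draws=10**5, seed=4)
        assert abs(orc["mean"][0] - 0.7978846) < 3 * orc["mean_se"][0]

    def test_oracle_rejects_tiny_acceptance(self):
        region = TruncationRegion([8.0], [8.5])
        with pytest.raises(TmvnError, match="acceptance"):
            tmvn_mc_oracle(region, [0.0], [[1.0]], n_draws=10**4, seed=0)


class TestBivariateBatch:
    def test_matches_per_record_moments(self):
        rng = np.random.default_rng(12)
        S = np.array([[1.1, -0.4], [-0.4, 0.8]])
        n = 25
        mu = rng.normal(size=(n, 2))
        lo = mu + rng.uniform(-2, 0, size=(n, 2))
        hi = lo + rng.uniform(0.5, 3, size=(n, 2))
        lo[rng.random((n, 2)) < 0.3] = -np.inf
        hi[rng.random((n, 2)) < 0.3] = np.inf
        prob, mean, cov, delta, gamma = bivariate_truncated_moments(lo, hi, mu, S)
        for i in range(n):
            mom = tmvn_moments(TruncationRegion(lo[i], hi[i]), mu[i], S)
            assert prob[i] == pytest.approx(mom.prob, abs=1e-12)
            assert np.allclose(mean[i], mom.mean, atol=1e-10)
            assert np.allclose(cov[i], mom.cov, atol=1e-10)
            assert np.allclose(gamma[i], mom.gamma, atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    rho=st.floats(-0.85, 0.85),
    a=st.floats(-2.5, 1.5),
    w=st.floats(0.3, 3.0),
    mid=st.floats(-0.9, 0.9),
)
def test_probability_additivity_property(rho, a, w, mid):
    """Splitting a rectangle along one axis preserves total probability."""
    S = np.array([[1.0, rho], [rho, 1.0]])
    lo = np.array([a, -1.0])
    hi = np.array([a + w, 1.5])
    cut = lo[0] + (mid + 1.0) / 2.0 * w
    full = mvn_probability(lo, hi, [0, 0], S)
    left = mvn_probability(lo, [cut, hi[1]], [0, 0], S)
    right = mvn_probability([cut, lo[1]], hi, [0, 0], S)
    assert full == pytest.approx(left + right, abs=1e-9)
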