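"""Correctness of the marginal likelihood against independent oracles.

The central property: the adaptive (conditional-moment-centred)
quadrature over the discrete factors, with the continuous factors
marginalized analytically, must agree with a non-adaptive full-dimension
tensor-product rule evaluated with no analytic factorization.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm
from scipy.special import log_expit

from voxsem.growth import GrowthSpec, ParamPacker, TwoPartData, TwoPartParams
from voxsem.likelihood import (
    build_groups,
    implied_moments,
    loglik_bruteforce,
    marginal_loglik,
)

from conftest import toy_data, toy_params


class TestOracleAgreement:
    def test_matches_bruteforce_on_toys(self, rng, spec):
        worst = 0.0
        for _ in range(2):
            data = toy_data(rng, n=3)
            params = toy_params(rng, spec)
            d = abs(
                marginal_loglik(params, data, spec)
                - loglik_bruteforce(params, data, spec, n_nodes=56)
            )
            worst = max(worst, d)
        assert worst < 1e-6

    def test_bruteforce_node_convergence(self, rng, spec):
        data = toy_data(rng, n=2)
        params = toy_params(rng, spec)
        a = loglik_bruteforce(params, data, spec, n_nodes=56)
        b = loglik_bruteforce(params, data, spec, n_nodes=64)
        assert abs(a - b) < 1e-8

    def test_bruteforce_guards(self, rng, spec):
        data = toy_data(rng, n=3)
        params = toy_params(rng, spec)
        with pytest.raises(ValueError, match="nodes"):
            loglik_bruteforce(params, data, spec, n_nodes=10)
        big = toy_data(rng, n=12)
        with pytest.raises(ValueError, match="subjects"):
            loglik_bruteforce(params, big, spec)

    def test_probit_link_also_agrees(self, rng):
        # the probit log-likelihood has Gaussian tails, so the adaptive
        # rule needs a few more nodes than the logit default
        spec = GrowthSpec(link="probit")
        data = toy_data(rng, n=3)
        params = toy_params(rng, spec)
        d = abs(
            marginal_loglik(params, data, spec, n_quad=25)
            - loglik_bruteforce(params, data, spec, n_nodes=56)
        )
        assert d < 1e-6


class TestClosedForms:
    def test_degenerate_latents_factorize(self, rng, spec):
        """Zero latent variance: independent Bernoulli + normal terms."""
        data = toy_data(rng, n=5, covariate=False)
        mu = np.array([0.4, 0.2, 0.8, 0.3])
        params = TwoPartParams(mu, np.zeros((4, 4)), np.array([0.7, 0.8, 0.9]))
        lam = np.array(spec.time_scores)
        expected = 0.0
        for i in range(5):
            for t in range(3):
                b = data.binary[i, t]
                if np.isfinite(b):
                    lp = mu[0] + lam[t] * mu[1]
                    expected += float(log_expit((2 * b - 1) * lp))
                c = data.continuous[i, t]
                if np.isfinite(c):
                    expected += float(
                        norm.logpdf(c, mu[2] + lam[t] * mu[3], np.sqrt(params.theta[t]))
                    )
        assert marginal_loglik(params, data, spec) == pytest.approx(expected, abs=1e-8)

    def test_saturated_binary_part_splits_into_mvn_plus_binary(self, rng):
        """All binary cells 1 and zero cross-covariance: the two-part
        log-likelihood equals the closed-form normal growth model
        log-likelihood plus the binary-part marginal."""
        spec = GrowthSpec(psi_cross="none")
        n = 6
        params = toy_params(rng, spec)
        lam = np.array(spec.time_scores)
        Lc = spec.loadings_continuous
        mean = Lc @ params.mu[2:]
        cov = Lc @ params.psi[2:, 2:] @ Lc.T + np.diag(params.theta)
        y = rng.multivariate_normal(mean, cov, size=n)
        b = np.ones((n, 3))
        data = TwoPartData(b, y, covariates=None)
        total = marginal_loglik(params, data, spec)
        binary_only = marginal_loglik(
            params, TwoPartData(b, np.full((n, 3), np.nan)), spec
        )
        mvn = multivariate_normal(mean, cov).logpdf(y).sum()
        assert total - binary_only == pytest.approx(mvn, abs=1e-8)

    def test_subject_with_no_observed_cells_contributes_zero(self, rng, spec):
        data = toy_data(rng, n=4, covariate=False)
        params = toy_params(rng, spec)
        ll = marginal_loglik(params, data, spec)
        b2 = np.vstack([data.binary, np.full((1, 3), np.nan)])
        c2 = np.vstack([data.continuous, np.full((1, 3), np.nan)])
        ll2 = marginal_loglik(params, TwoPartData(b2, c2), spec)
        assert ll2 == pytest.approx(ll, abs=1e-10)


class TestInvariances:
    def test_subject_order_invariance(self, rng, spec):
        data = toy_data(rng, n=6)
        params = toy_params(rng, spec)
        perm = rng.permutation(6)
        shuffled = TwoPartData(
            data.binary[perm], data.continuous[perm],
            covariates=data.covariates.iloc[perm].reset_index(drop=True),
        )
        assert marginal_loglik(params, shuffled, spec) == pytest.approx(
            marginal_loglik(params, data, spec), abs=1e-9
        )

    def test_quadrature_node_stability(self, rng, spec):
        data = toy_data(rng, n=5)
        params = toy_params(rng, spec)
        a = marginal_loglik(params, data, spec, n_quad=15)
        b = marginal_loglik(params, data, spec, n_quad=25)
        assert abs(a - b) < 1e-7

    def test_infeasible_covariance_is_flagged(self, rng, spec):
        data = toy_data(rng, n=4)
        params = toy_params(rng, spec)
        params.psi = params.psi.copy()
        params.psi[0, 1] = params.psi[1, 0] = 10.0  # grossly indefinite
        assert marginal_loglik(params, data, spec) == -np.inf


class TestGradient:
    @pytest.mark.parametrize("cross", ["intercepts", "none", "full"])
    def test_analytic_gradient_matches_finite_differences(self, rng, cross):
        spec = GrowthSpec(psi_cross=cross)
        data = toy_data(rng, n=7)
        packer = ParamPacker(spec, 1, has_voxel=False)
        x = rng.normal(0.0, 0.4, packer.n_params)
        params = packer.unpack(x)
        _, g = marginal_loglik(
            params, data, spec, grad=True, packer=packer, x_packed=x
        )
        for j in rng.choice(packer.n_params, size=6, replace=False):
            h = 1e-6
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            fd = (
                marginal_loglik(packer.unpack(xp), data, spec)
                - marginal_loglik(packer.unpack(xm), data, spec)
            ) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_scores_sum_to_gradient(self, rng, spec):
        data = toy_data(rng, n=6)
        packer = ParamPacker(spec, 1, has_voxel=False)
        x = rng.normal(0.0, 0.4, packer.n_params)
        params = packer.unpack(x)
        _, g = marginal_loglik(params, data, spec, grad=True, packer=packer, x_packed=x)
        _, S = marginal_loglik(params, data, spec, score=True, packer=packer, x_packed=x)
        assert S.shape == (6, packer.n_params)
        np.testing.assert_allclose(S.sum(axis=0), g, atol=1e-10)


class TestImpliedMoments:
    def test_identity_covariance_limit(self, spec):
        params = TwoPartParams(np.zeros(4), np.zeros((4, 4)), np.ones(3))
        _, cov = implied_moments(params, spec)
        np.testing.assert_allclose(cov, np.eye(3))

    def test_hand_matrix_algebra(self, spec):
        psi = np.zeros((4, 4))
        psi[2, 2] = psi[3, 3] = 1.0
        params = TwoPartParams(np.zeros(4), psi, np.full(3, 1e-12))
        _, cov = implied_moments(params, spec)
        np.testing.assert_allclose(cov, [[1, 1, 1], [1, 2, 3], [1, 3, 5]], atol=1e-10)

    def test_always_symmetric_psd(self, rng, spec):
        params = toy_params(rng, spec)
        _, cov = implied_moments(params, spec)
        np.testing.assert_allclose(cov, cov.T)
        assert np.min(np.linalg.eigvalsh(cov)) > 0
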