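import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from coxsusie import (NormalPrior, UnivariateCoxFit, fit_univariate_coxph,
                      log_abf, log_laplace_bf, log_quadrature_bf,
                      posterior_moments)
from coxsusie.survival_core import _batch_eval, _prepare
from helpers import random_survival_fixture


def _fake_fit(bhat, se, loglik_mle=0.0, loglik_null=0.0, degenerate=False):
    return UnivariateCoxFit(bhat=bhat, se=se, z=bhat / se if se > 0 else 0.0,
                            loglik_mle=loglik_mle, loglik_null=loglik_null,
                            converged=True, degenerate=degenerate)


class TestPosteriorMoments:
    def test_harmonic_shrinkage_arithmetic(self):
        post = posterior_moments(_fake_fit(2.0, 1.0), NormalPrior(1.0))
        assert post.variance == pytest.approx(0.5)
        assert post.mean == pytest.approx(1.0)

    def test_point_mass_prior(self):
        post = posterior_moments(_fake_fit(2.0, 1.0), NormalPrior(0.0))
        assert post.mean == 0.0 and post.variance == 0.0

    def test_flat_prior_limit(self):
        fit = _fake_fit(0.7, 0.3)
        post = posterior_moments(fit, NormalPrior(1e12))
        assert post.variance == pytest.approx(fit.se ** 2, rel=1e-6)
        assert post.mean == pytest.approx(fit.bhat, rel=1e-6)

    def test_shrinkage_bounds(self):
        fit = _fake_fit(1.5, 0.4)
        post = posterior_moments(fit, NormalPrior(0.8))
        assert 0 <= post.variance <= min(fit.se ** 2, 0.8)
        assert abs(post.mean) <= abs(fit.bhat)


class TestLogABF:
    def test_zero_signal_occam_factor(self):
        # z = 0, s^2 = 1, sigma0^2 = 3: ABF = sqrt(1/4) = 0.5
        assert log_abf(_fake_fit(0.0, 1.0), NormalPrior(3.0)) == \
            pytest.approx(np.log(0.5), abs=1e-12)

    def test_null_prior_gives_unit_bf(self):
        assert log_abf(_fake_fit(1.0, 0.5), NormalPrior(0.0)) == 0.0

    def test_strictly_increasing_in_z_squared(self):
        vals = [log_abf(_fake_fit(z * 0.5, 0.5), NormalPrior(1.0))
                for z in np.arange(0, 10.5, 0.5)]
        assert np.all(np.diff(vals) > 0)

    def test_no_overflow_at_extreme_z(self):
        val = log_abf(_fake_fit(1e4 * 0.01, 0.01), NormalPrior(1.0))
        assert np.isfinite(val) and val > 1e6


class TestLogLaplaceBF:
    def test_identity_embedded_in_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            fit = _fake_fit(rng.normal(), abs(rng.normal()) + 0.05,
                            loglik_mle=-40.0 + abs(rng.normal()),
                            loglik_null=-40.0)
            prior = NormalPrior(abs(rng.normal()) + 0.1)
            lhs = log_laplace_bf(fit, prior)
            rhs = (log_abf(fit, prior) - 0.5 * fit.z ** 2
                   + fit.loglik_mle - fit.loglik_null)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_at_null_mle_reduces_to_occam_factor(self):
        fit = _fake_fit(0.0, 1.0)
        expected = 0.5 * np.log(1.0 / (3.0 + 1.0))
        assert log_laplace_bf(fit, NormalPrior(3.0)) == \
            pytest.approx(expected, abs=1e-12)

    def test_degenerate_fit_gives_unit_bf(self):
        fit = _fake_fit(0.0, np.inf, degenerate=True)
        assert log_laplace_bf(fit, NormalPrior(1.0)) == 0.0

    def test_vanishes_as_prior_collapses(self):
        x, out = random_survival_fixture(seed=4, n=100)
        fit = fit_univariate_coxph(x, out)
        # ABF -> 1 exactly; the Laplace BF limit is exp(logLR - z^2/2),
        # i.e. 1 up to the quadratic-approximation remainder
        assert abs(log_abf(fit, NormalPrior(1e-12))) < 1e-4
        remainder = fit.loglik_mle - fit.loglik_null - 0.5 * fit.z ** 2
        assert log_laplace_bf(fit, NormalPrior(1e-12)) == \
            pytest.approx(remainder, abs=1e-6)


class TestQuadratureBF:
    def test_prior_collapse_returns_null(self):
        x, out = random_survival_fixture(seed=6, n=100)
        assert abs(log_quadrature_bf(x, out, prior=NormalPrior(1e-10))) < 1e-4

    def test_matches_dense_trapezoid_oracle(self):
        x, out = random_survival_fixture(seed=3, n=200, effect=0.5)
        fit = fit_univariate_coxph(x, out)
        lq = log_quadrature_bf(x, out, prior=NormalPrior(1.0))
        bs = np.linspace(fit.bhat - 10 * fit.se, fit.bhat + 10 * fit.se,
                         20001)
        XsT, cs = _prepare(x, out, None)
        llb = _batch_eval(bs, np.broadcast_to(XsT, (len(bs), XsT.shape[1])),
                          cs, out.layout, "efron", derivs=False)
        ll0 = _batch_eval(np.zeros(1), XsT, cs, out.layout, "efron",
                          derivs=False)[0]
        oracle = logsumexp(llb - ll0 + norm.logpdf(bs, 0.0, 1.0),
                           b=np.gradient(bs))
        assert lq == pytest.approx(oracle, rel=1e-6)

    def test_stable_under_node_doubling(self):
        x, out = random_survival_fixture(seed=8, n=150, effect=0.3)
        a = log_quadrature_bf(x, out, prior=NormalPrior(1.0), n_nodes=32)
        b = log_quadrature_bf(x, out, prior=NormalPrior(1.0), n_nodes=64)
        assert abs(a - b) <= 1e-4

    def test_too_few_nodes_rejected(self):
        x, out = random_survival_fixture(seed=1, n=50)
        with pytest.raises(ValueError):
            log_quadrature_bf(x, out, n_nodes=4)

    def test_prior_centered_mode_agrees_when_scales_match(self):
        # weak data: posterior nearly as wide as the prior, so both node
        # placements resolve the integrand
        x, out = random_survival_fixture(seed=12, n=30, effect=0.0,
                                         censoring=0.0)
        a = log_quadrature_bf(x, out, prior=NormalPrior(0.05))
        b = log_quadrature_bf(x, out, prior=NormalPrior(0.05),
                              recenter=False)
        assert a == pytest.approx(b, abs=5e-3)
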