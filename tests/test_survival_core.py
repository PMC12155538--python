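import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from coxsusie import (SurvivalOutcome, fit_covariate_offsets,
                      fit_univariate_coxph, partial_loglik,
                      batch_univariate_coxph)
from helpers import naive_partial_loglik, random_survival_fixture


class TestPartialLoglik:
    def test_null_model_distinct_event_times(self):
        # 3 subjects all failing at distinct times: risk sets 3, 2, 1
        out = SurvivalOutcome(times=np.array([1.0, 2.0, 3.0]),
                              status=np.array([1, 1, 1]))
        x = np.zeros(3)
        for b in (0.0, 1.3, -2.0):
            assert partial_loglik(b, x, out) == pytest.approx(-np.log(6),
                                                              abs=1e-12)

    def test_offset_shift_invariance(self):
        out = SurvivalOutcome(times=np.array([1.0, 2.0, 3.0]),
                              status=np.array([1, 1, 1]))
        x = np.array([0.5, 1.0, 0.0])
        c = np.array([0.2, -0.1, 0.4])
        a = partial_loglik(0.7, x, out, offset=c)
        b = partial_loglik(0.7, x, out, offset=c + 5.0)
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_longhand_efron_on_tied_toy(self, toy_tied_outcome):
        x, out = toy_tied_outcome
        for b in (-0.5, 0.0, 0.3, 1.1):
            expected = naive_partial_loglik(b, x, out.times, out.status,
                                            ties="efron")
            assert partial_loglik(b, x, out, ties="efron") == \
                pytest.approx(expected, abs=1e-12)

    def test_matches_longhand_breslow_on_tied_toy(self, toy_tied_outcome):
        x, out = toy_tied_outcome
        expected = naive_partial_loglik(0.4, x, out.times, out.status,
                                        ties="breslow")
        assert partial_loglik(0.4, x, out, ties="breslow") == \
            pytest.approx(expected, abs=1e-12)

    def test_monotone_time_transform_invariance(self, toy_tied_outcome):
        x, out = toy_tied_outcome
        warped = SurvivalOutcome(times=np.exp(out.times / 3.0),
                                 status=out.status)
        assert partial_loglik(0.8, x, out) == \
            pytest.approx(partial_loglik(0.8, x, warped), abs=1e-10)

    def test_no_events_is_an_error(self):
        out = SurvivalOutcome(times=np.array([1.0, 2.0]),
                              status=np.array([0, 0]))
        with pytest.raises(ValueError, match="no events"):
            partial_loglik(0.0, np.array([0.0, 1.0]), out)

    def test_nonfinite_inputs_rejected(self, toy_tied_outcome):
        x, out = toy_tied_outcome
        with pytest.raises(ValueError):
            partial_loglik(np.inf, x, out)
        with pytest.raises(ValueError):
            partial_loglik(0.0, np.r_[x[:-1], np.nan], out)


class TestFitUnivariate:
    def test_constant_covariate_degenerate(self, toy_tied_outcome):
        _, out = toy_tied_outcome
        fit = fit_univariate_coxph(np.ones(out.n), out)
        assert fit.degenerate
        assert fit.bhat == 0.0
        assert fit.loglik_mle == fit.loglik_null

    def test_sign_symmetry(self):
        x, out = random_survival_fixture(seed=5)
        f1 = fit_univariate_coxph(x, out)
        f2 = fit_univariate_coxph(-x, out)
        assert f1.bhat == pytest.approx(-f2.bhat, abs=1e-9)
        assert f1.se == pytest.approx(f2.se, rel=1e-9)
        assert f1.loglik_mle == pytest.approx(f2.loglik_mle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_golden_section_oracle(self, seed):
        x, out = random_survival_fixture(seed=seed, n=50)
        fit = fit_univariate_coxph(x, out)
        res = minimize_scalar(lambda b: -partial_loglik(b, x, out),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.converged
        assert fit.bhat == pytest.approx(res.x, abs=1e-6)

    def test_mle_dominates_null(self):
        x, out = random_survival_fixture(seed=3, n=80)
        fit = fit_univariate_coxph(x, out)
        assert fit.loglik_mle >= fit.loglik_null
        assert fit.z == pytest.approx(fit.bhat / fit.se)

    def test_efron_equals_breslow_without_ties(self):
        x, out = random_survival_fixture(seed=11, n=60)
        assert len(np.unique(out.times[out.status == 1])) == out.n_events
        fe = fit_univariate_coxph(x, out, ties="efron")
        fb = fit_univariate_coxph(x, out, ties="breslow")
        assert fe.bhat == pytest.approx(fb.bhat, abs=1e-10)
        assert fe.loglik_mle == pytest.approx(fb.loglik_mle, abs=1e-10)

    def test_order_independence(self):
        x, out = random_survival_fixture(seed=13, n=70)
        perm = np.random.default_rng(0).permutation(out.n)
        out_p = SurvivalOutcome(times=out.times[perm],
                                status=out.status[perm])
        f1 = fit_univariate_coxph(x, out)
        f2 = fit_univariate_coxph(x[perm], out_p)
        assert f1.bhat == pytest.approx(f2.bhat, abs=1e-9)
        assert f1.se == pytest.approx(f2.se, rel=1e-9)

    def test_complete_separation_capped_and_flagged(self):
        # covariate perfectly orders the event times: monotone likelihood
        times = np.arange(1.0, 9.0)
        out = SurvivalOutcome(times=times, status=np.ones(8, dtype=int))
        x = -times  # later failure <=> smaller x, so b -> +inf
        fit = fit_univariate_coxph(x, out)
        assert not fit.converged
        assert abs(fit.bhat) >= 10

    def test_agrees_with_lifelines_on_tied_data(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        x, out = random_survival_fixture(seed=42, n=300, effect=0.8,
                                         round_times=1)
        fit = fit_univariate_coxph(x, out)
        df = pd.DataFrame({"T": out.times, "E": out.status, "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.bhat == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
        assert fit.loglik_mle == pytest.approx(cph.log_likelihood_, abs=1e-6)


class TestBatchFits:
    def test_batch_matches_per_column_fits(self, medium_dataset):
        X, out, _ = medium_dataset
        batch = batch_univariate_coxph(X[:, :8], out)
        for j in range(8):
            single = fit_univariate_coxph(X[:, j], out)
            assert batch.bhat[j] == pytest.approx(single.bhat, abs=1e-10)
            assert batch.loglik_mle[j] == pytest.approx(single.loglik_mle,
                                                        abs=1e-10)


class TestCovariateOffsets:
    def test_all_ones_column_gives_zero_offsets(self, medium_dataset):
        _, out, _ = medium_dataset
        offs = fit_covariate_offsets(np.ones((out.n, 1)), out)
        assert np.allclose(offs, 0.0)

    def test_single_column_matches_univariate_fit(self):
        x, out = random_survival_fixture(seed=9, n=120)
        offs = fit_covariate_offsets(x[:, None], out)
        fit = fit_univariate_coxph(x, out)
        expected = fit.bhat * x - np.mean(fit.bhat * x)
        assert np.allclose(offs, expected, atol=1e-6)

    def test_duplicate_columns_error(self):
        x, out = random_survival_fixture(seed=2, n=60)
        Z = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear"):
            fit_covariate_offsets(Z, out, column_names=["a", "b"])

    def test_offsets_centered_and_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        rng = np.random.default_rng(17)
        x, out = random_survival_fixture(seed=17, n=250)
        Z = np.column_stack([x, rng.normal(size=out.n)])
        offs = fit_covariate_offsets(Z, out)
        assert abs(offs.mean()) < 1e-12
        df = pd.DataFrame({"T": out.times, "E": out.status,
                           "z1": Z[:, 0], "z2": Z[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        ref = Z @ cph.params_.to_numpy()
        ref -= ref.mean()
        assert np.allclose(offs, ref, atol=1e-4)
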