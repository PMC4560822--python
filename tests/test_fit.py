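"""Cost functions, priors, two-phase fitting, and posterior sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_decay_data
from phenodyn import (
    Condition,
    FitConfig,
    ParamVector,
    Record,
    TimeSeriesSet,
    build_hierarchy,
    chi_squared,
    fit_model,
    log_prior,
    posterior_sample,
)
from phenodyn.fit import FitResult, FitStatus, _Transform
from phenodyn.model_classes import ModelClass, ModelSpec


@pytest.fixture(scope="module")
def decay_setup():
    spec = build_hierarchy(ModelClass.SIGMOIDAL, 1, 0, 1)[0]
    true = ParamVector(spec, {"tau_1": 2.0, "theta_1": 0.0, "w_1_1": 0.0})
    return spec, true


class TestChiSquared:
    def test_zero_on_noiseless_self_data(self, decay_setup):
        spec, true = decay_setup
        ts = np.array([0.5, 1.5, 3.0])
        x0 = 1.3
        vals = x0 * np.exp(-ts / 2.0)
        data = TimeSeriesSet(
            ["x1"],
            [Condition("c", np.zeros(0), np.array([x0]),
                       [Record(float(t), "x1", float(v), 0.1)
                        for t, v in zip(ts, vals)])],
        )
        assert chi_squared(spec, true, data) == pytest.approx(0.0, abs=1e-6)

    def test_single_record_unit_residual(self, decay_setup):
        spec, true = decay_setup
        # prediction at t=0 is x0=2; value 1, sigma 1 -> chi2 = 1
        data = TimeSeriesSet(
            ["x1"],
            [Condition("c", np.zeros(0), np.array([2.0]),
                       [Record(0.0, "x1", 1.0, 1.0)])],
        )
        assert chi_squared(spec, true, data) == pytest.approx(1.0, abs=1e-9)

    def test_failed_integration_is_infinite(self):
        spec = ModelSpec(ModelClass.S_SYSTEM, 1, 0, 0, ("beta_1",))
        pv = ParamVector(spec, {"beta_1": 1.0})
        data = TimeSeriesSet(
            ["x1"],
            [Condition("c", np.zeros(0), np.array([0.5]),
                       [Record(2.0, "x1", 1.0, 0.1)])],
        )
        assert chi_squared(spec, pv, data) == math.inf

    def test_sampling_distribution_mean_is_N(self, decay_setup):
        """chi2 of the true model on correctly-noised data ~ chi2_N."""
        spec, true = decay_setup
        N, n_seeds = 20, 200
        chis = []
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ts = np.sort(rng.uniform(0.2, 4.0, N))
            x0 = 1.5
            truth = x0 * np.exp(-ts / 2.0)
            sigma = 0.05 * np.abs(truth)
            vals = truth + sigma * rng.standard_normal(N)
            data = TimeSeriesSet(
                ["x1"],
                [Condition("c", np.zeros(0), np.array([x0]),
                           [Record(float(t), "x1", float(v), float(s))
                            for t, v, s in zip(ts, vals, sigma)])],
            )
            chis.append(chi_squared(spec, true, data))
        assert np.mean(chis) == pytest.approx(N, rel=0.1)


class TestLogPrior:
    def test_maximal_at_prior_means(self, decay_setup):
        spec, _ = decay_setup
        at_mean = ParamVector(spec, {"tau_1": 1.0, "theta_1": 0.0, "w_1_1": 0.0})
        lp0 = log_prior(at_mean)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = ParamVector(
                spec,
                {"tau_1": float(np.exp(rng.normal())),
                 "theta_1": float(rng.normal()),
                 "w_1_1": float(rng.normal())},
            )
            assert log_prior(other) <= lp0 + 1e-12

    def test_quadratic_decrement_in_deviation(self, decay_setup):
        spec, _ = decay_setup
        base = {"tau_1": 1.0, "theta_1": 0.0, "w_1_1": 0.0}
        lp0 = log_prior(ParamVector(spec, base))
        lp1 = log_prior(ParamVector(spec, {**base, "w_1_1": 2.0}))
        lp2 = log_prior(ParamVector(spec, {**base, "w_1_1": 4.0}))
        # Gaussian: doubling the deviation quadruples the quadratic penalty
        assert (lp0 - lp2) == pytest.approx(4 * (lp0 - lp1), rel=1e-9)

    def test_matches_independent_density_formula(self, decay_setup):
        """Sum of normal log-pdfs: log-scale for tau, linear for the rest."""
        spec, _ = decay_setup
        rng = np.random.default_rng(4)
        for _ in range(50):
            tau = float(np.exp(rng.normal()))
            theta = float(rng.normal(scale=5))
            w = float(rng.normal(scale=5))
            pv = ParamVector(spec, {"tau_1": tau, "theta_1": theta, "w_1_1": w})
            want = (
                stats.norm.logpdf(math.log(tau), 0.0, math.log(10.0))
                + stats.norm.logpdf(theta, 0.0, 10.0)
                + stats.norm.logpdf(w, 0.0, 10.0)
            )
            assert log_prior(pv) == pytest.approx(want, rel=1e-12)


class TestFitModel:
    CFG = dict(anneal_stages=4, proposals_per_stage=10, max_nfev=80)

    def test_recovers_decay_time_constant(self, decay_setup):
        spec, _ = decay_setup
        data = make_decay_data(n_conditions=5, records_per_condition=10,
                               noise=0.05, tau=2.0, seed=2)
        start = ParamVector(spec, {"tau_1": 1.0, "theta_1": 0.0, "w_1_1": 0.0})
        fit = fit_model(spec, data, start, FitConfig(seed=1, **self.CFG))
        assert fit.status is FitStatus.OK
        assert fit.params.values["tau_1"] == pytest.approx(2.0, rel=0.05)

    def test_never_worse_than_start(self, decay_setup):
        spec, true = decay_setup
        data = make_decay_data(seed=5, tau=2.0)
        fit = fit_model(spec, data, true, FitConfig(seed=0, **self.CFG))
        start_cost = 0.5 * chi_squared(spec, true, data) - log_prior(true)
        assert fit.cost <= start_cost + 1e-9

    def test_seed_reproducibility(self, decay_setup):
        spec, _ = decay_setup
        data = make_decay_data(seed=6)
        start = ParamVector(spec, {"tau_1": 1.0, "theta_1": 0.0, "w_1_1": 0.0})
        f1 = fit_model(spec, data, start, FitConfig(seed=3, **self.CFG))
        f2 = fit_model(spec, data, start, FitConfig(seed=3, **self.CFG))
        assert f1.params.values == f2.params.values
        assert f1.chi2 == f2.chi2 and f1.Lhat == f2.Lhat

    def test_all_failing_start_gives_failed_status(self):
        spec = ModelSpec(ModelClass.S_SYSTEM, 1, 0, 0, ("beta_1",))
        data = TimeSeriesSet(
            ["x1"],
            [Condition("c", np.zeros(0), np.array([-1.0]),
                       [Record(1.0, "x1", 1.0, 0.1)])],
        )
        start = ParamVector(spec, {"beta_1": 1.0})
        fit = fit_model(spec, data, start,
                        FitConfig(seed=0, anneal_stages=2,
                                  proposals_per_stage=5, max_nfev=10))
        assert fit.status is FitStatus.FAILED
        assert fit.Lhat == -math.inf

    def test_effective_not_above_nominal(self, decay_setup):
        spec, _ = decay_setup
        data = make_decay_data(seed=7)
        start = ParamVector(spec, {"tau_1": 1.0, "theta_1": 0.0, "w_1_1": 0.0})
        fit = fit_model(spec, data, start, FitConfig(seed=0, **self.CFG))
        assert 0 <= fit.n_effective <= fit.n_nominal
        assert len(fit.hessian_eigenvalues) == fit.n_nominal


class TestPosteriorSample:
    def _toy_fit(self, H_w):
        """A hand-built quadratic-posterior fit with linear parameters only."""
        spec = ModelSpec(ModelClass.SIGMOIDAL, 1, 0, 0, ("theta_1", "w_1_1"))
        config = FitConfig()
        trans = _Transform(spec, config)
        assert not trans.is_log.any()
        z = np.array([0.5, -1.0])
        lam = np.linalg.eigvalsh(H_w)
        return FitResult(
            params=trans.param_vector(z), chi2=1.0, log_prior=0.0,
            hessian_eigenvalues=lam, n_nominal=2, n_effective=2,
            Lhat=0.0, status=FitStatus.OK, cost=0.5,
            z_opt=z, hessian_whitened=H_w, config=config,
        ), spec, trans

    def test_zero_samples(self, decay_setup):
        fit, spec, _ = self._toy_fit(np.eye(2))
        assert posterior_sample(fit, spec, None, 0) == []

    def test_mean_converges_to_best_fit(self):
        fit, spec, trans = self._toy_fit(np.diag([4.0, 1.0]))
        samples = posterior_sample(fit, spec, None, 10_000, seed=1)
        arr = np.array([s.as_array() for s in samples])
        se = trans.prior_scale / math.sqrt(10_000)  # generous bound
        np.testing.assert_allclose(arr.mean(axis=0), fit.z_opt, atol=4 * se.max())

    def test_covariance_matches_inverse_curvature(self):
        H_w = np.array([[3.0, 1.0], [1.0, 2.0]])
        fit, spec, trans = self._toy_fit(H_w)
        samples = posterior_sample(fit, spec, None, 10_000, seed=2)
        arr = np.array([s.as_array() for s in samples])
        S = np.diag(trans.prior_scale)
        want = S @ np.linalg.inv(H_w + np.eye(2)) @ S
        got = np.cov(arr.T)
        np.testing.assert_allclose(got, want, rtol=0.1, atol=0.1 * want.max())
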