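"""Out-of-sample correlation, error-vs-N tables, posterior bands."""

import numpy as np
import pytest

from phenodyn import ParamVector, build_hierarchy
from phenodyn.evaluate import (
    OOSCondition,
    out_of_sample_correlation,
    posterior_prediction_bands,
    prediction_error_vs_N,
)
from phenodyn.fit import FitConfig, FitResult, FitStatus, _Transform
from phenodyn.model_classes import ModelClass, ModelSpec, StructuralError


@pytest.fixture(scope="module")
def decay_model():
    spec = build_hierarchy(ModelClass.SIGMOIDAL, 1, 0, 1)[0]
    pv = ParamVector(spec, {"tau_1": 2.0, "theta_1": 0.0, "w_1_1": 0.0})
    return spec, pv


def _conditions(x0s):
    return [
        OOSCondition(f"c{i}", np.array([x0]), np.array([x0]), np.zeros(0))
        for i, x0 in enumerate(x0s)
    ]


class TestOutOfSampleCorrelation:
    def test_model_against_itself_scores_one(self, decay_model):
        spec, pv = decay_model

        def truth(cond, times):
            return cond.truth_x0[0] * np.exp(-np.asarray(times) / 2.0)[:, None]

        report = out_of_sample_correlation(
            spec, pv, truth, _conditions([0.5, 1.0, 2.0]), np.linspace(0, 5, 40)
        )
        assert report.per_condition_correlations == pytest.approx([1.0] * 3, abs=1e-6)
        assert report.mean_correlation == pytest.approx(1.0, abs=1e-6)
        assert report.mean_error == pytest.approx(0.0, abs=1e-8)

    def test_anticorrelated_truth_scores_minus_one(self, decay_model):
        spec, pv = decay_model

        def truth(cond, times):
            # mean-centred mirror image of the prediction
            pred = cond.truth_x0[0] * np.exp(-np.asarray(times) / 2.0)
            return (2 * pred.mean() - pred)[:, None]

        report = out_of_sample_correlation(
            spec, pv, truth, _conditions([1.0]), np.linspace(0, 5, 40)
        )
        assert report.mean_correlation == pytest.approx(-1.0, abs=1e-6)

    def test_failed_integration_scores_zero_and_is_logged(self):
        spec = ModelSpec(ModelClass.S_SYSTEM, 1, 0, 0, ("beta_1",))
        pv = ParamVector(spec, {"beta_1": 1.0})  # dx/dt = -1 crosses zero

        def truth(cond, times):
            return np.ones((len(times), 1))

        report = out_of_sample_correlation(
            spec, pv, truth, _conditions([0.5]), np.linspace(0, 5, 20)
        )
        assert report.per_condition_correlations == [0.0]
        assert report.metadata["n_failed_integrations"] == 1

    def test_condition_ordering_invariance(self, decay_model):
        spec, pv = decay_model

        def truth(cond, times):
            return cond.truth_x0[0] * np.exp(-np.asarray(times) / 1.7)[:, None]

        grid = np.linspace(0, 4, 30)
        fwd = out_of_sample_correlation(spec, pv, truth, _conditions([0.5, 2.0]), grid)
        rev = out_of_sample_correlation(spec, pv, truth, _conditions([2.0, 0.5]), grid)
        assert fwd.mean_correlation == pytest.approx(rev.mean_correlation)
        assert fwd.mean_error == pytest.approx(rev.mean_error)

    def test_missing_oracle_is_structural_error(self, decay_model):
        spec, pv = decay_model
        with pytest.raises(StructuralError):
            out_of_sample_correlation(spec, pv, None, [], np.linspace(0, 1, 5))


class TestPredictionErrorVsN:
    def test_truth_fitter_has_zero_error_and_table_shape(self):
        times = np.linspace(0.5, 3.0, 7)

        def truth_curve(x0):
            return x0 * np.exp(-times)

        def make_data(N, seed):
            return N  # opaque; fitters ignore it

        def make_heldout(seed):
            conds = [0.5, 1.5]
            return conds, times, [truth_curve(c) for c in conds]

        fitters = {
            "truth": lambda data, seed: ((lambda c, t: truth_curve(c)), 2),
            "biased": lambda data, seed: ((lambda c, t: truth_curve(c) + 1.0), 1),
        }
        table = prediction_error_vs_N(fitters, [10, 20], 3, 0, make_data, make_heldout)
        assert set(table["model"]) == {"truth", "biased"}
        assert len(table) == 2 * 2 * 3
        truth_rows = table[table.model == "truth"]
        assert np.allclose(truth_rows["mse"], 0.0)
        biased_rows = table[table.model == "biased"]
        assert np.allclose(biased_rows["mse"], 1.0)
        # s.d. of the mean uses the replicate count
        assert np.allclose(table["sdom"].dropna(), 0.0)


class TestPhosphoCompetitors:
    def test_three_fitters_run_and_report_parameter_counts(self):
        """Full (32-state), simple (5-parameter) and adaptive fitters all
        produce finite held-out errors; the full model carries the most
        parameters, the simple model exactly five."""
        from phenodyn.benchmarks import (
            BenchmarkConfig,
            build_phospho_network,
            generate_phospho_data,
        )
        from phenodyn.evaluate import phospho_fitters
        from phenodyn.fit import FitConfig
        import numpy as np

        network = build_phospho_network(5)
        times = np.linspace(0.5, 8.0, 6)

        def make_data(N, seed):
            data, _ = generate_phospho_data(
                BenchmarkConfig.phosphorylation(N=N, seed=seed)
            )
            return data

        def make_heldout(seed):
            rng = np.random.default_rng(seed + 500)
            conds, truths = [], []
            for c in range(2):
                V = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
                conds.append(OOSCondition(
                    f"h{c}", network.initial_state(), np.array([0.0]),
                    np.array([V]),
                ))
                truths.append(network.observable(V, times))
            return conds, times, truths

        fitters = phospho_fitters(
            fit_config=FitConfig(anneal_stages=2, proposals_per_stage=4,
                                 max_nfev=15),
            max_models=2, full_max_nfev=3,
        )
        table = prediction_error_vs_N(fitters, [20], 1, 0, make_data, make_heldout)
        assert set(table["model"]) == {"full", "simple", "adaptive"}
        assert np.all(np.isfinite(table["mse"]))
        n_params = dict(zip(table["model"], table["n_params"]))
        assert n_params["simple"] == 5
        assert n_params["full"] == 64
        assert n_params["adaptive"] >= 3


class TestPosteriorBands:
    def _fit(self, H_scale):
        spec = ModelSpec(ModelClass.SIGMOIDAL, 1, 0, 0, ("theta_1", "w_1_1"))
        config = FitConfig()
        trans = _Transform(spec, config)
        z = np.array([0.0, 0.5])
        H = np.eye(2) * H_scale
        return FitResult(
            params=trans.param_vector(z), chi2=0.0, log_prior=0.0,
            hessian_eigenvalues=np.diag(H), n_nominal=2, n_effective=2,
            Lhat=0.0, status=FitStatus.OK, cost=0.0,
            z_opt=z, hessian_whitened=H, config=config,
        ), spec

    def test_tight_posterior_gives_narrow_band_containing_median(self):
        fit, spec = self._fit(1e12)  # essentially zero posterior variance
        med, lo, hi = posterior_prediction_bands(
            fit, spec, None, np.zeros(0), [1.0], np.linspace(0, 3, 15),
            n_samples=50, seed=0,
        )
        assert np.all(lo <= med + 1e-12) and np.all(med <= hi + 1e-12)
        assert np.max(hi - lo) < 1e-3

    def test_loose_posterior_band_winds(self):
        fit, spec = self._fit(1.0)
        med, lo, hi = posterior_prediction_bands(
            fit, spec, None, np.zeros(0), [1.0], np.linspace(0, 3, 15),
            n_samples=200, seed=1,
        )
        assert np.all(lo <= med) and np.all(med <= hi)
        assert np.max(hi - lo) > 1e-3
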