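"""Out-of-sample evaluation protocols for inferred dynamical models.

Three protocols:

* predicted-vs-true time-course correlation over fresh initial conditions
  (how well does the selected model generalize outside the training ranges);
* mean out-of-sample prediction error as a function of training-set size,
  comparing the full mechanistic model, a hand-built simple model, and the
  adaptive model (the overfitting/underfitting trade-off);
* posterior predictive medians with 90% bands from Laplace-posterior samples.

Failed out-of-sample integrations score correlation 0 rather than being
excluded, which prevents survivorship inflation of the mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitConfig, FitResult, TimeSeriesSet, posterior_sample
from .model_classes import ModelSpec, ParamVector, StructuralError
from .simulate import EvalCounter, InputSignal, TrajectoryStatus, integrate

__all__ = [
    "EvaluationReport",
    "OOSCondition",
    "out_of_sample_correlation",
    "prediction_error_vs_N",
    "posterior_prediction_bands",
    "phospho_fitters",
]


@dataclass
class OOSCondition:
    """One held-out condition: what the truth model and the fitted model see.

    ``truth_x0`` is the full initial state of the generating system (possibly
    higher-dimensional than the fitted model); ``observed_x0`` and ``inputs``
    are what the fitted model is given.
    """

    id: str
    truth_x0: np.ndarray
    observed_x0: np.ndarray
    inputs: InputSignal | np.ndarray


@dataclass
class EvaluationReport:
    """Per-condition and aggregate out-of-sample scores."""

    per_condition_correlations: list[float]
    mean_correlation: float
    per_condition_errors: list[float]
    mean_error: float
    n_conditions: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "mean_correlation": self.mean_correlation,
                "mean_error": self.mean_error,
                "n_conditions": self.n_conditions,
                "per_condition_correlations": self.per_condition_correlations,
                "per_condition_errors": self.per_condition_errors,
                "metadata": self.metadata,
            },
            **kw,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": range(self.n_conditions),
                "correlation": self.per_condition_correlations,
                "squared_error": self.per_condition_errors,
            }
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; degenerate (constant) series score 0."""
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-300 or sb < 1e-300:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return 0.0 if math.isnan(r) else r


def out_of_sample_correlation(
    spec: ModelSpec,
    params: ParamVector,
    truth_fn,
    conditions: list[OOSCondition],
    time_grid,
    config: FitConfig | None = None,
    counter: EvalCounter | None = None,
) -> EvaluationReport:
    """Correlate model and truth time courses over held-out conditions.

    ``truth_fn(cond, times)`` must return the noiseless observed-variable
    time courses of the generating system, shape (n_times, n_observed).
    Correlations are computed per observed species over the time course,
    averaged over species within a condition, then over conditions; failed
    model integrations score 0 and are logged in the metadata.
    """
    if truth_fn is None:
        raise StructuralError("a truth oracle is required for evaluation")
    config = config or FitConfig()
    time_grid = np.asarray(time_grid, float)
    n_obs = spec.n_observed
    corrs, errs, pooled_pred, pooled_truth, n_failed = [], [], [], [], 0
    for cond in conditions:
        truth = np.asarray(truth_fn(cond, time_grid), float)
        traj = integrate(
            spec, params, cond.observed_x0, cond.inputs, time_grid,
            rtol=config.rtol, atol=config.atol, counter=counter,
        )
        if traj.status is not TrajectoryStatus.OK or len(traj.times) < len(time_grid):
            n_failed += 1
            corrs.append(0.0)
            errs.append(float(np.mean(truth**2)))
            continue
        pred = traj.states[:, :n_obs]
        corrs.append(
            float(np.mean([_pearson(pred[:, j], truth[:, j]) for j in range(n_obs)]))
        )
        errs.append(float(np.mean((pred - truth) ** 2)))
        pooled_pred.append(pred)
        pooled_truth.append(truth)
    pooled = (
        _pearson(
            np.concatenate(pooled_pred, axis=0).ravel(),
            np.concatenate(pooled_truth, axis=0).ravel(),
        )
        if pooled_pred
        else 0.0
    )
    return EvaluationReport(
        per_condition_correlations=corrs,
        mean_correlation=float(np.mean(corrs)) if corrs else 0.0,
        per_condition_errors=errs,
        mean_error=float(np.mean(errs)) if errs else 0.0,
        n_conditions=len(conditions),
        metadata={
            "n_failed_integrations": n_failed,
            "pooled_correlation": pooled,
            "aggregation": "pearson per species per condition, "
            "mean over species then conditions",
            "time_grid": [float(time_grid[0]), float(time_grid[-1]), len(time_grid)],
        },
    )


def prediction_error_vs_N(
    fitters: dict,
    data_sizes,
    n_replicates: int,
    seed: int,
    make_data,
    make_heldout,
) -> pd.DataFrame:
    """Out-of-sample error of competing models versus training-set size.

    ``fitters`` maps a model name to a callable
    ``fitter(train_data, seed) -> (predict_fn, n_parameters)`` where
    ``predict_fn(condition, times)`` returns predicted observable values.
    ``make_data(N, seed)`` generates a training TimeSeriesSet;
    ``make_heldout(seed)`` returns (conditions, times, truth_values) with
    ``truth_values[c]`` the noiseless truth for condition c.

    Returns a tidy DataFrame (model, N, replicate, mse, n_params) plus the
    aggregate mean and s.d. of the mean over replicates per (model, N).
    """
    rows = []
    for N in data_sizes:
        for rep in range(n_replicates):
            rep_seed = seed + 1000 * rep + N
            train = make_data(N, rep_seed)
            conditions, times, truth_values = make_heldout(rep_seed)
            for name, fitter in fitters.items():
                predict, n_params = fitter(train, rep_seed)
                sq = []
                for cond, truth in zip(conditions, truth_values):
                    pred = np.asarray(predict(cond, times), float)
                    sq.append(float(np.mean((pred - np.asarray(truth)) ** 2)))
                rows.append(
                    {
                        "model": name,
                        "N": N,
                        "replicate": rep,
                        "mse": float(np.mean(sq)),
                        "n_params": n_params,
                    }
                )
    table = pd.DataFrame(rows)
    agg = (
        table.groupby(["model", "N"])["mse"]
        .agg(mean_mse="mean", sdom=lambda v: v.std(ddof=1) / math.sqrt(len(v)))
        .reset_index()
    )
    return table.merge(agg, on=["model", "N"])


def phospho_fitters(
    fit_config: FitConfig | None = None,
    max_models: int = 6,
    full_max_nfev: int = 100,
    rate_seed: int = 42,
):
    """The three competitors of the phosphorylation error-versus-N study.

    Returns a dict of fitters compatible with :func:`prediction_error_vs_N`:

    * ``full`` -- maximum-likelihood fit of the generating 32-microstate
      network's own rate constants (all (V, K) pairs, on log scale);
      structurally correct but heavily over-parameterized for small N.
    * ``simple`` -- the hand-built 5-parameter saturation model.
    * ``adaptive`` -- hierarchy selection in the sigmoidal class with the
      input V, complexity chosen by Lhat.

    Each fitter maps ``(train_data, seed) -> (predict_fn, n_parameters)``
    with ``predict_fn(condition, times)`` returning the predicted total
    phosphorylation; conditions carry the input V in ``cond.inputs``.
    """
    from scipy.optimize import curve_fit, least_squares

    from .benchmarks import PhosphoNetwork, draw_phospho_rates, simple_phospho_model
    from .hierarchy import build_hierarchy
    from .select import SelectionConfig, select_model

    fit_config = fit_config or FitConfig(
        anneal_stages=4, proposals_per_stage=8, max_nfev=40
    )
    base_rates = draw_phospho_rates(5, seed=rate_seed)
    keys = sorted(base_rates)

    def _train_arrays(train):
        ts, Vs, ys, sigmas = [], [], [], []
        for cond in train.conditions:
            V = float(np.asarray(cond.inputs).reshape(-1)[0])
            for rec in cond.records:
                ts.append(rec.time)
                Vs.append(V)
                ys.append(rec.value)
                sigmas.append(rec.sigma)
        return (np.array(ts), np.array(Vs), np.array(ys), np.array(sigmas))

    def fit_full(train, seed):
        ts, Vs, ys, sigmas = _train_arrays(train)
        uniq_V = np.unique(Vs)

        def predict_all(log_rates):
            rates = {
                k: (math.exp(log_rates[2 * i]), math.exp(log_rates[2 * i + 1]))
                for i, k in enumerate(keys)
            }
            net = PhosphoNetwork(5, rates)
            out = np.empty_like(ys)
            for V in uniq_V:
                m = Vs == V
                order = np.argsort(ts[m])
                times = np.maximum(ts[m][order], 1e-9)
                vals = net.observable(V, np.sort(times))
                out[np.flatnonzero(m)[order]] = vals
            return out

        x0 = np.log(np.array([v for k in keys for v in base_rates[k]]))
        rng = np.random.default_rng(seed)
        x0 = x0 + 0.5 * rng.standard_normal(len(x0))  # rates unknown a priori
        sol = least_squares(
            lambda lr: (predict_all(lr) - ys) / sigmas, x0,
            method="trf", max_nfev=full_max_nfev,
        )
        rates = {
            k: (math.exp(sol.x[2 * i]), math.exp(sol.x[2 * i + 1]))
            for i, k in enumerate(keys)
        }
        net = PhosphoNetwork(5, rates)

        def predict(cond, times):
            V = float(np.asarray(cond.inputs).reshape(-1)[0])
            return net.observable(V, np.maximum(np.asarray(times, float), 1e-9))

        return predict, len(sol.x)

    def fit_simple(train, seed):
        ts, Vs, ys, sigmas = _train_arrays(train)

        def f(tv, A, V0, w, tau, c):
            t, V = tv
            return simple_phospho_model([A, V0, w, tau, c])(t, V)

        p0 = [np.max(ys) + 1e-3, np.median(Vs), 1.0, 1.0, 0.0]
        try:
            popt, _ = curve_fit(
                f, (ts, Vs), ys, p0=p0, sigma=sigmas, maxfev=2000
            )
        except RuntimeError:
            popt = p0
        model = simple_phospho_model(popt)

        def predict(cond, times):
            V = float(np.asarray(cond.inputs).reshape(-1)[0])
            return model(np.asarray(times, float), V)

        return predict, 5

    def fit_adaptive(train, seed):
        hierarchy = build_hierarchy(
            "sigmoidal", n_observed=1, n_inputs=1, max_models=max_models
        )
        trace = select_model(
            hierarchy, train,
            SelectionConfig(fit=fit_config, margin=2.0, patience=2, seed=seed),
        )
        sel = trace.selected

        def predict(cond, times):
            traj = integrate(
                sel.params.spec, sel.params, np.array([0.0]), cond.inputs,
                np.asarray(times, float),
            )
            if traj.status is not TrajectoryStatus.OK:
                return np.zeros(len(times))
            return traj.states[:, 0]

        return predict, sel.n_nominal

    return {"full": fit_full, "simple": fit_simple, "adaptive": fit_adaptive}


def posterior_prediction_bands(
    fit: FitResult,
    spec: ModelSpec,
    data: TimeSeriesSet,
    inputs,
    observed_x0,
    time_grid,
    n_samples: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
):
    """Pointwise median and 90% band of posterior-sampled trajectories.

    Integrates each Laplace-posterior parameter sample under the given
    (possibly time-varying) input; returns (median, lo5, hi95), each of
    shape (n_times, n_observed).  Samples whose integration fails are
    dropped (their count is irrelevant to the band definition but a fully
    degenerate posterior raises).
    """
    config = config or (fit.config or FitConfig())
    time_grid = np.asarray(time_grid, float)
    samples = posterior_sample(fit, spec, data, n_samples, seed=seed)
    curves = []
    for pv in samples:
        traj = integrate(
            spec, pv, observed_x0, inputs, time_grid,
            rtol=config.rtol, atol=config.atol,
        )
        if traj.status is TrajectoryStatus.OK and len(traj.times) == len(time_grid):
            curves.append(traj.states[:, : spec.n_observed])
    if not curves:
        raise RuntimeError(
            "posterior is degenerate: no sampled parameter set integrates"
        )
    stack = np.stack(curves)
    return (
        np.median(stack, axis=0),
        np.percentile(stack, 5, axis=0),
        np.percentile(stack, 95, axis=0),
    )
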