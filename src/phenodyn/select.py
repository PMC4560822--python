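"""Model scoring and the stop-at-peak search over a model hierarchy.

Each fitted model is scored by Lhat, a generalized-BIC estimate of its
Bayesian log-likelihood, whose Occam penalty charges only the parameter
directions the data actually constrain.  Along a nested hierarchy Lhat
first rises (fit improves) and then falls (overfitting penalty), and up to
statistical fluctuations there is a single peak, so the search can stop
once Lhat has dropped sufficiently below the running maximum; the model at
the maximum is selected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._laplace import (
    clamp_eigenvalues,
    effective_parameter_count,
    log_likelihood_estimate,
)
from .fit import FitConfig, FitResult, FitStatus, TimeSeriesSet, fit_model
from .hierarchy import Hierarchy, warm_start_params
from .model_classes import ModelSpec, ParamVector
from .simulate import EvalCounter

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "StopReason",
    "count_effective_parameters",
    "estimate_log_likelihood",
    "select_model",
]

#: Lhat ties within this margin are broken toward the simpler model.
_TIE_TOL = 1e-6


def count_effective_parameters(eigenvalues, N=None, prior_precisions=None) -> int:
    """Count directions whose data curvature exceeds the prior curvature.

    ``eigenvalues`` are curvature eigenvalues of the data-only cost (chi2/2)
    at the optimum; in the prior-whitened basis (the default) the prior
    precision is 1 in every direction.  ``N`` is accepted for context but the
    count depends on the data only through the curvature itself.
    """
    return effective_parameter_count(eigenvalues, prior_precisions)


def estimate_log_likelihood(fit: FitResult, N: int | None = None) -> float:
    """Generalized-BIC log-likelihood estimate Lhat for a fitted model.

    ``Lhat = -chi2/2 + log_prior - (1/2) sum_i ln((lam_i + p_i)/p_i)`` with
    the whitened prior precisions p_i = 1.  Reduces to standard-BIC
    differences (up to O(1)) between nested models when all directions are
    data-dominated with curvature proportional to N.
    """
    if fit.status is FitStatus.FAILED:
        return -math.inf
    return log_likelihood_estimate(
        fit.chi2, fit.log_prior, fit.hessian_eigenvalues
    )


class StopReason(str, Enum):
    PEAK_PASSED = "peak_passed"
    HIERARCHY_EXHAUSTED = "hierarchy_exhausted"
    BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass
class SelectionConfig:
    """Stopping-rule constants and the fit configuration for the search."""

    fit: FitConfig = field(default_factory=FitConfig)
    margin: float = 2.0       # log-units below the peak that count as a drop
    patience: int = 3         # consecutive dropped models before stopping
    max_model_evaluations: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "margin": self.margin,
            "patience": self.patience,
            "max_model_evaluations": self.max_model_evaluations,
            "seed": self.seed,
        }


@dataclass
class SelectionTrace:
    """Per-model fit results in hierarchy order plus the selection outcome."""

    fits: list[FitResult]
    selected_index: int
    stop_reason: StopReason
    eval_counter: EvalCounter

    @property
    def selected(self) -> FitResult:
        return self.fits[self.selected_index]

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "selected_index": self.selected_index,
                "stop_reason": self.stop_reason.value,
                "total_model_evaluations": self.eval_counter.total_model_evaluations,
                "total_rhs_evaluations": self.eval_counter.total_rhs_evaluations,
                "models": [
                    {
                        "hierarchy_index": f.params.spec.hierarchy_index,
                        "n_hidden": f.params.spec.n_hidden,
                        **f.to_dict(),
                    }
                    for f in self.fits
                ],
            },
            **kw,
        )


def select_model(
    hierarchy: Hierarchy,
    data: TimeSeriesSet,
    config: SelectionConfig | None = None,
    counter: EvalCounter | None = None,
) -> SelectionTrace:
    """Fit models in hierarchy order with warm starts and select the Lhat peak.

    Stops when Lhat has stayed below (max - margin) for ``patience``
    consecutive models, when the hierarchy is exhausted, or when the
    model-evaluation budget runs out.  Returns the argmax-Lhat model, ties
    broken toward the simpler one.
    """
    if len(hierarchy) == 0:
        raise ValueError("hierarchy is empty")
    config = config or SelectionConfig()
    counter = counter if counter is not None else EvalCounter()

    fits: list[FitResult] = []
    best_lhat = -math.inf
    best_index = -1
    n_dropped = 0
    stop_reason = StopReason.HIERARCHY_EXHAUSTED
    prev_ok: FitResult | None = None

    for m, spec in enumerate(hierarchy.specs):
        if (
            config.max_model_evaluations is not None
            and counter.total_model_evaluations >= config.max_model_evaluations
        ):
            stop_reason = StopReason.BUDGET_EXHAUSTED
            break
        if prev_ok is None:
            start = _neutral_start(spec)
        else:
            start = warm_start_params(prev_ok.params, spec)
        fit_cfg = FitConfig(**{**config.fit.to_dict(), "seed": config.seed + m})
        fit = fit_model(spec, data, start, fit_cfg, counter)
        fit.Lhat = estimate_log_likelihood(fit, data.N)
        fits.append(fit)
        if fit.status is not FitStatus.FAILED:
            prev_ok = fit
        if fit.Lhat > best_lhat + _TIE_TOL:
            best_lhat = fit.Lhat
            best_index = m
            n_dropped = 0
        elif fit.Lhat < best_lhat - config.margin:
            n_dropped += 1
            if n_dropped >= config.patience:
                stop_reason = StopReason.PEAK_PASSED
                break
        else:
            n_dropped = 0

    if best_index < 0:
        if stop_reason is StopReason.BUDGET_EXHAUSTED and not fits:
            # budget spent before any model could be fit
            return SelectionTrace(
                fits=[], selected_index=-1,
                stop_reason=stop_reason, eval_counter=counter,
            )
        last = fits[-1] if fits else None
        detail = last.status.value if last is not None else "no model fitted"
        raise RuntimeError(
            f"every model in the hierarchy failed to fit (last: {detail})"
        )
    return SelectionTrace(
        fits=fits,
        selected_index=best_index,
        stop_reason=stop_reason,
        eval_counter=counter,
    )


def _neutral_start(spec: ModelSpec) -> ParamVector:
    from .hierarchy import neutral_value

    values = {
        n: neutral_value(n, spec.model_class)
        for n in spec.active_params + spec.hidden_x0_names
    }
    # give prefactors/weights a nonzero nudge so the minimal model is not
    # identically static at the start of the very first fit
    for n in list(values):
        head = n.split("_", 1)[0]
        if head in ("alpha", "beta"):
            values[n] = 1.0
    return ParamVector(spec, values)
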