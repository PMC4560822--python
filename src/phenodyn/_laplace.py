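"""Laplace-approximation arithmetic shared by fitting and model scoring.

Works throughout in the prior-whitened basis: parameters are rescaled by
their prior standard deviations, so the prior precision is the identity and
the data-cost curvature eigenvalues are directly comparable to 1.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "clamp_eigenvalues",
    "effective_parameter_count",
    "log_likelihood_estimate",
]

#: Negative curvature beyond this fraction of the top eigenvalue triggers a
#: degenerate-optimum warning before clamping.
_NEG_TOL = 1e-8


def clamp_eigenvalues(eigenvalues) -> np.ndarray:
    """Clamp small negative curvature eigenvalues to zero, warning if large."""
    lam = np.asarray(eigenvalues, float)
    if lam.size == 0:
        return lam
    scale = max(np.max(np.abs(lam)), 1.0)
    if np.any(lam < -_NEG_TOL * scale):
        warnings.warn(
            "negative curvature at optimum beyond numerical tolerance; "
            "eigenvalues clamped to 0 (degenerate optimum)",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(lam, 0.0, None)


def effective_parameter_count(eigenvalues, prior_precisions=None) -> int:
    """Number of parameter directions actually constrained by the data.

    A direction counts as effective when the data-cost curvature exceeds the
    prior curvature there (eigenvalue > prior precision); the remaining,
    'sloppy' directions are pinned by the prior alone.
    """
    lam = clamp_eigenvalues(eigenvalues)
    p = (
        np.ones_like(lam)
        if prior_precisions is None
        else np.asarray(prior_precisions, float)
    )
    return int(np.sum(lam > p))


def log_likelihood_estimate(
    chi2: float, log_prior: float, eigenvalues, prior_precisions=None
) -> float:
    """Generalized-BIC estimate of the Bayesian log-likelihood of a model.

    ::

        Lhat = -chi2/2 + log_prior - (1/2) sum_i ln((lam_i + p_i) / p_i)

    The Occam penalty charges each parameter direction by how strongly the
    data constrain it relative to the prior; directions the data do not
    constrain (lam_i << p_i) contribute essentially nothing, so the penalty
    counts *effective* rather than nominal parameters.  When all k
    directions are data-dominated with curvature growing linearly in the
    number of observations N, the penalty approaches the familiar
    (k/2) ln N of the Bayesian Information Criterion up to an O(1) constant.
    """
    lam = clamp_eigenvalues(eigenvalues)
    p = (
        np.ones_like(lam)
        if prior_precisions is None
        else np.asarray(prior_precisions, float)
    )
    penalty = 0.5 * float(np.sum(np.log1p(lam / p)))
    return -0.5 * chi2 + log_prior - penalty
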