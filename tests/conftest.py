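"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-evaluate the model-class equations term by term
with scalar Python arithmetic, independent of the vectorized implementations
they check.
"""

import math

import numpy as np
import pytest

from phenodyn import (
    Condition,
    ModelSpec,
    ParamVector,
    Record,
    TimeSeriesSet,
    build_hierarchy,
)
from phenodyn.model_classes import ModelClass


def ssystem_rhs_literal(state, inputs, alpha, beta, g, h):
    """Term-by-term S-system rhs: dx_i = a_i prod x^g_ij - b_i prod x^h_ij."""
    x = list(state) + list(inputs)
    out = []
    for i in range(len(state)):
        prod_g = 1.0
        prod_h = 1.0
        for j, xj in enumerate(x):
            prod_g *= math.pow(xj, g[i][j])
            prod_h *= math.pow(xj, h[i][j])
        out.append(alpha[i] * prod_g - beta[i] * prod_h)
    return out


def sigmoidal_rhs_literal(state, inputs, tau, W, theta):
    """Term-by-term sigmoidal rhs: dx_i = -x_i/tau_i + sum_j W_ij xi(th_j - x_j)."""
    x = list(state) + list(inputs)
    out = []
    for i in range(len(state)):
        acc = -state[i] / tau[i]
        for j, xj in enumerate(x):
            acc += W[i][j] / (1.0 + math.exp(theta[j] - xj))
        out.append(acc)
    return out


@pytest.fixture(scope="session")
def decay_spec():
    """Minimal 1-variable sigmoidal spec (pure relaxation when w_1_1 = 0)."""
    return build_hierarchy(ModelClass.SIGMOIDAL, 1, 0, 1)[0]


def make_decay_data(n_conditions=5, records_per_condition=10, noise=0.05,
                    tau=2.0, seed=1):
    """Noisy exponential-decay measurements from x(t) = x0 exp(-t / tau)."""
    rng = np.random.default_rng(seed)
    conds = []
    for c in range(n_conditions):
        ts = np.sort(rng.uniform(0.1, 4.0, records_per_condition))
        x0 = rng.uniform(0.5, 2.0)
        vals = x0 * np.exp(-ts / tau)
        recs = [
            Record(
                float(t),
                "x1",
                float(v * (1 + noise * rng.normal())),
                max(noise * abs(v), 0.01),
            )
            for t, v in zip(ts, vals)
        ]
        conds.append(Condition(f"c{c}", np.zeros(0), np.array([x0]), recs))
    return TimeSeriesSet(["x1"], conds)


@pytest.fixture(scope="session")
def decay_data():
    return make_decay_data()


def draw_random_ssystem(rng, J, K):
    """Random S-system arrays and a strictly positive state/input draw."""
    from phenodyn import SSystemParams

    params = SSystemParams(
        alpha=rng.uniform(0.0, 3.0, J),
        beta=rng.uniform(0.0, 3.0, J),
        g=rng.uniform(-2.0, 2.0, (J, J + K)),
        h=rng.uniform(-2.0, 2.0, (J, J + K)),
        hidden_x0=np.ones(0),
    )
    state = rng.uniform(0.1, 5.0, J)
    inputs = rng.uniform(0.1, 5.0, K)
    return params, state, inputs


def draw_random_sigmoidal(rng, J, K):
    """Random sigmoidal-network arrays and a real state/input draw."""
    from phenodyn import SigmoidalParams

    params = SigmoidalParams(
        tau=rng.uniform(0.2, 5.0, J),
        W=rng.uniform(-5.0, 5.0, (J, J + K)),
        theta=rng.uniform(-5.0, 5.0, J + K),
        hidden_x0=np.zeros(0),
    )
    state = rng.uniform(-5.0, 5.0, J)
    inputs = rng.uniform(-5.0, 5.0, K)
    return params, state, inputs
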