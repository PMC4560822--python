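"""Robust trajectory integration for model-class ODEs, with cost accounting.

Integration failures are data, not exceptions: candidate parameters routinely
drive S-systems to non-positive states or blow trajectories up, and the
fitting layer treats those as infinitely bad fits.  The integrator therefore
always returns a :class:`Trajectory` whose ``status`` records what happened,
never raising for dynamical pathologies.

Model evaluations are counted as one trajectory integration over one
experimental condition (the unit used for the search's cost accounting);
right-hand-side call counts are tracked separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model_classes import ModelClass, ModelSpec, ParamVector, unpack_params

__all__ = [
    "Trajectory",
    "TrajectoryStatus",
    "EvalCounter",
    "InputSignal",
    "integrate",
    "gravity_rhs",
    "BLOWUP_BOUND",
]

#: |state| beyond this is treated as a blown-up trajectory.
BLOWUP_BOUND = 1e10


class TrajectoryStatus(str, Enum):
    OK = "ok"
    POSITIVITY_VIOLATION = "positivity_violation"
    BLOW_UP = "blow_up"
    SOLVER_FAILURE = "solver_failure"


@dataclass
class EvalCounter:
    """Monotone counters of integration effort across an inference run."""

    total_model_evaluations: int = 0
    total_rhs_evaluations: int = 0

    def add(self, n_rhs: int) -> None:
        self.total_model_evaluations += 1
        self.total_rhs_evaluations += int(n_rhs)


@dataclass
class Trajectory:
    """Integrated states at requested times, with failure diagnostics.

    When ``status`` is not OK the trajectory is truncated at the last time
    point before the failure; ``states`` is finite wherever returned.
    """

    times: np.ndarray       # (n,) strictly increasing
    states: np.ndarray      # (n, J)
    status: TrajectoryStatus
    n_rhs_evals: int = 0

    @property
    def ok(self) -> bool:
        return self.status is TrajectoryStatus.OK

    def to_frame(self, var_names, condition: str = "") -> pd.DataFrame:
        """Tidy (condition, time, variable, value) table."""
        rows = []
        for j, name in enumerate(var_names):
            for t, v in zip(self.times, self.states[:, j]):
                rows.append((condition, float(t), name, float(v)))
        return pd.DataFrame(rows, columns=["condition", "time", "variable", "value"])


@dataclass
class InputSignal:
    """Piecewise-constant input signal I(t).

    ``values[s]`` holds on ``[times[s], times[s+1])``; the last segment
    extends to infinity.  A constant signal is a single segment.
    """

    times: np.ndarray   # (S,) segment start times, times[0] == 0
    values: np.ndarray  # (S, K)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("segment times must start at 0 and increase")
        if len(self.times) != len(self.values):
            raise ValueError("one value row per segment required")

    @classmethod
    def constant(cls, values) -> "InputSignal":
        return cls(np.array([0.0]), np.atleast_2d(np.asarray(values, float)))

    def at(self, t: float) -> np.ndarray:
        s = int(np.searchsorted(self.times, t, side="right") - 1)
        return self.values[max(s, 0)]


def _as_signal(inputs, n_inputs: int) -> InputSignal:
    if isinstance(inputs, InputSignal):
        return inputs
    arr = np.asarray(inputs if inputs is not None else [], float).reshape(-1)
    if len(arr) != n_inputs:
        raise ValueError(f"expected {n_inputs} inputs, got {len(arr)}")
    return InputSignal.constant(arr)


def _safe_rhs(spec: ModelSpec, full, inputs_row: np.ndarray):
    """odeint-callable rhs defined (finitely) everywhere.

    Solvers probe trial states outside the feasible region while controlling
    their steps; the rhs must not blow up there.  States are clipped into the
    computable domain and non-finite derivatives are saturated; genuine
    pathologies (positivity violations, blow-ups) are detected afterwards
    from the returned trajectory, not from solver probes.
    """
    s_system = spec.model_class is ModelClass.S_SYSTEM
    if s_system:
        alpha, beta, g, h = full.alpha, full.beta, full.g, full.h
    else:
        tau, W, theta = full.tau, full.W, full.theta

    def f(x, t):
        with np.errstate(all="ignore"):
            if s_system:
                xc = np.clip(x, 1e-12, BLOWUP_BOUND)
                logx = np.log(np.concatenate([xc, inputs_row]))
                dx = alpha * np.exp(np.clip(g @ logx, -700, 700)) - beta * np.exp(
                    np.clip(h @ logx, -700, 700)
                )
            else:
                xf = np.concatenate([x, inputs_row])
                z = np.clip(theta - xf, -700, 700)
                dx = -x / tau + W @ (1.0 / (1.0 + np.exp(z)))
        return np.nan_to_num(dx, nan=0.0, posinf=1e12, neginf=-1e12)

    return f


def integrate(
    spec: ModelSpec,
    params: ParamVector,
    observed_x0,
    inputs,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    counter: EvalCounter | None = None,
) -> Trajectory:
    """Integrate a parameterized model from t=0 over the requested times.

    Hidden initial values come from the parameters; inputs may be constant
    (array of K values) or an :class:`InputSignal`.  ``times`` must be
    strictly increasing and non-negative; the state at t=0 is included in
    the integration start, not required in ``times``.
    """
    full = unpack_params(params)
    return integrate_full(
        spec, full, observed_x0, inputs, times, rtol=rtol, atol=atol, counter=counter
    )


def integrate_full(
    spec: ModelSpec,
    full,
    observed_x0,
    inputs,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    counter: EvalCounter | None = None,
) -> Trajectory:
    """As :func:`integrate`, for already-unpacked full parameter arrays."""
    times = np.asarray(times, float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-D array")
    if times[0] < 0:
        raise ValueError("times must be >= 0")
    signal = _as_signal(inputs, spec.n_inputs)
    x0 = np.concatenate([np.asarray(observed_x0, float), full.hidden_x0])
    if len(x0) != spec.n_dynamical:
        raise ValueError("observed_x0 length does not match spec.n_observed")

    s_system = spec.model_class is ModelClass.S_SYSTEM
    nfe = 0

    # segment boundaries intersecting [0, times[-1]]
    bounds = [0.0] + [float(t) for t in signal.times if 0.0 < t < times[-1]]
    bounds.append(float(times[-1]))
    out_t: list[float] = []
    out_x: list[np.ndarray] = []
    if times[0] == 0.0:  # the t=0 record is the initial state itself
        out_t.append(0.0)
        out_x.append(x0.copy())
    state = x0
    solver_ok = True
    if not (s_system and np.any(x0 <= 0)):
        for s in range(len(bounds) - 1):
            a, b = bounds[s], bounds[s + 1]
            if a == b or not solver_ok:
                continue
            seg_times = times[(times > a) & (times <= b)]
            teval = np.concatenate([[a], seg_times])
            if teval[-1] < b:
                teval = np.concatenate([teval, [b]])
            f = _safe_rhs(spec, full, signal.at(a))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol, info = odeint(
                    f, state, teval, rtol=rtol, atol=atol,
                    full_output=True, mxstep=5000, printmessg=False,
                )
            nfe += int(info["nfe"][-1]) if len(info["nfe"]) else 0
            solver_ok = info["message"] == "Integration successful."
            state = sol[-1]
            keep = np.isin(teval, seg_times)
            if not solver_ok:
                # outputs beyond the solver's last reached time are invalid
                t_reached = float(info["tcur"][-1]) if len(info["tcur"]) else a
                keep &= teval <= t_reached
            out_t.extend(teval[keep])
            out_x.extend(sol[keep])

    out_t_arr = np.asarray(out_t)
    out_x_arr = (
        np.asarray(out_x) if out_x else np.empty((0, spec.n_dynamical))
    )
    # scan outputs for the first genuine pathology and truncate there
    bad_blow = ~np.all(
        np.isfinite(out_x_arr) & (np.abs(out_x_arr) <= BLOWUP_BOUND), axis=1
    )
    bad_pos = (
        np.any(out_x_arr <= 0.0, axis=1)
        if s_system
        else np.zeros(len(out_t_arr), bool)
    )
    status = TrajectoryStatus.OK
    n_keep = len(out_t_arr)
    bad = bad_blow | bad_pos
    if bad.any():
        n_keep = int(np.argmax(bad))
        status = (
            TrajectoryStatus.POSITIVITY_VIOLATION
            if bad_pos[n_keep]
            else TrajectoryStatus.BLOW_UP
        )
    elif not solver_ok:
        status = TrajectoryStatus.SOLVER_FAILURE
    elif len(out_t_arr) < len(times):
        status = TrajectoryStatus.SOLVER_FAILURE
    if s_system and np.any(x0 <= 0):
        status = TrajectoryStatus.POSITIVITY_VIOLATION
        n_keep = 0
    out_t_arr, out_x_arr = out_t_arr[:n_keep], out_x_arr[:n_keep]
    if counter is not None:
        counter.add(nfe)
    return Trajectory(out_t_arr, out_x_arr, status, n_rhs_evals=nfe)


def gravity_rhs(r: float, v: float, ell: float, mu: float):
    """Reduced radial two-body dynamics.

    For a particle with angular momentum per unit mass ``ell`` in an
    attractive inverse-square field of strength ``mu``::

        dr/dt = v
        dv/dt = ell**2 / r**3 - mu / r**2

    The radial velocity ``v`` is the dynamical degree of freedom hidden from
    the observer, who measures only the distance ``r``.
    """
    if r <= 0:
        raise ValueError("radial distance must be positive")
    return v, ell**2 / r**3 - mu / r**2
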