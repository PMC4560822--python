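"""Fitting a single model to sparse, noisy time-series measurements.

The data are weighted least squares: each measurement record (time,
variable, value, sigma) contributes ``((prediction - value) / sigma)**2`` to
chi-squared, with predictions obtained by integrating the model ODEs per
experimental condition.  Weakly informative priors regularize the many
poorly-constrained ('sloppy') parameter directions: zero-mean Gaussians on
exponents, weights and offsets, log-normal on positivity-constrained
prefactors, time constants and S-system initial values.

A fit runs in two phases, akin to simulated annealing: a temperature-ladder
random walk around the starting point explores the posterior cost globally
(rejecting parameters whose trajectories fail to integrate), then a
derivative-based least-squares refinement polishes the best point found.
The returned optimum never has higher cost than the starting point, which
together with neutral warm starts makes chi-squared non-increasing along a
model hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._laplace import (
    clamp_eigenvalues,
    effective_parameter_count,
    log_likelihood_estimate,
)
from .model_classes import (
    ModelClass,
    ModelSpec,
    ParamVector,
    StructuralError,
)
from .model_classes import unpack_params
from .simulate import (
    EvalCounter,
    InputSignal,
    TrajectoryStatus,
    integrate_full,
)

__all__ = [
    "Record",
    "Condition",
    "TimeSeriesSet",
    "FitConfig",
    "FitResult",
    "FitStatus",
    "chi_squared",
    "log_prior",
    "fit_model",
    "posterior_sample",
]

_FAIL_RESIDUAL = 1e4  # per-record residual charged to a failed integration


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Record:
    """One measurement: variable ``variable`` observed at ``time`` with
    value ``value`` and Gaussian measurement uncertainty ``sigma``."""

    time: float
    variable: str
    value: float
    sigma: float


@dataclass
class Condition:
    """One experimental condition: inputs, known observed initial values,
    and the measurement records taken under them."""

    id: str
    inputs: InputSignal | np.ndarray | Sequence[float]
    observed_x0: np.ndarray
    records: list[Record]

    def __post_init__(self) -> None:
        self.observed_x0 = np.asarray(self.observed_x0, float)


@dataclass
class TimeSeriesSet:
    """The experimental data: named observed variables and their conditions."""

    observed_names: list[str]
    conditions: list[Condition]

    def __post_init__(self) -> None:
        for cond in self.conditions:
            for rec in cond.records:
                if rec.sigma <= 0:
                    raise ValueError(
                        f"condition {cond.id!r}: record at t={rec.time} has "
                        f"sigma={rec.sigma}; measurement uncertainties must be > 0"
                    )
                if rec.variable not in self.observed_names:
                    raise ValueError(
                        f"condition {cond.id!r}: {rec.variable!r} is not an "
                        f"observed variable {self.observed_names}"
                    )
                if rec.time < 0:
                    raise ValueError(
                        f"condition {cond.id!r}: negative record time {rec.time}"
                    )

    @property
    def N(self) -> int:
        """Total number of measurement records."""
        return sum(len(c.records) for c in self.conditions)


class _CompiledCondition:
    """Record bookkeeping pre-resolved for fast repeated cost evaluation."""

    __slots__ = ("inputs", "x0", "times", "t_idx", "v_idx", "values", "sigmas")

    def __init__(self, cond: Condition, observed_names: list[str]):
        self.inputs = cond.inputs
        self.x0 = cond.observed_x0
        rec_times = np.array([r.time for r in cond.records])
        self.times, self.t_idx = np.unique(rec_times, return_inverse=True)
        name_to_idx = {n: j for j, n in enumerate(observed_names)}
        self.v_idx = np.array([name_to_idx[r.variable] for r in cond.records])
        self.values = np.array([r.value for r in cond.records])
        self.sigmas = np.array([r.sigma for r in cond.records])


def _compile(data: TimeSeriesSet) -> list[_CompiledCondition]:
    return [_CompiledCondition(c, data.observed_names) for c in data.conditions]


class _StackedData:
    """All constant-input conditions stacked into one block ODE system.

    Repeated cost evaluations integrate every condition simultaneously (the
    right-hand side vectorizes over conditions), which is far cheaper than
    one solver call per condition.  Conditions with time-varying inputs fall
    back to the per-condition path.
    """

    def __init__(self, compiled: list[_CompiledCondition]):
        self.n_c = len(compiled)
        self.x0_obs = np.stack([cc.x0 for cc in compiled])
        inputs = []
        for cc in compiled:
            if isinstance(cc.inputs, InputSignal):
                if len(cc.inputs.times) > 1:
                    raise ValueError("time-varying inputs cannot be stacked")
                inputs.append(cc.inputs.values[0])
            else:
                inputs.append(np.asarray(cc.inputs, float).reshape(-1))
        self.inputs = np.stack(inputs) if inputs else np.zeros((self.n_c, 0))
        all_times = np.concatenate([cc.times for cc in compiled])
        self.times = np.unique(all_times)
        t_pos = {t: i for i, t in enumerate(self.times)}
        c_idx, t_idx, v_idx, values, sigmas = [], [], [], [], []
        for c, cc in enumerate(compiled):
            for local_t, v, val, sig in zip(
                cc.t_idx, cc.v_idx, cc.values, cc.sigmas
            ):
                c_idx.append(c)
                t_idx.append(t_pos[cc.times[local_t]])
                v_idx.append(v)
                values.append(val)
                sigmas.append(sig)
        self.c_idx = np.array(c_idx)
        self.t_idx = np.array(t_idx)
        self.v_idx = np.array(v_idx)
        self.values = np.array(values)
        self.sigmas = np.array(sigmas)
        # active_mask[i, c]: does output time i precede condition c's last
        # record?  Pathologies after a condition's own records are ignored.
        last_t = np.zeros(self.n_c)
        np.maximum.at(last_t, self.c_idx, self.times[self.t_idx])
        self.active_mask = self.times[:, None] <= last_t[None, :]


def _try_stack(compiled: list[_CompiledCondition]) -> _StackedData | None:
    try:
        return _StackedData(compiled)
    except ValueError:
        return None


def _residuals_stacked(
    spec: ModelSpec,
    full,
    sd: _StackedData,
    config: FitConfig,
    counter: EvalCounter | None,
) -> tuple[np.ndarray, bool]:
    """Weighted data residuals via one stacked integration of all conditions."""
    from .simulate import BLOWUP_BOUND  # local to avoid hard coupling at import

    n_c, J = sd.n_c, spec.n_dynamical
    s_system = spec.model_class is ModelClass.S_SYSTEM
    x0 = np.hstack([sd.x0_obs, np.tile(full.hidden_x0, (n_c, 1))])
    nfe = [0]

    if s_system:
        alpha, beta, gT, hT = full.alpha, full.beta, full.g.T, full.h.T
    else:
        tau, WT, theta = full.tau, full.W.T, full.theta

    def f(xflat, t):
        # safe everywhere: solvers probe infeasible trial states, so clip
        # into the computable domain and saturate non-finite derivatives
        nfe[0] += 1
        X = xflat.reshape(n_c, J)
        with np.errstate(all="ignore"):
            if s_system:
                Xc = np.clip(X, 1e-12, BLOWUP_BOUND)
                logx = np.log(np.hstack([Xc, sd.inputs]))
                dx = alpha * np.exp(np.clip(logx @ gT, -700, 700)) - beta * np.exp(
                    np.clip(logx @ hT, -700, 700)
                )
            else:
                xf = np.hstack([X, sd.inputs])
                z = np.clip(theta - xf, -700, 700)
                dx = -X / tau + (1.0 / (1.0 + np.exp(z))) @ WT
        return np.nan_to_num(dx, nan=0.0, posinf=1e12, neginf=-1e12).ravel()

    teval = (
        sd.times
        if len(sd.times) and sd.times[0] == 0.0
        else np.concatenate([[0.0], sd.times])
    )
    if len(teval) == 1:  # all records at t=0: the initial state is the answer
        sol, solver_ok = x0.ravel()[None, :], True
    else:
        with np.errstate(all="ignore"):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                sol, solver_ok = odeint_stacked(
                    f, x0.ravel(), teval, config.rtol, config.atol,
                    band=J - 1, mxstep=config.max_steps,
                )
    states = sol[-len(sd.times):].reshape(len(sd.times), n_c, J)
    # a condition fails if any of its states, at any output time up to its
    # last record, is non-finite, beyond the blow-up bound, or (S-systems)
    # non-positive
    invalid = ~np.all(
        np.isfinite(states) & (np.abs(states) <= BLOWUP_BOUND), axis=2
    )
    if s_system:
        invalid |= np.any(states <= 0.0, axis=2)
    failed = np.any(invalid & sd.active_mask, axis=0)
    if s_system:
        failed |= np.any(x0 <= 0.0, axis=1)
    if not solver_ok:
        failed |= True
    preds = states[sd.t_idx, sd.c_idx, sd.v_idx]
    rec_failed = failed[sd.c_idx] | ~np.isfinite(preds)
    resid = np.where(rec_failed, _FAIL_RESIDUAL, (preds - sd.values) / sd.sigmas)
    if counter is not None:
        counter.total_model_evaluations += n_c
        counter.total_rhs_evaluations += nfe[0] * n_c
    return resid, not bool(rec_failed.any())


def odeint_stacked(f, x0, teval, rtol, atol, band=None, mxstep=2000):
    """odeint wrapper returning (solution, success_flag).

    ``band`` exploits the block-diagonal structure of stacked independent
    conditions: the Jacobian bandwidth is the per-condition dimension minus
    one, which keeps LSODA's stiff mode cheap.
    """
    from scipy.integrate import odeint

    sol, info = odeint(
        f, x0, teval, rtol=rtol, atol=atol,
        ml=band, mu=band,
        full_output=True, mxstep=mxstep, printmessg=False,
    )
    return sol, info["message"] == "Integration successful."


# ---------------------------------------------------------------------------
# Configuration, priors, parameter transform
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Priors, annealing schedule and optimizer settings for one fit.

    Defaults are weakly informative: scale-10 Gaussians on linear-scale
    parameters and ln(10)-scale log-normals on positive ones, a geometric
    temperature ladder from 10 to 1 for the exploration phase, and
    trust-region least squares for refinement.
    """

    prior_scale_linear: float = 10.0
    prior_scale_log: float = math.log(10.0)
    anneal_stages: int = 20
    proposals_per_stage: int = 50
    t_start: float = 10.0
    t_end: float = 1.0
    proposal_scale: float = 0.25
    max_nfev: int = 200
    opt_tol: float = 1e-8
    rtol: float = 1e-6
    atol: float = 1e-8
    max_steps: int = 2000   # internal solver steps per cost evaluation
    global_move_prob: float = 0.25  # chance of a prior-resample move
    log_floor: float = 1e-3
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_log_param(name: str, model_class: ModelClass) -> bool:
    head = name.split("_", 1)[0]
    if head in ("alpha", "beta", "tau"):
        return True
    if head == "x0":
        return model_class is ModelClass.S_SYSTEM  # positivity constraint
    return False


class _Transform:
    """Map named natural parameters <-> unconstrained optimization vector.

    Positive-constrained parameters are optimized on log scale, where their
    log-normal prior is Gaussian; everything else is linear.  Prior means are
    the neutral values (0 on linear / log scale), so warm-started additions
    start at their prior mode.
    """

    def __init__(self, spec: ModelSpec, config: FitConfig):
        self.spec = spec
        self.names = spec.active_params + spec.hidden_x0_names
        self.is_log = np.array(
            [_is_log_param(n, spec.model_class) for n in self.names]
        )
        self.prior_scale = np.where(
            self.is_log, config.prior_scale_log, config.prior_scale_linear
        )
        self.prior_mean = np.zeros(len(self.names))
        self.log_floor = config.log_floor

    @property
    def n(self) -> int:
        return len(self.names)

    def to_opt(self, natural: np.ndarray) -> np.ndarray:
        z = np.asarray(natural, float).copy()
        z[self.is_log] = np.log(np.maximum(z[self.is_log], self.log_floor))
        return z

    def from_opt(self, z: np.ndarray) -> np.ndarray:
        p = np.asarray(z, float).copy()
        p[self.is_log] = np.exp(p[self.is_log])
        return p

    def param_vector(self, z: np.ndarray) -> ParamVector:
        return ParamVector.from_array(self.spec, self.from_opt(z))

    def log_prior(self, z: np.ndarray) -> float:
        dev = (z - self.prior_mean) / self.prior_scale
        return float(
            -0.5 * np.sum(dev**2)
            - np.sum(np.log(self.prior_scale * math.sqrt(2 * math.pi)))
        )


# ---------------------------------------------------------------------------
# Cost functions
# ---------------------------------------------------------------------------

def _residuals_full(
    spec: ModelSpec,
    full,
    compiled: list[_CompiledCondition],
    config: FitConfig,
    counter: EvalCounter | None,
) -> tuple[np.ndarray, bool]:
    """Weighted data residuals; failed conditions filled with a sentinel."""
    chunks = []
    all_ok = True
    for cc in compiled:
        traj = integrate_full(
            spec, full, cc.x0, cc.inputs, cc.times,
            rtol=config.rtol, atol=config.atol, counter=counter,
        )
        if traj.status is not TrajectoryStatus.OK or len(traj.times) < len(cc.times):
            chunks.append(np.full(len(cc.values), _FAIL_RESIDUAL))
            all_ok = False
            continue
        pred = traj.states[cc.t_idx, cc.v_idx]
        chunks.append((pred - cc.values) / cc.sigmas)
    return np.concatenate(chunks) if chunks else np.zeros(0), all_ok


def _make_residual_fn(spec, compiled, config, counter):
    """Residual evaluator choosing the stacked fast path when possible."""
    sd = _try_stack(compiled)
    if sd is not None:
        return lambda full: _residuals_stacked(spec, full, sd, config, counter)
    return lambda full: _residuals_full(spec, full, compiled, config, counter)


def chi_squared(
    spec: ModelSpec,
    params: ParamVector,
    data: TimeSeriesSet,
    config: FitConfig | None = None,
    counter: EvalCounter | None = None,
) -> float:
    """Weighted sum of squared residuals over all measurement records.

    Any condition whose integration fails (positivity violation, blow-up,
    solver failure) makes the fit infinitely bad: returns ``inf``.
    """
    config = config or FitConfig()
    full = unpack_params(params)
    rfn = _make_residual_fn(spec, _compile(data), config, counter)
    resid, all_ok = rfn(full)
    if not all_ok:
        return math.inf
    return float(np.sum(resid**2))


def log_prior(params: ParamVector, config: FitConfig | None = None) -> float:
    """Log prior density of a parameter set (Gaussian on the fitting scale)."""
    config = config or FitConfig()
    trans = _Transform(params.spec, config)
    return trans.log_prior(trans.to_opt(params.as_array()))


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

class FitStatus(str, Enum):
    OK = "ok"
    DEGENERATE = "degenerate"
    FAILED = "failed"


@dataclass
class FitResult:
    """Best fit of one model plus the Laplace summary used for selection.

    ``hessian_eigenvalues`` are the eigenvalues of the data-only cost
    (chi2/2) curvature at the optimum in the prior-whitened basis, so the
    prior precision is 1 in every direction.
    """

    params: ParamVector
    chi2: float
    log_prior: float
    hessian_eigenvalues: np.ndarray
    n_nominal: int
    n_effective: int
    Lhat: float
    status: FitStatus
    cost: float = math.nan              # chi2/2 - log_prior at the optimum
    z_opt: np.ndarray | None = field(default=None, repr=False)
    hessian_whitened: np.ndarray | None = field(default=None, repr=False)
    config: FitConfig | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "log_prior": self.log_prior,
            "Lhat": self.Lhat,
            "n_nominal": self.n_nominal,
            "n_effective": self.n_effective,
            "status": self.status.value,
            "hessian_eigenvalues": [float(v) for v in self.hessian_eigenvalues],
            "params": dict(self.params.values),
        }


# ---------------------------------------------------------------------------
# Two-phase fitting
# ---------------------------------------------------------------------------

def _anneal(cost, z0, c0, trans, config, rng):
    """Temperature-ladder random walk; returns the best point seen.

    The proposal kernel mixes local Gaussian steps (all coordinates) with
    occasional global moves that resample one coordinate from its prior --
    the latter let parameters sitting at a switched-off neutral value (for
    example a new hidden variable's production rate) jump onto the scale
    where they influence the dynamics at all.
    """
    z, c = z0.copy(), c0
    best_z, best_c = z0.copy(), c0
    temps = np.geomspace(config.t_start, config.t_end, config.anneal_stages)
    for T in temps:
        step = config.proposal_scale * trans.prior_scale * math.sqrt(T / config.t_start)
        for _ in range(config.proposals_per_stage):
            if rng.random() < config.global_move_prob:
                zp = z.copy()
                i = int(rng.integers(trans.n))
                zp[i] = trans.prior_mean[i] + trans.prior_scale[i] * rng.normal()
            else:
                zp = z + rng.normal(size=trans.n) * step
            cp = cost(zp)
            if math.isfinite(cp) and (
                cp < c or rng.random() < math.exp(-min((cp - c) / T, 700.0))
            ):
                z, c = zp, cp
                if c < best_c:
                    best_z, best_c = z.copy(), c
    return best_z, best_c


def _fd_jacobian(resid_fn, z, rel_step=1e-5):
    """Central finite-difference Jacobian of a residual vector."""
    r0 = resid_fn(z)
    J = np.empty((len(r0), len(z)))
    for i in range(len(z)):
        h = rel_step * max(abs(z[i]), 1.0)
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        J[:, i] = (resid_fn(zp) - resid_fn(zm)) / (2 * h)
    return J


def fit_model(
    spec: ModelSpec,
    data: TimeSeriesSet,
    start: ParamVector,
    config: FitConfig | None = None,
    counter: EvalCounter | None = None,
) -> FitResult:
    """Fit one model to the data, starting from ``start`` (usually a warm
    start from the previous model in the hierarchy).

    Phase 1 explores with an annealed random walk on the posterior cost
    chi2/2 - log_prior; phase 2 refines the best point with trust-region
    least squares (data residuals plus prior residuals).  The result's cost
    never exceeds the cost at ``start``.  Fixed config seed => identical
    result.
    """
    config = config or FitConfig()
    if start.spec != spec:
        raise StructuralError("start parameters do not match the spec to fit")
    compiled = _compile(data)
    rfn = _make_residual_fn(spec, compiled, config, counter)
    trans = _Transform(spec, config)
    rng = np.random.default_rng(config.seed)

    def data_resid(z):
        return rfn(unpack_params(trans.param_vector(z)))[0]

    def cost_at(z):
        r, all_ok = rfn(unpack_params(trans.param_vector(z)))
        if not all_ok:
            return math.inf
        return 0.5 * float(np.sum(r**2)) - trans.log_prior(z)

    # exact start cost (no log-floor distortion): evaluate at natural values
    start_chi2 = chi_squared(spec, start, data, config, counter)
    z0 = trans.to_opt(start.as_array())
    start_cost = (
        0.5 * start_chi2 - log_prior(start, config)
        if math.isfinite(start_chi2)
        else math.inf
    )

    z_best, c_best = z0, cost_at(z0)
    if config.anneal_stages > 0 and config.proposals_per_stage > 0:
        z_best, c_best = _anneal(cost_at, z_best, c_best, trans, config, rng)

    if not math.isfinite(c_best) and not math.isfinite(start_cost):
        return FitResult(
            params=start, chi2=math.inf, log_prior=log_prior(start, config),
            hessian_eigenvalues=np.full(trans.n, math.nan),
            n_nominal=spec.n_nominal, n_effective=0, Lhat=-math.inf,
            status=FitStatus.FAILED, cost=math.inf, config=config,
        )

    def ls_resid(z):
        r = data_resid(z)
        prior_r = (z - trans.prior_mean) / trans.prior_scale
        return np.concatenate([r, prior_r])

    if math.isfinite(c_best) and config.max_nfev > 0:
        sol = least_squares(
            ls_resid, z_best, method="trf",
            max_nfev=config.max_nfev,
            xtol=config.opt_tol, ftol=config.opt_tol, gtol=config.opt_tol,
        )
        c_ref = cost_at(sol.x)
        if c_ref < c_best:
            z_best, c_best = sol.x, c_ref

    # monotone contract: never worse than the warm start
    if start_cost <= c_best:
        z_best = z0
        c_best = start_cost
        chi2_best = start_chi2
        params_best = start
    else:
        params_best = trans.param_vector(z_best)
        chi2_best = chi_squared(spec, params_best, data, config, counter)
    lp_best = trans.log_prior(z_best)

    # Laplace summary: data-cost curvature in the prior-whitened basis
    status = FitStatus.OK
    if math.isfinite(chi2_best):
        J = _fd_jacobian(data_resid, z_best)
        H_z = J.T @ J  # Gauss-Newton curvature of chi2/2
        S = np.diag(trans.prior_scale)
        H_w = S @ H_z @ S
        lam = clamp_eigenvalues(np.linalg.eigvalsh(0.5 * (H_w + H_w.T)))
        if not np.all(np.isfinite(lam)):
            lam = np.zeros(trans.n)
            status = FitStatus.DEGENERATE
    else:
        H_w = np.zeros((trans.n, trans.n))
        lam = np.full(trans.n, math.nan)
        status = FitStatus.FAILED

    n_eff = (
        effective_parameter_count(lam) if status is not FitStatus.FAILED else 0
    )
    Lhat = (
        log_likelihood_estimate(chi2_best, lp_best, lam)
        if status is not FitStatus.FAILED
        else -math.inf
    )
    return FitResult(
        params=params_best,
        chi2=chi2_best,
        log_prior=lp_best,
        hessian_eigenvalues=lam,
        n_nominal=spec.n_nominal,
        n_effective=n_eff,
        Lhat=Lhat,
        status=status,
        cost=c_best,
        z_opt=z_best,
        hessian_whitened=H_w,
        config=config,
    )


# ---------------------------------------------------------------------------
# Posterior sampling (Laplace approximation)
# ---------------------------------------------------------------------------

def posterior_sample(
    fit: FitResult,
    spec: ModelSpec,
    data: TimeSeriesSet,
    n_samples: int,
    seed: int = 0,
) -> list[ParamVector]:
    """Draw parameter sets from the Gaussian (Laplace) posterior at the fit.

    The covariance is the pseudo-inverse of the posterior curvature (data
    curvature plus unit prior precision, in the whitened basis); singular
    directions fall back to the prior scale.
    """
    if fit.status is FitStatus.FAILED:
        raise StructuralError("cannot sample the posterior of a failed fit")
    if n_samples == 0:
        return []
    config = fit.config or FitConfig()
    trans = _Transform(spec, config)
    H_post = fit.hessian_whitened + np.eye(trans.n)
    lam, Q = np.linalg.eigh(0.5 * (H_post + H_post.T))
    lam = np.maximum(lam, 1e-12)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_samples, trans.n)) / np.sqrt(lam)
    dz_w = draws @ Q.T
    dz = dz_w * trans.prior_scale  # unwhiten
    return [trans.param_vector(fit.z_opt + d) for d in dz]
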