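"""Phenomenological ODE model classes: S-systems and sigmoidal networks.

Two nested-complete model families are implemented, both able to approximate
any smooth dynamics given enough (hidden) variables:

* **S-systems** -- each variable's rate is a difference of a production and a
  degradation term, each a product of powers of all variables (a
  generalization of mass-action kinetics)::

      dx_i/dt = alpha_i * prod_j x_j**g_ij  -  beta_i * prod_j x_j**h_ij

* **Sigmoidal (CTRNN-style) networks** -- each variable relaxes with a time
  constant and is driven by a weighted sum of saturating functions of the
  variables::

      dx_i/dt = -x_i / tau_i + sum_j W_ij * xi(theta_j - x_j)

  with ``xi(y) = 1 / (1 + exp(y))``.

A model has ``n_observed`` measured variables, ``n_hidden`` unmeasured
dynamical variables (whose initial values are fit parameters), and
``n_inputs`` externally controlled inputs that enter both classes as constant
pseudo-variables appended after the dynamical ones.

Parameter naming: dynamical variables are numbered 1..J (observed first,
hidden after), inputs are labelled ``I1..IK``.  S-system names are
``alpha_i``, ``beta_i``, ``g_i_j``, ``h_i_j``; sigmoidal names are ``tau_i``,
``theta_j``, ``w_i_j``; hidden initial conditions are ``x0_i``.  Inactive
parameters are pinned at neutral values (exponents and weights 0, prefactors
of absent terms 0, tau 1) so that models earlier in a hierarchy are exact
restrictions of later ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelClass",
    "ModelSpec",
    "SSystemParams",
    "SigmoidalParams",
    "ParamVector",
    "sigmoid",
    "ssystem_rhs",
    "sigmoidal_rhs",
    "pack_params",
    "unpack_params",
    "PositivityError",
    "SIGMOID_CONVENTION",
]

#: Serialized tag disambiguating the sigmoid argument convention: one offset
#: per *source* variable, sigmoid applied per source before the weighted sum.
SIGMOID_CONVENTION = "per_source: xi(theta_j - x_j), xi(y) = 1/(1+exp(y))"


class ModelClass(str, Enum):
    S_SYSTEM = "s_system"
    SIGMOIDAL = "sigmoidal"


class PositivityError(ValueError):
    """S-system dynamics evaluated at a non-positive state.

    Power laws with real exponents are ill-defined for non-positive
    arguments, so the S-system class requires strictly positive states.
    """


class StructuralError(ValueError):
    """Parameter container inconsistent with its ModelSpec."""


# ---------------------------------------------------------------------------
# Specs and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A point in a model hierarchy.

    ``active_params`` lists the structural parameters free to vary, in
    hierarchy order; every name not listed is pinned at its neutral value.
    Hidden initial conditions (``x0_i``) are fitted but tracked through
    ``n_hidden`` rather than ``active_params``.
    """

    model_class: ModelClass
    n_observed: int
    n_hidden: int = 0
    n_inputs: int = 0
    active_params: tuple[str, ...] = ()
    hierarchy_index: int = -1

    def __post_init__(self) -> None:
        if self.n_observed < 1:
            raise StructuralError("need at least one observed variable")
        if self.n_hidden < 0 or self.n_inputs < 0:
            raise StructuralError("n_hidden and n_inputs must be >= 0")

    @property
    def n_dynamical(self) -> int:
        """J, the total number of dynamical variables (observed + hidden)."""
        return self.n_observed + self.n_hidden

    @property
    def n_sources(self) -> int:
        """J + K: dynamical variables plus input pseudo-variables."""
        return self.n_dynamical + self.n_inputs

    @property
    def hidden_x0_names(self) -> tuple[str, ...]:
        return tuple(
            f"x0_{i}" for i in range(self.n_observed + 1, self.n_dynamical + 1)
        )

    @property
    def n_nominal(self) -> int:
        """Number of fitted parameters (active structural + hidden x0)."""
        return len(self.active_params) + self.n_hidden

    def source_label(self, j: int) -> str:
        """Name of source column ``j`` (0-based): 1..J then I1..IK."""
        if j < self.n_dynamical:
            return str(j + 1)
        return f"I{j - self.n_dynamical + 1}"

    def source_index(self, label: str) -> int:
        """Inverse of :meth:`source_label`."""
        if label.startswith("I"):
            k = int(label[1:])
            if not 1 <= k <= self.n_inputs:
                raise StructuralError(f"unknown input label {label!r}")
            return self.n_dynamical + k - 1
        i = int(label)
        if not 1 <= i <= self.n_dynamical:
            raise StructuralError(f"unknown variable label {label!r}")
        return i - 1


@dataclass
class SSystemParams:
    """Full parameter arrays for an S-system of J variables and K inputs."""

    alpha: np.ndarray      # (J,)  production prefactors, >= 0
    beta: np.ndarray       # (J,)  degradation prefactors, >= 0
    g: np.ndarray          # (J, J+K) production exponents, any sign
    h: np.ndarray          # (J, J+K) degradation exponents, any sign
    hidden_x0: np.ndarray  # (n_hidden,) hidden initial values, > 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        self.g = np.atleast_2d(np.asarray(self.g, float))
        self.h = np.atleast_2d(np.asarray(self.h, float))
        self.hidden_x0 = np.asarray(self.hidden_x0, float)
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise StructuralError("alpha and beta must be non-negative")


@dataclass
class SigmoidalParams:
    """Full parameter arrays for a sigmoidal network of J variables, K inputs."""

    tau: np.ndarray        # (J,)   time constants, > 0
    W: np.ndarray          # (J, J+K) interaction weights
    theta: np.ndarray      # (J+K,) per-source sigmoid offsets
    hidden_x0: np.ndarray  # (n_hidden,) hidden initial values (real)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        self.W = np.atleast_2d(np.asarray(self.W, float))
        self.theta = np.asarray(self.theta, float)
        self.hidden_x0 = np.asarray(self.hidden_x0, float)
        if np.any(self.tau <= 0):
            raise StructuralError("time constants tau must be positive")


@dataclass
class ParamVector:
    """Named parameter values for a ModelSpec.

    ``values`` covers exactly ``spec.active_params`` plus the hidden initial
    conditions; it round-trips losslessly through pack/unpack.
    """

    spec: ModelSpec
    values: dict[str, float]

    def __post_init__(self) -> None:
        expected = set(self.spec.active_params) | set(self.spec.hidden_x0_names)
        got = set(self.values)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise StructuralError(
                f"ParamVector keys mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        """Canonical ordering: active params in hierarchy order, then x0s."""
        return self.spec.active_params + self.spec.hidden_x0_names

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.names], float)

    @classmethod
    def from_array(cls, spec: ModelSpec, arr: np.ndarray) -> "ParamVector":
        names = spec.active_params + spec.hidden_x0_names
        if len(arr) != len(names):
            raise StructuralError(
                f"expected {len(names)} values, got {len(arr)}"
            )
        return cls(spec, dict(zip(names, (float(v) for v in arr))))


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def sigmoid(y):
    """Saturating function xi(y) = 1 / (1 + exp(y)), numerically stable.

    Decreasing in ``y``; xi(0) = 1/2; xi(y) + xi(-y) = 1.  Saturates cleanly
    at 0 and 1 for large |y| instead of overflowing.
    """
    return expit(-np.asarray(y, float))


def ssystem_rhs(state, inputs, params: SSystemParams) -> np.ndarray:
    """S-system time derivative at a strictly positive state.

    ``dx_i/dt = alpha_i prod_j x_j**g_ij - beta_i prod_j x_j**h_ij`` with the
    K inputs appended to the J dynamical variables as x_{J+k} = I_k.
    """
    state = np.asarray(state, float)
    inputs = np.asarray(inputs, float).reshape(-1)
    if np.any(state <= 0) or not np.all(np.isfinite(state)):
        raise PositivityError(
            "S-system dynamics are ill-defined at non-positive states"
        )
    x = np.concatenate([state, inputs])
    logx = np.log(x)
    prod_g = np.exp(params.g @ logx)
    prod_h = np.exp(params.h @ logx)
    return params.alpha * prod_g - params.beta * prod_h


def sigmoidal_rhs(state, inputs, params: SigmoidalParams) -> np.ndarray:
    """Sigmoidal-network time derivative.

    ``dx_i/dt = -x_i/tau_i + sum_j W_ij xi(theta_j - x_j)`` with inputs as
    appended pseudo-variables.
    """
    state = np.asarray(state, float)
    inputs = np.asarray(inputs, float).reshape(-1)
    x = np.concatenate([state, inputs])
    return -state / params.tau + params.W @ sigmoid(params.theta - x)


# ---------------------------------------------------------------------------
# Packing / unpacking
# ---------------------------------------------------------------------------

def _neutral_hidden_x0(model_class: ModelClass) -> float:
    # positivity forces 1 for S-systems; 0 is the natural origin for sigmoids
    return 1.0 if model_class is ModelClass.S_SYSTEM else 0.0


def _full_arrays(spec: ModelSpec):
    """Neutral-valued full parameter arrays for a spec."""
    J, JK = spec.n_dynamical, spec.n_sources
    if spec.model_class is ModelClass.S_SYSTEM:
        return SSystemParams(
            alpha=np.zeros(J), beta=np.zeros(J),
            g=np.zeros((J, JK)), h=np.zeros((J, JK)),
            hidden_x0=np.full(spec.n_hidden, 1.0),
        )
    return SigmoidalParams(
        tau=np.ones(J), W=np.zeros((J, JK)), theta=np.zeros(JK),
        hidden_x0=np.zeros(spec.n_hidden),
    )


def _param_slot(spec: ModelSpec, name: str):
    """Map a parameter name to (array attribute, index tuple)."""
    if name.startswith("x0_"):
        i = int(name[3:])
        return "hidden_x0", (i - spec.n_observed - 1,)
    head, _, rest = name.partition("_")
    if head in ("alpha", "beta", "tau"):
        return head, (int(rest) - 1,)
    if head == "theta":
        return "theta", (spec.source_index(rest),)
    if head in ("g", "h", "w"):
        i_str, _, j_str = rest.partition("_")
        attr = "W" if head == "w" else head
        return attr, (int(i_str) - 1, spec.source_index(j_str))
    raise StructuralError(f"unrecognized parameter name {name!r}")


def unpack_params(v: ParamVector):
    """Expand a named ParamVector into full class-specific arrays.

    Inactive entries take their neutral values so that the returned arrays
    define exactly the restricted model.
    """
    full = _full_arrays(v.spec)
    for name, value in v.values.items():
        attr, idx = _param_slot(v.spec, name)
        getattr(full, attr)[idx] = value
    return full


def pack_params(params, spec: ModelSpec) -> ParamVector:
    """Collect the active entries of full parameter arrays into a ParamVector."""
    J, JK = spec.n_dynamical, spec.n_sources
    expect = SSystemParams if spec.model_class is ModelClass.S_SYSTEM else SigmoidalParams
    if not isinstance(params, expect):
        raise StructuralError(
            f"{type(params).__name__} does not match model class {spec.model_class}"
        )
    shapes = {
        "alpha": (J,), "beta": (J,), "tau": (J,),
        "g": (J, JK), "h": (J, JK), "W": (J, JK),
        "theta": (JK,), "hidden_x0": (spec.n_hidden,),
    }
    for attr in vars(params):
        arr = getattr(params, attr)
        if arr.shape != shapes[attr]:
            raise StructuralError(
                f"{attr} has shape {arr.shape}, expected {shapes[attr]}"
            )
    values = {}
    for name in spec.active_params + spec.hidden_x0_names:
        attr, idx = _param_slot(spec, name)
        values[name] = float(getattr(params, attr)[idx])
    return ParamVector(spec, values)


def rhs(spec: ModelSpec, params, state, inputs) -> np.ndarray:
    """Dispatch to the class right-hand side for full parameter arrays."""
    if spec.model_class is ModelClass.S_SYSTEM:
        return ssystem_rhs(state, inputs, params)
    return sigmoidal_rhs(state, inputs, params)
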