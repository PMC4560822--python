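"""A-priori ordered, nested hierarchies of model specifications.

The adaptive search needs a single ordered list of models of growing
complexity, jointly increasing the degree of nonlinearity (number of
interaction terms / exponents) and the number of hidden variables.  The
ordering is fixed before seeing any data.

Construction rule
-----------------
Models are enumerated by strictly increasing nominal parameter count.  The
first model is minimal: no hidden variables and, per observed variable, only
the parameters needed for independent production/decay (S-systems:
``alpha_i, beta_i, h_i_i``; sigmoidal: ``tau_i, theta_i, w_i_i``).  Each
subsequent model activates the next interaction parameter in a fixed
row-major sweep over (target, source) pairs; once the model at the current
hidden-variable count is fully connected, the next model instead introduces a
new hidden variable (its own time constant / production-degradation pair,
self-term, initial value, and coupling to the most recently added dynamical
variable), after which the row-major sweep resumes over the enlarged network.
Because parameters are only ever appended, every model is an exact
restriction of every later model (earlier parameters stay active, newly
added ones are neutral-initialized), which is what warm starting and the
one-peak model-selection argument rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .model_classes import (
    ModelClass,
    ModelSpec,
    ParamVector,
    StructuralError,
    _neutral_hidden_x0,
)

__all__ = ["Hierarchy", "build_hierarchy", "warm_start_params", "neutral_value"]


def neutral_value(name: str, model_class: ModelClass) -> float:
    """Value at which a parameter leaves the dynamics unchanged when added."""
    head = name.split("_", 1)[0]
    if head == "tau":
        return 1.0
    if head == "x0":
        return _neutral_hidden_x0(model_class)
    # alpha, beta, exponents, weights, offsets: absent term / flat exponent
    return 0.0


def _source_labels(n_dynamical: int, n_inputs: int) -> list[str]:
    return [str(j) for j in range(1, n_dynamical + 1)] + [
        f"I{k}" for k in range(1, n_inputs + 1)
    ]


def _enumerate_steps(model_class: ModelClass, n_observed: int, n_inputs: int):
    """Yield (names_added, n_hidden) for each successive model, indefinitely."""
    sig = model_class is ModelClass.SIGMOIDAL
    active: set[str] = set()
    n_hidden = 0

    def minimal() -> list[str]:
        names = []
        for i in range(1, n_observed + 1):
            if sig:
                names += [f"tau_{i}", f"theta_{i}", f"w_{i}_{i}"]
            else:
                names += [f"alpha_{i}", f"beta_{i}", f"h_{i}_{i}"]
        return names

    def fill_steps():
        """Row-major sweep over missing interaction terms at this n_hidden."""
        J = n_observed + n_hidden
        for i in range(1, J + 1):
            for lab in _source_labels(J, n_inputs):
                if sig:
                    step = []
                    if f"theta_{lab}" not in active:
                        step.append(f"theta_{lab}")
                    if f"w_{i}_{lab}" not in active:
                        step.append(f"w_{i}_{lab}")
                    if step:
                        yield step
                else:
                    for sym in ("g", "h"):
                        if f"{sym}_{i}_{lab}" not in active:
                            yield [f"{sym}_{i}_{lab}"]

    def hidden_block(v: int) -> list[str]:
        prev = v - 1
        if sig:
            names = [f"tau_{v}", f"theta_{v}", f"w_{v}_{v}"]
            if prev >= 1:
                names += [f"w_{v}_{prev}", f"w_{prev}_{v}"]
        else:
            names = [f"alpha_{v}", f"beta_{v}", f"h_{v}_{v}"]
            if prev >= 1:
                names += [f"g_{v}_{prev}", f"g_{prev}_{v}"]
        return names

    step = minimal()
    while True:
        active.update(step)
        yield list(step), n_hidden
        for step in fill_steps():
            active.update(step)
            yield list(step), n_hidden
        n_hidden += 1
        step = hidden_block(n_observed + n_hidden)


@dataclass(frozen=True)
class Hierarchy:
    """Deterministic ordered list of nested ModelSpecs for one model class."""

    model_class: ModelClass
    n_observed: int
    n_inputs: int
    specs: tuple[ModelSpec, ...]

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, m: int) -> ModelSpec:
        return self.specs[m]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "hierarchy_index": s.hierarchy_index,
                    "model_class": s.model_class.value,
                    "n_observed": s.n_observed,
                    "n_hidden": s.n_hidden,
                    "n_inputs": s.n_inputs,
                    "n_nominal": s.n_nominal,
                    "active_params": list(s.active_params),
                }
                for s in self.specs
            ],
            indent=1,
        )


def build_hierarchy(
    model_class: ModelClass | str,
    n_observed: int,
    n_inputs: int = 0,
    max_models: int = 20,
) -> Hierarchy:
    """Build the first ``max_models`` specs of the a-priori hierarchy.

    Deterministic: identical arguments always produce identical hierarchies.
    Nominal parameter counts are strictly increasing along the list.
    """
    if n_observed < 1 or max_models < 1:
        raise StructuralError("need n_observed >= 1 and max_models >= 1")
    model_class = ModelClass(model_class)
    specs: list[ModelSpec] = []
    names: list[str] = []
    gen = _enumerate_steps(model_class, n_observed, n_inputs)
    for m in range(max_models):
        added, n_hidden = next(gen)
        names = names + added
        specs.append(
            ModelSpec(
                model_class=model_class,
                n_observed=n_observed,
                n_hidden=n_hidden,
                n_inputs=n_inputs,
                active_params=tuple(names),
                hierarchy_index=m,
            )
        )
    return Hierarchy(model_class, n_observed, n_inputs, tuple(specs))


def warm_start_params(prev_fit: ParamVector, next_spec: ModelSpec) -> ParamVector:
    """Start values for ``next_spec`` from a simpler model's best fit.

    Shared parameters are copied; newly activated ones take their neutral
    values, so the richer model's initial trajectories (and hence its initial
    goodness of fit) equal those of the simpler model at its optimum.
    """
    prev_spec = prev_fit.spec
    compatible = (
        prev_spec.model_class == next_spec.model_class
        and prev_spec.n_observed == next_spec.n_observed
        and prev_spec.n_inputs == next_spec.n_inputs
        and prev_spec.n_hidden <= next_spec.n_hidden
        and next_spec.active_params[: len(prev_spec.active_params)]
        == prev_spec.active_params
    )
    if not compatible:
        raise StructuralError(
            "specs are not an ordered pair from the same hierarchy"
        )
    values = dict(prev_fit.values)
    for name in next_spec.active_params + next_spec.hidden_x0_names:
        if name not in values:
            values[name] = neutral_value(name, next_spec.model_class)
    return ParamVector(next_spec, values)
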