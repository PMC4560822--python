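"""Readers and writers: time-series CSV + JSON sidecar, model JSON and SBML.

Time series travel as tidy CSV (columns condition, time, variable, value,
sigma; UTF-8, '.' decimal, no index) with a JSON sidecar holding what the
table cannot: per-condition inputs (constant or piecewise) and known
observed initial values.  Models serialize to JSON (exact parameter values
plus the sigmoid-argument convention tag) and to SBML Level 3 rate rules
for exchange with standard kinetic-modelling tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_classes import (
    SIGMOID_CONVENTION,
    ModelClass,
    ModelSpec,
    ParamVector,
    unpack_params,
)
from .simulate import InputSignal

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "export_model",
    "load_model",
    "sidecar_path",
]

_COLUMNS = ["condition", "time", "variable", "value", "sigma"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _inputs_to_jsonable(inputs):
    if isinstance(inputs, InputSignal):
        return {
            "times": [float(t) for t in inputs.times],
            "values": [[float(v) for v in row] for row in inputs.values],
        }
    return [float(v) for v in np.asarray(inputs, float).reshape(-1)]


def _inputs_from_jsonable(obj):
    if isinstance(obj, dict):
        return InputSignal(np.asarray(obj["times"]), np.asarray(obj["values"]))
    return np.asarray(obj, float)


def write_timeseries(data, path) -> None:
    """Write a TimeSeriesSet as CSV + JSON sidecar (lossless round trip)."""
    path = Path(path)
    rows = [
        (c.id, r.time, r.variable, r.value, r.sigma)
        for c in data.conditions
        for r in c.records
    ]
    # %.17g guarantees binary round-trip of IEEE doubles through text
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = {
        "observed_names": list(data.observed_names),
        "conditions": {
            c.id: {
                "inputs": _inputs_to_jsonable(c.inputs),
                "observed_x0": [float(v) for v in c.observed_x0],
            }
            for c in data.conditions
        },
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_timeseries(path):
    """Read a TimeSeriesSet written by :func:`write_timeseries`.

    Validation names the offending row and column; duplicate
    (condition, time, variable) keys, non-positive sigmas, non-numeric
    fields and empty files are all rejected explicitly.
    """
    from .fit import Condition, Record, TimeSeriesSet  # avoid import cycle

    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    if table.empty:
        raise ValueError(f"{path}: no measurement records (empty data set)")
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time", "value", "sigma"):
        converted = pd.to_numeric(table[col], errors="coerce")
        nonnum = converted.isna()
        if nonnum.any():
            row = int(np.flatnonzero(nonnum)[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        table[col] = converted
    bad_sigma = table["sigma"] <= 0
    if bad_sigma.any():
        row = int(np.flatnonzero(bad_sigma)[0])
        raise ValueError(
            f"{path}: sigma <= 0 in column 'sigma' at data row {row}"
        )
    dup = table.duplicated(subset=["condition", "time", "variable"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(
            f"{path}: duplicate (condition, time, variable) key at data row {row}"
        )

    side = json.loads(sidecar_path(path).read_text())
    observed = list(side["observed_names"])
    conditions = []
    for cid, group in table.groupby("condition", sort=False):
        meta = side["conditions"].get(str(cid))
        if meta is None:
            raise ValueError(f"{path}: condition {cid!r} missing from sidecar")
        records = [
            Record(float(r.time), str(r.variable), float(r.value), float(r.sigma))
            for r in group.itertuples()
        ]
        conditions.append(
            Condition(
                id=str(cid),
                inputs=_inputs_from_jsonable(meta["inputs"]),
                observed_x0=np.asarray(meta["observed_x0"], float),
                records=records,
            )
        )
    return TimeSeriesSet(observed, conditions)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def export_model(spec: ModelSpec, params: ParamVector, path, format: str = "json"):
    """Write a fitted model to JSON (exact values) or SBML L3 (rate rules)."""
    path = Path(path)
    if format == "json":
        doc = {
            "model_class": spec.model_class.value,
            "n_observed": spec.n_observed,
            "n_hidden": spec.n_hidden,
            "n_inputs": spec.n_inputs,
            "hierarchy_index": spec.hierarchy_index,
            "active_params": list(spec.active_params),
            "sigmoid_convention": (
                SIGMOID_CONVENTION
                if spec.model_class is ModelClass.SIGMOIDAL
                else None
            ),
            "params": {k: float(v) for k, v in params.values.items()},
        }
        path.write_text(json.dumps(doc, indent=1))
    elif format == "sbml":
        path.write_text(_to_sbml(spec, params))
    else:
        raise ValueError(f"unsupported export format {format!r}")
    return path


def load_model(path) -> tuple[ModelSpec, ParamVector]:
    """Inverse of JSON :func:`export_model`; bit-exact on parameter values."""
    doc = json.loads(Path(path).read_text())
    spec = ModelSpec(
        model_class=ModelClass(doc["model_class"]),
        n_observed=doc["n_observed"],
        n_hidden=doc["n_hidden"],
        n_inputs=doc["n_inputs"],
        active_params=tuple(doc["active_params"]),
        hierarchy_index=doc["hierarchy_index"],
    )
    return spec, ParamVector(spec, {k: float(v) for k, v in doc["params"].items()})


def _var_id(spec: ModelSpec, j: int) -> str:
    lab = spec.source_label(j)
    return f"input_{lab[1:]}" if lab.startswith("I") else f"x_{lab}"


def _sbml_formula(spec: ModelSpec, full, i: int) -> str:
    """Explicit rate-rule formula for dynamical variable i (0-based)."""
    terms_pos, terms_neg = [], []
    if spec.model_class is ModelClass.S_SYSTEM:
        for coef, exps, bucket in (
            (full.alpha[i], full.g[i], terms_pos),
            (full.beta[i], full.h[i], terms_neg),
        ):
            if coef == 0.0:
                continue
            factors = [repr(float(coef))] + [
                f"pow({_var_id(spec, j)}, {repr(float(e))})"
                for j, e in enumerate(exps)
                if e != 0.0
            ]
            bucket.append(" * ".join(factors))
    else:
        terms_neg.append(f"x_{i + 1} / {repr(float(full.tau[i]))}")
        for j in range(spec.n_sources):
            w = full.W[i, j]
            if w == 0.0:
                continue
            xi = f"1 / (1 + exp({repr(float(full.theta[j]))} - {_var_id(spec, j)}))"
            terms_pos.append(f"{repr(float(w))} * ({xi})")
    expr = " + ".join(terms_pos) if terms_pos else "0"
    for t in terms_neg:
        expr += f" - {t}"
    return expr


def _to_sbml(spec: ModelSpec, params: ParamVector) -> str:
    import libsbml

    full = unpack_params(params)
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("phenodyn_model")
    model.setNotes(
        f"<body xmlns='http://www.w3.org/1999/xhtml'><p>"
        f"{spec.model_class.value} phenomenological model; "
        f"sigmoid convention: {SIGMOID_CONVENTION}</p></body>"
    )
    x0 = {**{f"x_{i+1}": 1.0 for i in range(spec.n_dynamical)}}
    for h, name in enumerate(spec.hidden_x0_names):
        x0[f"x_{spec.n_observed + h + 1}"] = float(params.values[name])
    for i in range(spec.n_dynamical):
        p = model.createParameter()
        p.setId(f"x_{i + 1}")
        p.setValue(x0[f"x_{i + 1}"])
        p.setConstant(False)
    for k in range(spec.n_inputs):
        p = model.createParameter()
        p.setId(f"input_{k + 1}")
        p.setValue(0.0)
        p.setConstant(True)
    for i in range(spec.n_dynamical):
        rule = model.createRateRule()
        rule.setVariable(f"x_{i + 1}")
        math_ast = libsbml.parseL3Formula(_sbml_formula(spec, full, i))
        if math_ast is None:
            raise RuntimeError(f"could not parse rate formula for x_{i + 1}")
        rule.setMath(math_ast)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise RuntimeError(doc.getErrorLog().toString())
    return libsbml.writeSBMLToString(doc)
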