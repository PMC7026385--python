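"""Readers and writers for the package's plain-text interchange formats.

* Item parameter tables: CSV with columns ``item,beta0,beta1`` or the JSON
  equivalent ``{item_id: {"beta0": ..., "beta1": ...}}``.
* Response matrices: CSV, header row of item IDs, one 0/1 row per subject.
* Estimates: JSON with the item table, the row-major covariance and an index
  legend so the stacked parameter order is explicit.
* Misfit / copula specifications: YAML (or JSON — YAML is a superset).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .misfit import CopulaSpec, MisfitItemSpec
from .mml import EstimateWithCovariance
from .model_core import ItemParameters, ResponseMatrix

__all__ = [
    "read_item_parameters",
    "write_item_parameters",
    "read_responses",
    "write_responses",
    "estimates_to_dict",
    "write_estimates",
    "load_misfit_specs",
    "load_copula_spec",
]


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


def read_item_parameters(path) -> ItemParameters:
    path = Path(path)
    if path.suffix.lower() == ".json":
        table = json.loads(path.read_text())
        ids = [_maybe_int(k) for k in table]
        beta0 = [table[k]["beta0"] for k in table]
        beta1 = [table[k]["beta1"] for k in table]
        return ItemParameters(tuple(ids), np.array(beta0), np.array(beta1))
    df = pd.read_csv(path)
    missing = {"item", "beta0", "beta1"} - set(df.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns: {sorted(missing)}")
    return ItemParameters(
        tuple(_maybe_int(i) for i in df["item"]),
        df["beta0"].to_numpy(float),
        df["beta1"].to_numpy(float),
    )


def write_item_parameters(params: ItemParameters, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        table = {
            str(i): {"beta0": float(b0), "beta1": float(b1)}
            for i, b0, b1 in zip(params.item_ids, params.beta0, params.beta1)
        }
        path.write_text(json.dumps(table, indent=1))
        return
    pd.DataFrame(
        {"item": params.item_ids, "beta0": params.beta0, "beta1": params.beta1}
    ).to_csv(path, index=False)


def read_responses(path) -> ResponseMatrix:
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("response matrix must not contain missing values")
    return ResponseMatrix(
        data=df.to_numpy(dtype=np.int8),
        item_ids=tuple(_maybe_int(c) for c in df.columns),
    )


def write_responses(data: ResponseMatrix, path) -> None:
    pd.DataFrame(data.data, columns=[str(i) for i in data.item_ids]).to_csv(
        path, index=False
    )


def estimates_to_dict(est: EstimateWithCovariance) -> dict:
    ids = est.params.item_ids
    legend = []
    for i in ids:
        legend += [f"beta0[{i}]", f"beta1[{i}]"]
    return {
        "estimator": est.estimator_tag,
        "n_subjects": est.n_subjects,
        "converged": est.converged,
        "items": {
            str(i): {"beta0": float(b0), "beta1": float(b1)}
            for i, b0, b1 in zip(ids, est.params.beta0, est.params.beta1)
        },
        "covariance_index": legend,
        "covariance": np.asarray(est.covariance).ravel().tolist(),
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in est.diagnostics.items()
        },
    }


def write_estimates(est: EstimateWithCovariance, path) -> None:
    Path(path).write_text(json.dumps(estimates_to_dict(est), indent=1))


def load_misfit_specs(path) -> tuple[MisfitItemSpec, ...]:
    """YAML layout: ``misfit: [{item: 3, family: bounded, a: ..., ...}]``."""
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["misfit"] if isinstance(doc, dict) else doc
    return tuple(
        MisfitItemSpec(
            item_id=_maybe_int(e["item"]),
            family=e["family"],
            a=float(e["a"]),
            b=float(e["b"]),
            c=float(e["c"]),
            l=float(e["l"]),
        )
        for e in entries
    )


def load_copula_spec(path) -> CopulaSpec:
    """YAML layout: ``copula: {rho: 0.5, pairs: [[1, 2], [4, 5]]}``."""
    doc = yaml.safe_load(Path(path).read_text())
    spec = doc["copula"] if "copula" in doc else doc
    pairs = [tuple(_maybe_int(i) for i in p) for p in spec["pairs"]]
    return CopulaSpec(pairs, spec["rho"])
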