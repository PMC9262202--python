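"""Delimited-table input and JSON model persistence.

Feature tables are CSV/TSV with samples in rows, numeric variables in
columns and one label column; missing values are rejected rather than
imputed.  Fitted models round-trip through a versioned JSON schema; floats
are serialised at full precision so reloaded models predict bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hyperplane
from .exceptions import SchemaError, ValidationError
from .model import LPDAResults
from .multiclass import PairwiseLPDAResults
from .pca import PCAModel

__all__ = ["LabeledTable", "read_labeled_table", "write_labeled_table",
           "save_model", "load_model", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LabeledTable:
    """Numeric feature matrix with per-sample group labels."""

    features: np.ndarray
    feature_names: list
    sample_ids: list
    labels: np.ndarray

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def to_frame(self, label_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names,
                          index=pd.Index(self.sample_ids, name="sample"))
        df.insert(0, label_column, self.labels)
        return df


def read_labeled_table(path, label_column: str = "group",
                       delimiter: str = ",") -> LabeledTable:
    """Parse a delimited table, validating that every feature cell is numeric.

    The first column is used as the sample id when its name is empty or
    ``sample``; otherwise row numbers are used.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"duplicate feature names: {dupes}")
    # round_trip parsing so written floats reload bit-identically
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    first = df.columns[0]
    if first.lower() in ("sample", "id", "") or first.startswith("Unnamed"):
        df = df.set_index(first)
        sample_ids = [str(s) for s in df.index]
    else:
        sample_ids = [str(i) for i in range(len(df))]
    if label_column not in df.columns:
        raise ValidationError(
            f"label column {label_column!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    labels = df[label_column]
    if labels.isna().any():
        raise ValidationError(f"missing values in label column {label_column!r}")
    feats = df.drop(columns=[label_column])
    names = list(feats.columns)
    if len(set(names)) != len(names):
        dupes = sorted({c for c in names if names.count(c) > 1})
        raise ValidationError(f"duplicate feature names: {dupes}")
    for col in names:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = numeric.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric value {feats[col].iloc[row]!r} in column {col!r}, "
                f"row {sample_ids[row]}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValidationError(f"missing value in column {col!r}, row {sample_ids[row]}")
        feats[col] = numeric
    return LabeledTable(features=feats.to_numpy(float), feature_names=names,
                        sample_ids=sample_ids, labels=labels.to_numpy())


def write_labeled_table(table: LabeledTable | pd.DataFrame, path,
                        label_column: str = "group", delimiter: str = ",") -> None:
    df = table.to_frame(label_column) if isinstance(table, LabeledTable) else table
    df.to_csv(path, sep=delimiter, index=isinstance(table, LabeledTable))


def _pca_to_dict(p: PCAModel | None):
    if p is None:
        return None
    return {
        "mu": p.mu.tolist(),
        "loadings": p.loadings.tolist(),  # row-major p x q
        "explained": p.explained.tolist(),
        "explained_full": p.explained_full.tolist(),
        "q": p.q,
        "scale": None if p.scale is None else p.scale.tolist(),
    }


def _pca_from_dict(d) -> PCAModel | None:
    if d is None:
        return None
    loadings = np.asarray(d["loadings"], dtype=float)
    if loadings.ndim != 2 or loadings.shape[1] != d["q"]:
        raise SchemaError(f"PCA loadings shape {loadings.shape} inconsistent with q={d['q']}")
    return PCAModel(
        mu=np.asarray(d["mu"], dtype=float),
        loadings=loadings,
        explained=np.asarray(d["explained"], dtype=float),
        explained_full=np.asarray(d["explained_full"], dtype=float),
        q=int(d["q"]),
        scale=None if d.get("scale") is None else np.asarray(d["scale"], dtype=float),
    )


def _binary_to_dict(res: LPDAResults) -> dict:
    return {
        "a": res.hyperplane.a.tolist(),
        "b": res.hyperplane.b,
        "p": res.hyperplane.p,
        "labels": list(res.labels),
        "objective": res.objective,
        "weights_policy": "per-group weights renormalised to sum 1",
        "pca": _pca_to_dict(res.pca),
    }


def _binary_from_dict(d: dict) -> LPDAResults:
    a = np.asarray(d["a"], dtype=float)
    if a.shape != (int(d["p"]),):
        raise SchemaError(f"coefficient vector length {a.size} does not match p={d['p']}")
    return LPDAResults(
        hyperplane=Hyperplane(a, float(d["b"])),
        labels=tuple(d["labels"]),
        pca=_pca_from_dict(d.get("pca")),
        objective=float(d["objective"]),
    )


def save_model(results: LPDAResults | PairwiseLPDAResults, path) -> None:
    """Serialise a fitted model (binary or pairwise) as versioned JSON."""
    if isinstance(results, LPDAResults):
        doc = {"schema_version": SCHEMA_VERSION, "kind": "binary",
               "model": _binary_to_dict(results)}
    elif isinstance(results, PairwiseLPDAResults):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "pairwise",
            "group_labels": list(results.group_labels),
            "models": [
                {"pair": [la, lb], "model": _binary_to_dict(res)}
                for (la, lb), res in results.models.items()
            ],
        }
    else:
        raise ValidationError(f"cannot serialise object of type {type(results).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> LPDAResults | PairwiseLPDAResults:
    """Reload a model saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path} is not valid JSON: {err}") from err
    found = doc.get("schema_version")
    if found != SCHEMA_VERSION:
        raise SchemaError(f"schema version mismatch: expected {SCHEMA_VERSION}, found {found}")
    try:
        if doc["kind"] == "binary":
            return _binary_from_dict(doc["model"])
        if doc["kind"] == "pairwise":
            models = {tuple(e["pair"]): _binary_from_dict(e["model"]) for e in doc["models"]}
            return PairwiseLPDAResults(group_labels=list(doc["group_labels"]),
                                       models=models, settings={})
        raise SchemaError(f"unknown model kind {doc.get('kind')!r}")
    except (KeyError, TypeError) as err:
        raise SchemaError(f"malformed model file {path}: missing field {err}") from err
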