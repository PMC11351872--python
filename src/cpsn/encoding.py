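"""Uniform one-hot encoding of mixed-type clinical variables.

Every variable — continuous, binary, categorical — is mapped to a block of
binary indicator features, one per state. Continuous variables are first
discretized into four quartile bins fitted on the observed (non-missing)
training values; a missing value activates the variable's dedicated ``NA``
feature rather than being imputed. With M variables whose i-th variable has
Ni states, a patient becomes a row of the n × ΣNi feature embedding matrix
with exactly one active feature per variable, so every row sums to M.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, PATIENT_ID_COLUMN
from .schema import MISSING_STATE, CohortSchema

_BIN_LABELS = ("Q1", "Q2", "Q3", "Q4")


class EncodingError(ValueError):
    pass


@dataclass
class EncodingModel:
    """Fitted encoder: quartile cut points plus the feature-name layout.

    ``bin_edges[var]`` holds the three interior quartile cut points
    (Q1, Q2, Q3) computed with linear interpolation between order
    statistics; ``observed_range[var]`` the training min/max (informational
    only — out-of-range values clamp into the outer bins).
    """

    schema: CohortSchema
    bin_edges: dict[str, tuple[float, float, float]]
    observed_range: dict[str, tuple[float, float]]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [
                f"{var.name}={state}" for var in self.schema for state in var.encoded_states
            ]

    @property
    def n_features(self) -> int:
        """Total one-hot feature count, ΣNi over the M variables."""
        return len(self.feature_names)

    def feature_blocks(self) -> dict[str, slice]:
        """Column slice of the feature matrix owned by each variable."""
        blocks, start = {}, 0
        for var in self.schema:
            k = var.n_encoded_states
            blocks[var.name] = slice(start, start + k)
            start += k
        return blocks

    def to_json(self, path=None) -> str:
        doc = {
            "schema_name": self.schema.name,
            "bin_edges": {k: list(v) for k, v in self.bin_edges.items()},
            "observed_range": {k: list(v) for k, v in self.observed_range.items()},
            "feature_names": self.feature_names,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source, schema: CohortSchema) -> "EncodingModel":
        p = Path(str(source))
        doc = json.loads(p.read_text(encoding="utf-8") if p.exists() else str(source))
        return cls(
            schema=schema,
            bin_edges={k: tuple(v) for k, v in doc["bin_edges"].items()},
            observed_range={k: tuple(v) for k, v in doc["observed_range"].items()},
            feature_names=list(doc["feature_names"]),
        )


@dataclass
class FeatureMatrix:
    """Binary patient-embedding matrix (n × ΣNi), one row per patient."""

    patient_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match ids/names")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.patient_ids, name=PATIENT_ID_COLUMN), columns=self.feature_names)

    def save(self, path_prefix) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` plus a ``<prefix>.meta.json`` sidecar."""
        prefix = Path(str(path_prefix))
        tsv = prefix.with_suffix(".tsv") if prefix.suffix != ".tsv" else prefix
        meta = tsv.with_suffix("").with_suffix(".meta.json")
        self.to_frame().to_csv(tsv, sep="\t")
        meta.write_text(json.dumps({"feature_names": self.feature_names}, indent=1), encoding="utf-8")
        return tsv, meta

    @classmethod
    def load(cls, tsv_path) -> "FeatureMatrix":
        df = pd.read_csv(tsv_path, sep="\t", index_col=PATIENT_ID_COLUMN)
        return cls(list(df.index.astype(str)), df.to_numpy(np.int8), list(df.columns))


def fit_encoder(table: CohortTable, schema: CohortSchema | None = None) -> EncodingModel:
    """Fit quartile cut points on the observed values of each continuous variable.

    Cut points are the 25th/50th/75th percentiles of the non-missing values
    (linear interpolation between order statistics). Categorical blocks are
    taken verbatim from the schema. Fitting requires at least four distinct
    observed values per continuous variable; heavy ties that collapse cut
    points are tolerated (empty bins are allowed at transform time).
    """
    schema = schema or table.schema
    if table.n == 0:
        raise EncodingError("cannot fit an encoder on an empty cohort")
    edges: dict[str, tuple[float, float, float]] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for var in schema:
        if var.kind != "continuous":
            continue
        vals = table.data[var.name].dropna().to_numpy(float)
        if len(np.unique(vals)) < 4:
            raise EncodingError(
                f"{var.name}: needs >= 4 distinct non-missing values to fit "
                f"quartile bins, got {len(np.unique(vals))}"
            )
        q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        edges[var.name] = (float(q1), float(q2), float(q3))
        ranges[var.name] = (float(vals.min()), float(vals.max()))
    return EncodingModel(schema=schema, bin_edges=edges, observed_range=ranges)


def discretize(value, edges: tuple[float, float, float]) -> str:
    """Quartile-bin label for one value: Q1 (≤Q1 cut) … Q4 (>Q3 cut).

    Bins are upper-inclusive: a value exactly equal to a cut point falls in
    the lower bin. Missing (None/NaN) maps to ``"NA"``; values outside the
    training range clamp into the outer bins.
    """
    if value is None:
        return MISSING_STATE
    v = float(value)
    if np.isnan(v):
        return MISSING_STATE
    if not np.isfinite(v):
        raise EncodingError(f"non-finite value {value!r}")
    return _BIN_LABELS[int(np.sum(v > np.asarray(edges, dtype=float)))]


def transform(model: EncodingModel, table: CohortTable, lenient: bool = False) -> FeatureMatrix:
    """Encode a cohort with an already-fitted model.

    Unseen categorical levels raise by default; with ``lenient=True`` they
    map to the variable's ``NA`` feature when the variable allows missing
    values (and still raise otherwise).
    """
    n = table.n
    X = np.zeros((n, model.n_features), dtype=np.int8)
    blocks = model.feature_blocks()
    for var in model.schema:
        block = blocks[var.name]
        states = list(var.encoded_states)
        col = table.data[var.name]
        if var.kind == "continuous":
            vals = col.to_numpy(float)
            na = np.isnan(vals)
            if na.any() and MISSING_STATE not in states:
                raise EncodingError(f"{var.name}: missing values but no NA feature")
            edges = np.asarray(model.bin_edges[var.name], dtype=float)
            idx = np.sum(vals[:, None] > edges[None, :], axis=1)
            if na.any():
                idx[na] = states.index(MISSING_STATE)
        else:
            labels = col.to_numpy(object)
            idx = np.empty(n, dtype=int)
            lookup = {s: i for i, s in enumerate(states)}
            for i, lab in enumerate(labels):
                if lab is np.nan or (isinstance(lab, float) and np.isnan(lab)):
                    lab = MISSING_STATE
                j = lookup.get(lab)
                if j is None:
                    if lenient and var.allow_missing:
                        warnings.warn(
                            f"{var.name}: unseen level {lab!r} mapped to NA", stacklevel=2
                        )
                        j = lookup[MISSING_STATE]
                    else:
                        raise EncodingError(
                            f"{var.name}: state {lab!r} is not part of the fitted model"
                        )
                idx[i] = j
        X[np.arange(n), block.start + idx] = 1
    return FeatureMatrix(table.patient_ids, X, list(model.feature_names))


def n_features(model: EncodingModel) -> int:
    """Total one-hot feature count ΣNi of a fitted model."""
    return model.n_features
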