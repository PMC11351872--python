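"""Cohort tables: validated per-patient clinical values plus survival records.

Tables live in pandas DataFrames indexed by patient id, with one column per
schema variable in schema order. Continuous columns are float (``NaN`` for
missing); categorical columns are strings (``NaN`` for missing / the ``NA``
state — the two are deliberately the same thing throughout this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import MISSING_STATE, CohortSchema

PATIENT_ID_COLUMN = "patient_id"


class CohortValidationError(ValueError):
    """A cohort table does not conform to its schema."""


@dataclass
class CohortTable:
    """Raw clinical values for a cohort, validated against a schema."""

    schema: CohortSchema
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate(self.data, self.schema)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, patient_ids) -> "CohortTable":
        return CohortTable(self.schema, self.data.loc[list(patient_ids)])

    def equals(self, other: "CohortTable") -> bool:
        """Value equality: same patients, same entries (NaN == NaN)."""
        if self.patient_ids != other.patient_ids:
            return False
        for var in self.schema:
            a, b = self.data[var.name], other.data[var.name]
            if var.kind == "continuous":
                if not np.allclose(a.to_numpy(float), b.to_numpy(float), equal_nan=True, rtol=0, atol=0):
                    return False
            elif not a.fillna(MISSING_STATE).equals(b.fillna(MISSING_STATE)):
                return False
        return True


def _validate(df: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CohortValidationError(f"duplicate patient id {dup!r}")
    missing_cols = [v.name for v in schema if v.name not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort is missing schema columns: {missing_cols}")
    df = df[list(schema.variable_names)].copy()
    for var in schema:
        col = df[var.name]
        if var.kind == "continuous":
            try:
                # numpy parsing is correctly rounded (exact round-trip with repr)
                vals = pd.Series(col.to_numpy(object).astype(float), index=col.index)
            except (ValueError, TypeError) as exc:
                raise CohortValidationError(f"{var.name}: non-numeric entry ({exc})") from None
            bad = np.isinf(vals.to_numpy(float))
            if bad.any():
                row = df.index[int(np.flatnonzero(bad)[0])]
                raise CohortValidationError(f"{var.name}: non-finite value at patient {row!r}")
            df[var.name] = vals
        else:
            col = col.astype(object).where(col.notna(), np.nan)
            # the literal NA state is stored as missing internally
            col = col.mask(col == MISSING_STATE, np.nan)
            observed = col.dropna()
            allowed = set(var.non_missing_states)
            bad = observed[~observed.isin(allowed)]
            if len(bad):
                row, val = bad.index[0], bad.iloc[0]
                raise CohortValidationError(
                    f"{var.name}: unknown state {val!r} at patient {row!r} "
                    f"(declared states: {sorted(allowed)})"
                )
            if not var.allow_missing and col.isna().any():
                row = col.index[int(np.flatnonzero(col.isna())[0])]
                raise CohortValidationError(
                    f"{var.name}: missing value at patient {row!r} but the "
                    "variable does not allow missing values"
                )
            df[var.name] = col
    return df


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_cohort(path, schema: CohortSchema, missing_marker: str = MISSING_STATE) -> CohortTable:
    """Read a delimited cohort table (TSV by default, CSV by extension).

    The file must have a ``patient_id`` column plus one column per schema
    variable. Entries equal to ``missing_marker`` become missing values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if PATIENT_ID_COLUMN not in df.columns:
        raise CohortValidationError(f"cohort file lacks a {PATIENT_ID_COLUMN!r} column")
    df = df.set_index(PATIENT_ID_COLUMN)
    df = df.mask(df == missing_marker, np.nan)
    return CohortTable(schema, df)


def save_cohort(table: CohortTable, path, missing_marker: str = MISSING_STATE) -> None:
    """Write a cohort table as delimited text; inverse of :func:`load_cohort`."""
    out = table.data.copy()
    for var in table.schema:
        col = out[var.name]
        if var.kind == "continuous":
            out[var.name] = col.map(lambda v: missing_marker if math.isnan(v) else repr(float(v)))
        else:
            out[var.name] = col.fillna(missing_marker)
    out.index.name = PATIENT_ID_COLUMN
    out.to_csv(path, sep=_sep_for(path))


def summarize_cohort(table: CohortTable, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Baseline-characteristics summary in long form.

    Continuous variables report median/min/max over observed values;
    binary/categorical variables report per-state patient counts, with an
    ``NA`` row counting unobserved patients whenever the variable allows
    missing values or any are observed missing. State counts per variable
    always sum to the cohort size.
    """
    schema = schema or table.schema
    rows = []
    for var in schema:
        col = table.data[var.name]
        if var.kind == "continuous":
            obs = col.dropna()
            rows.append((var.name, var.kind, "median", float(obs.median()) if len(obs) else np.nan))
            rows.append((var.name, var.kind, "min", float(obs.min()) if len(obs) else np.nan))
            rows.append((var.name, var.kind, "max", float(obs.max()) if len(obs) else np.nan))
            n_na = int(col.isna().sum())
            if var.allow_missing or n_na:
                rows.append((var.name, var.kind, "n_missing", n_na))
        else:
            for state in var.non_missing_states:
                rows.append((var.name, var.kind, state, int((col == state).sum())))
            n_na = int(col.isna().sum())
            if var.allow_missing or n_na:
                rows.append((var.name, var.kind, MISSING_STATE, n_na))
    return pd.DataFrame(rows, columns=["variable", "kind", "statistic", "value"])


def state_counts(summary: pd.DataFrame, variable: str) -> dict[str, int]:
    """Per-state counts for one categorical variable of a summary table."""
    sub = summary[(summary["variable"] == variable) & (summary["kind"] != "continuous")]
    return {str(r.statistic): int(r.value) for r in sub.itertuples()}


# ---------------------------------------------------------------------------
# Survival records
# ---------------------------------------------------------------------------

def load_survival(path) -> pd.DataFrame:
    """Read survival records: columns ``patient_id``, ``time``, ``event``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_survival(df)


def save_survival(survival: pd.DataFrame, path) -> None:
    validate_survival(survival).to_csv(path, sep=_sep_for(path), index=False)


def validate_survival(df: pd.DataFrame, cohort: CohortTable | None = None) -> pd.DataFrame:
    required = [PATIENT_ID_COLUMN, "time", "event"]
    for col in required:
        if col not in df.columns:
            raise CohortValidationError(f"survival table lacks column {col!r}")
    df = df[required].copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] < 0).any():
        raise CohortValidationError("survival times must be nonnegative")
    if not df["event"].isin([0, 1]).all():
        raise CohortValidationError("event indicator must be 0 (censored) or 1 (death)")
    if df[PATIENT_ID_COLUMN].duplicated().any():
        raise CohortValidationError("duplicate patient id in survival table")
    if cohort is not None:
        unknown = set(df[PATIENT_ID_COLUMN]) - set(cohort.patient_ids)
        if unknown:
            raise CohortValidationError(f"survival records for unknown patients: {sorted(unknown)[:5]}")
    return df
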