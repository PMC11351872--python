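"""Declarative schemas for mixed-type clinical cohorts.

A cohort is described by an ordered list of :class:`VariableSpec` entries,
one per clinical variable. Three kinds are supported:

``continuous``
    A numeric measurement (age, tumour-marker level, ...). Downstream
    encoding discretizes it into four quartile bins, plus a dedicated
    missing-value state when ``allow_missing`` is set.
``binary``
    Exactly two substantive states (e.g. ``Yes``/``No``), optionally with a
    literal ``"NA"`` state when the variable may be unobserved.
``categorical``
    Three or more substantive states, again optionally with ``"NA"``.

Missing values are never imputed anywhere in this package: a missing entry
is a first-class state of its variable, so an incompletely observed patient
is still a complete point in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import yaml

MISSING_STATE = "NA"

_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class VariableSpec:
    """One clinical variable: its kind and admissible states.

    Parameters
    ----------
    name
        Unique identifier, used as the column name in cohort tables.
    kind
        One of ``continuous``, ``binary``, ``categorical``.
    states
        Ordered state labels for binary/categorical variables. Includes the
        literal ``"NA"`` state when the variable may be unobserved. Must be
        empty for continuous variables (their states are fitted quartile
        bins, not declared ones).
    allow_missing
        Whether the variable may be unobserved. For binary/categorical
        variables this must agree with the presence of the ``"NA"`` state.
    units
        Optional free-text units for continuous variables.
    """

    name: str
    kind: str
    states: tuple[str, ...] = ()
    allow_missing: bool = False
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"{self.name}: unknown variable kind {self.kind!r}")
        object.__setattr__(self, "states", tuple(self.states))
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels")
        if self.kind == "continuous":
            if self.states:
                raise ValueError(
                    f"{self.name}: continuous variables declare no states "
                    "(bins are fitted by the encoder)"
                )
        else:
            n_sub = len(self.non_missing_states)
            if self.kind == "binary" and n_sub != 2:
                raise ValueError(
                    f"{self.name}: binary variables need exactly 2 non-missing "
                    f"states, got {n_sub}"
                )
            if self.kind == "categorical" and n_sub < 2:
                raise ValueError(f"{self.name}: needs at least 2 non-missing states")
            if self.allow_missing != (MISSING_STATE in self.states):
                raise ValueError(
                    f"{self.name}: allow_missing must agree with the presence "
                    f"of the {MISSING_STATE!r} state"
                )

    @property
    def non_missing_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != MISSING_STATE)

    @property
    def encoded_states(self) -> tuple[str, ...]:
        """States this variable contributes after one-hot encoding.

        Continuous variables contribute the four quartile bins (plus ``NA``
        when missing is allowed); binary/categorical variables contribute
        their declared states verbatim.
        """
        if self.kind == "continuous":
            bins = ("Q1", "Q2", "Q3", "Q4")
            return bins + (MISSING_STATE,) if self.allow_missing else bins
        return self.states

    @property
    def n_encoded_states(self) -> int:
        return len(self.encoded_states)


def continuous(name: str, units: str | None = None, allow_missing: bool = True) -> VariableSpec:
    return VariableSpec(name, "continuous", (), allow_missing, units)


def binary(name: str, states: tuple[str, str] = ("Yes", "No"), allow_missing: bool = False) -> VariableSpec:
    sts = tuple(states) + ((MISSING_STATE,) if allow_missing else ())
    return VariableSpec(name, "binary", sts, allow_missing)


def categorical(name: str, states: tuple[str, ...], allow_missing: bool = False) -> VariableSpec:
    sts = tuple(s for s in states if s != MISSING_STATE)
    sts = sts + ((MISSING_STATE,) if allow_missing else ())
    return VariableSpec(name, "categorical", sts, allow_missing)


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of variables describing one cohort table.

    The variable order is stable and defines column order in every
    downstream artifact (tables, feature matrices, profiles).
    """

    variables: tuple[VariableSpec, ...]
    name: str = "cohort"
    version: str = "1"
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        object.__setattr__(self, "_by_name", {v.name: v for v in self.variables})

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def M(self) -> int:
        """Number of variables (observation indices)."""
        return len(self.variables)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def total_encoded_states(self) -> int:
        """Sum of per-variable encoded state counts (the one-hot width)."""
        return sum(v.n_encoded_states for v in self.variables)

    # ---- serialization -------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {
            "name": self.name,
            "version": self.version,
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    **({"states": list(v.states)} if v.states else {}),
                    "allow_missing": v.allow_missing,
                    **({"units": v.units} if v.units else {}),
                }
                for v in self.variables
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CohortSchema":
        """Load a schema from a YAML string or file path."""
        import os

        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        variables = tuple(
            VariableSpec(
                name=v["name"],
                kind=v["kind"],
                states=tuple(v.get("states", ())),
                allow_missing=v.get("allow_missing", False),
                units=v.get("units"),
            )
            for v in doc["variables"]
        )
        return cls(variables, name=doc.get("name", "cohort"), version=str(doc.get("version", "1")))


# ---------------------------------------------------------------------------
# Built-in gastric-cancer schema
# ---------------------------------------------------------------------------

#: Baseline marginal summaries of the reference surgical gastric-cancer
#: cohort (n = 1000): continuous variables as (median, min, max).
GC_CONTINUOUS_SUMMARY: dict[str, tuple[float, float, float]] = {
    "age": (64, 24, 93),
    "BMI": (23.1, 14.2, 54.1),
    "lymphocyte_count": (1.41, 0.12, 3.81),
    "leukocyte_count": (6.4, 2.66, 27.58),
    "AFP": (2.46, 0.74, 136.41),
    "CA724": (2.2, 0.37, 300),
    "CA125": (10.7, 2.7, 391.4),
    "CA153": (7, 2.7, 20.2),
    "CEA": (2.3, 0.5, 1500),
    "Ki67_expression": (0.6, 0.01, 0.9),
    "Topo_expression": (0.4, 0.01, 0.9),
    "max_diameter": (3, 0.8, 18),
}

#: Per-state patient counts for the categorical/binary variables of the
#: reference cohort (n = 1000). ``"NA"`` rows count unobserved patients.
GC_STATE_COUNTS: dict[str, dict[str, int]] = {
    "operater_codeEMR": {
        "Laparotomy": 585,
        "Laparoscope": 283,
        "Laparoscopic_exploratory_surgery": 120,
        "NA": 12,
    },
    "Complications": {"Yes": 288, "No": 712},
    "Tumor_location": {"Lower": 408, "Middle": 222, "Upper": 360, "Residual": 10},
    "pT": {"Tis/T1": 309, "T2": 112, "T3": 394, "T4a": 172, "T4b": 13},
    "pN": {"N0": 447, "N1": 162, "N2": 157, "N3a": 149, "N3b": 85},
    "M": {"M0": 299, "M1": 6, "Mx": 134, "NA": 561},
    "AJCC_Stage": {"Stage 0/stage I": 338, "Stage II": 278, "Stage III": 378, "Stage IV": 6},
    "Sample_type": {"Proximal": 68, "Total": 409, "Distal": 508, "Residual": 15},
    "Differentiation": {"High": 26, "Middle": 367, "Poorly": 365, "Middle_poorly": 233, "High_middle": 9},
    "Lauren": {"Intestinal type": 128, "Diffuse type": 124, "Mixed": 76, "NA": 672},
    "Nerve_invasion": {"Yes": 433, "No": 567},
    "Tumor_thrombus": {"Yes": 353, "No": 647},
    "Cancerous_node": {"Yes": 138, "No": 862},
    "Positive_margin": {"Yes": 138, "No": 862},
    "Surgical_complications": {"Yes": 31, "No": 969},
    "Omental_involvement": {"Yes": 7, "No": 295, "NA": 698},
    "TRG": {"1 grade": 1, "2 grade": 4, "3 grade": 5, "NA": 990},
    "MLH1_IHC": {"(-)": 20, "(+)": 363, "NA": 617},
    "MSH2_IHC": {"(-)": 13, "(+)": 357, "Little (+)": 12, "NA": 618},
    "MSH6_IHC": {"(-)": 6, "(+)": 320, "Little (+)": 48, "NA": 626},
    "PMS2_IHC": {"(-)": 19, "(+)": 363, "NA": 618},
    "dMMR": {"Yes": 38, "No": 332, "NA": 630},
    "EGFR-IHC": {"(-)": 586, "(+)": 406, "(±)": 8},
    "ERBB2-IHC": {"(-)": 663, "(+)": 337},
    "p53-IHC": {"(-)": 183, "(+)": 185, "NA": 632},
}

#: Which of the categorical/binary variables are binary (two substantive states).
_GC_BINARY = {
    "Complications",
    "Nerve_invasion",
    "Tumor_thrombus",
    "Cancerous_node",
    "Positive_margin",
    "Surgical_complications",
    "Omental_involvement",
    "dMMR",
}

GC_COHORT_SIZE = 1000


def builtin_gc_schema() -> CohortSchema:
    """The built-in surgical gastric-cancer baseline schema.

    Thirty-seven variables: 12 continuous (demographics, blood counts,
    serum tumour markers, expression fractions, tumour size) and 25
    binary/categorical (surgical narrative, histopathology, TNM staging,
    immunohistochemistry). Categorical state lists carry a literal ``"NA"``
    state wherever the reference cohort had unobserved patients; all
    continuous variables allow missing values, so each contributes four
    quartile bins plus one missing state after encoding.
    """
    variables: list[VariableSpec] = []
    units = {
        "age": "years",
        "BMI": "kg/m^2",
        "lymphocyte_count": "10^9/L",
        "leukocyte_count": "10^9/L",
        "AFP": "ng/mL",
        "CA724": "U/mL",
        "CA125": "U/mL",
        "CA153": "U/mL",
        "CEA": "ng/mL",
        "max_diameter": "cm",
    }
    for name in GC_CONTINUOUS_SUMMARY:
        variables.append(continuous(name, units=units.get(name), allow_missing=True))
    for name, counts in GC_STATE_COUNTS.items():
        states = tuple(counts)
        allow_missing = MISSING_STATE in counts
        if name in _GC_BINARY:
            sub = tuple(s for s in states if s != MISSING_STATE)
            variables.append(binary(name, sub, allow_missing=allow_missing))
        else:
            variables.append(categorical(name, states, allow_missing=allow_missing))
    return CohortSchema(tuple(variables), name="gastric_cancer_baseline", version="1")
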