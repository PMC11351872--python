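"""Clinical validation of a patient subgrouping.

A similarity network is only clinically meaningful when its subgroups
separate a clinical endpoint. This module provides the assessment battery:
per-group Kaplan–Meier survival curves, the k-sample log-rank test (a
network whose clusters differ at p < 0.05 earns the "clinical" prefix),
Pearson chi-square association between a grouping and categorical markers
(significance called at p < 0.01), and per-cluster clinical-feature
frequency profiles.

The survival estimators are implemented from the standard product-limit
and observed-minus-expected formulas so they can be checked against
hand-computed tables and permutation oracles; the chi-square test delegates
to scipy. No multiple-testing correction is applied: raw p-values are
reported against the fixed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, PATIENT_ID_COLUMN
from .encoding import EncodingModel, fit_encoder, discretize
from .schema import MISSING_STATE, CohortSchema

SURVIVAL_ALPHA = 0.05   # log-rank threshold for calling the network clinical
MARKER_ALPHA = 0.01     # chi-square threshold for marker associations


@dataclass
class KMCurve:
    """Product-limit survival estimate for one patient group."""

    group: str
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n_events: np.ndarray       # deaths at each event time
    censor_times: np.ndarray   # censoring times (for tick marks)
    n: int = 0

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    table: pd.DataFrame | None = None
    expected: np.ndarray | None = None
    low_expected_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "low_expected_warning": bool(self.low_expected_warning),
        }


@dataclass
class ValidationReport:
    km_curves: list[KMCurve]
    logrank: TestResult
    is_clinical: bool
    marker_tests: dict[str, TestResult]
    profiles: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "logrank": self.logrank.to_dict(),
            "is_clinical": self.is_clinical,
            "marker_tests": {m: t.to_dict() for m, t in self.marker_tests.items()},
        }


def _as_arrays(times, events, groups):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (len(t) == len(e) == len(g)):
        raise ValueError("times, events and group labels must be aligned")
    if (t < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    return t, e, g


def km_estimate(times, events, group_labels=None) -> list[KMCurve]:
    """Kaplan–Meier product-limit curves, one per group.

    At tied times deaths are processed before censorings: a patient
    censored at t is still at risk for the deaths at t.
    """
    if group_labels is None:
        group_labels = ["all"] * len(times)
    t, e, g = _as_arrays(times, events, group_labels)
    curves = []
    for grp in pd.unique(g):
        mask = g == grp
        if not mask.any():
            raise ValueError(f"empty group {grp!r}")
        tt, ee = t[mask], e[mask]
        order = np.argsort(tt, kind="stable")
        tt, ee = tt[order], ee[order]
        event_times = np.unique(tt[ee == 1])
        n_at_risk = np.array([(tt >= u).sum() for u in event_times])
        n_deaths = np.array([((tt == u) & (ee == 1)).sum() for u in event_times])
        surv = np.cumprod(1.0 - n_deaths / n_at_risk) if len(event_times) else np.array([])
        curves.append(
            KMCurve(
                group=str(grp),
                times=event_times,
                survival=surv,
                at_risk=n_at_risk,
                n_events=n_deaths,
                censor_times=np.sort(tt[ee == 0]),
                n=int(mask.sum()),
            )
        )
    return curves


def logrank_test(times, events, group_labels) -> TestResult:
    """K-sample log-rank test of equal survival distributions.

    At each distinct event time the observed deaths per group are compared
    with those expected under the null (deaths allocated proportionally to
    the numbers at risk), accumulating the hypergeometric covariance. The
    quadratic form of the observed-minus-expected vector (one group dropped)
    against that covariance is chi-square with k−1 degrees of freedom.
    """
    t, e, g = _as_arrays(times, events, group_labels)
    groups = list(pd.unique(g))
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if e.sum() == 0:
        raise ValueError("log-rank test undefined: no events observed in any group")
    gidx = np.array([groups.index(x) for x in g])

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        n_j = at_risk.sum()
        d_j = ((t == u) & (e == 1)).sum()
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[(t == u) & (e == 1)], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            hyper = d_j * (n_j - d_j) / (n_j - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vr, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vr) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p, method="logrank")


def chisq_association(labels_a, labels_b, drop_na: bool = False) -> TestResult:
    """Pearson chi-square association between two categorical label vectors.

    Missing values are retained as an ``NA`` category by default, consistent
    with the encoding philosophy; ``drop_na=True`` removes pairs with a
    missing entry on either side. A flag is raised when any expected cell
    count falls below 5.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("label vectors must be aligned")
    if drop_na:
        keep = a.notna() & b.notna()
        a, b = a[keep], b[keep]
    else:
        a = a.fillna(MISSING_STATE)
        b = b.fillna(MISSING_STATE)
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table of shape {table.shape}; "
            "association is undefined with a single row or column"
        )
    stat, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return TestResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        method="chi-square",
        table=table,
        expected=expected,
        low_expected_warning=bool((expected < 5).any()),
    )


def cluster_profiles(
    table: CohortTable,
    schema: CohortSchema | None = None,
    assignments=None,
    encoder: EncodingModel | None = None,
) -> pd.DataFrame:
    """Within-cluster state frequencies for every variable (heatmap input).

    Continuous variables are profiled through their fitted quartile bins
    (plus ``NA``); categorical variables through their declared states.
    Frequencies for one variable sum to 1 within each cluster.
    """
    schema = schema or table.schema
    if assignments is None:
        assignments = ["all"] * table.n
    labels = pd.Series(np.asarray(assignments), index=table.data.index)
    if encoder is None:
        encoder = fit_encoder(table, schema)
    rows = []
    for var in schema:
        col = table.data[var.name]
        if var.kind == "continuous":
            edges = encoder.bin_edges[var.name]
            states = col.map(lambda v: discretize(v, edges))
        else:
            states = col.fillna(MISSING_STATE)
        for cluster, idx in labels.groupby(labels).groups.items():
            sub = states.loc[idx]
            freqs = sub.value_counts(normalize=True)
            for state in var.encoded_states:
                rows.append((str(cluster), var.name, state, float(freqs.get(state, 0.0))))
    return pd.DataFrame(rows, columns=["cluster", "variable", "state", "frequency"])


def conventional_groupings(table: CohortTable) -> dict[str, pd.Series]:
    """Conventional patient stratifications used as comparators.

    Age quartile groups (cohort quartiles of observed ages), tumour
    differentiation, and composite stage — the classifications a clinician
    would reach for before any similarity modelling.
    """
    out: dict[str, pd.Series] = {}
    schema = table.schema
    if "age" in schema:
        age = table.data["age"]
        obs = age.dropna()
        q1, q2, q3 = np.quantile(obs.to_numpy(float), [0.25, 0.5, 0.75])
        out["age_quartile"] = age.map(
            lambda v: MISSING_STATE if np.isnan(v) else discretize(v, (q1, q2, q3))
        )
    for var in ("Differentiation", "AJCC_Stage"):
        if var in schema:
            out[var] = table.data[var].fillna(MISSING_STATE)
    return out


def validate_clustering(
    table: CohortTable,
    schema: CohortSchema | None,
    assignments,
    survival: pd.DataFrame,
    markers: list[str] = (),
    encoder: EncodingModel | None = None,
    drop_na_markers: bool = False,
) -> ValidationReport:
    """Full clinical-validity assessment of a clustering.

    Assembles per-cluster Kaplan–Meier curves, the k-sample log-rank test
    (the network is flagged clinical when p < 0.05), chi-square association
    between clusters and each requested marker variable, and per-cluster
    feature-frequency profiles.
    """
    schema = schema or table.schema
    labels = pd.Series(np.asarray(assignments), index=table.data.index)
    surv = survival.set_index(PATIENT_ID_COLUMN).loc[table.patient_ids]
    times = surv["time"].to_numpy(float)
    events = surv["event"].to_numpy(int)
    glabels = labels.to_numpy()

    curves = km_estimate(times, events, glabels)
    lr = logrank_test(times, events, glabels)
    marker_tests = {}
    for marker in markers:
        if marker not in schema:
            raise KeyError(f"marker {marker!r} is not a schema variable")
        marker_tests[marker] = chisq_association(
            glabels, table.data[marker], drop_na=drop_na_markers
        )
    profiles = cluster_profiles(table, schema, glabels, encoder=encoder)
    return ValidationReport(
        km_curves=curves,
        logrank=lr,
        is_clinical=bool(lr.p_value < SURVIVAL_ALPHA),
        marker_tests=marker_tests,
        profiles=profiles,
    )
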