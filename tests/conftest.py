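"""Shared fixtures: small schemas and session-scoped simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from cpsn import (
    CohortTable,
    binary,
    categorical,
    continuous,
    CohortSchema,
    default_gc_config,
    fit_encoder,
    kmeans_scan,
    simulate_cohort,
    transform,
)


@pytest.fixture(scope="session")
def gc_schema():
    from cpsn import builtin_gc_schema

    return builtin_gc_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """Two categorical variables plus one continuous, with mixed missingness."""
    return CohortSchema(
        (
            binary("node_positive", ("Yes", "No")),
            categorical("histology", ("intestinal", "diffuse", "mixed"), allow_missing=True),
            continuous("marker", units="ng/mL", allow_missing=True),
        ),
        name="toy",
    )


@pytest.fixture()
def toy_cohort(toy_schema):
    data = pd.DataFrame(
        {
            "node_positive": ["Yes", "No", "No", "Yes", "No", "Yes", "No", "No"],
            "histology": ["intestinal", "diffuse", np.nan, "mixed", "diffuse", np.nan, "intestinal", "mixed"],
            "marker": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        },
        index=pd.Index([f"P{i}" for i in range(1, 9)], name="patient_id"),
    )
    return CohortTable(toy_schema, data)


@pytest.fixture(scope="session")
def small_sim():
    """Mid-sized planted-cluster cohort shared across read-only tests."""
    return simulate_cohort(default_gc_config(n=300, seed=7))


@pytest.fixture(scope="session")
def default_sim():
    """The default study-scale synthetic cohort: n=1000, 5 planted clusters."""
    return simulate_cohort(default_gc_config(n=1000, seed=0))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Encoded features + K scan of the default cohort (computed once)."""
    model = fit_encoder(default_sim.cohort)
    X = transform(model, default_sim.cohort)
    scan = kmeans_scan(X, k_values=range(2, 11), seed=0)
    return {"sim": default_sim, "model": model, "X": X, "scan": scan}
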