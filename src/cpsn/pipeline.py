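"""One-command orchestration: cohort → encoding → network → subgroups → report.

Runs the full analysis on either a loaded cohort or a freshly simulated
one, writes every intermediate artifact to the output directory, and
records a manifest with per-file checksums so a rerun with the same
configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, load_cohort, load_survival, validate_survival
from .clustering import elbow_select, gap_statistic, kmeans_scan
from .encoding import fit_encoder, transform
from .psn import pairwise_distances, tsne_embed
from .schema import CohortSchema
from .simulate import CohortSimConfig, default_gc_config, simulate_cohort
from .validation import validate_clustering

log = logging.getLogger("cpsn")

DEFAULT_MARKERS = ("dMMR", "EGFR-IHC", "ERBB2-IHC", "p53-IHC")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` (with ``survival_path`` and ``schema``)
    or ``sim_config`` must be provided.
    """

    outdir: str
    sim_config: CohortSimConfig | None = None
    cohort_path: str | None = None
    survival_path: str | None = None
    schema: CohortSchema | None = None
    k_values: tuple[int, ...] = tuple(range(2, 11))
    select: str = "elbow"              # "elbow" | "gap"
    gap_B: int = 10
    markers: tuple[str, ...] = ()
    lenient: bool = False
    embed: bool = True
    embed_dims: int = 3
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim_config is None) == (self.cohort_path is None):
            raise ValueError("provide exactly one of sim_config or cohort_path")
        if self.cohort_path is not None and (self.survival_path is None or self.schema is None):
            raise ValueError("cohort_path requires survival_path and schema")
        if self.select not in ("elbow", "gap"):
            raise ValueError("select must be 'elbow' or 'gap'")


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    files: dict[str, dict] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    timing_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "seed": self.seed,
                    "files": self.files,
                    "results": self.results,
                    "timing_s": self.timing_s,
                },
                indent=1,
                default=str,
            ),
            encoding="utf-8",
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and write all artifacts plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in vars(config).items() if k not in ("sim_config", "schema")},
        version=__version__,
        seed=config.seed,
    )

    def record(name: str, path: Path) -> None:
        manifest.files[name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest.timing_s[name] = round(time.perf_counter() - t0, 3)

        return done

    # --- input stage ----------------------------------------------------
    done = stage("input")
    if config.sim_config is not None:
        sim = simulate_cohort(config.sim_config.with_(seed=config.seed))
        for name, p in sim.save(outdir).items():
            record(name, Path(p))
        cohort, survival = sim.cohort, sim.survival
    else:
        cohort = load_cohort(config.cohort_path, config.schema)
        survival = validate_survival(load_survival(config.survival_path), cohort)
    schema = cohort.schema
    log.info("cohort: n=%d patients, M=%d variables", cohort.n, schema.M)
    done()

    # --- encoding -------------------------------------------------------
    done = stage("encode")
    model = fit_encoder(cohort, schema)
    X = transform(model, cohort, lenient=config.lenient)
    tsv, meta = X.save(outdir / "features.tsv")
    model.to_json(outdir / "encoder.json")
    record("features", tsv)
    record("features_meta", meta)
    record("encoder", outdir / "encoder.json")
    log.info("encoded %d one-hot features (sum of per-variable states)", model.n_features)
    done()

    # --- distances ------------------------------------------------------
    done = stage("distances")
    dm = pairwise_distances(X)
    dm.save(outdir / "distances.tsv")
    record("distances", outdir / "distances.tsv")
    done()

    # --- clustering -----------------------------------------------------
    done = stage("cluster")
    scan = kmeans_scan(X, k_values=config.k_values, seed=config.seed)
    if config.select == "elbow":
        selection = elbow_select(scan)
    else:
        selection = gap_statistic(X, k_values=config.k_values, B=config.gap_B, seed=config.seed)
    chosen_k = selection.chosen_k
    names = scan.cluster_names(chosen_k)
    (outdir / "kscan.json").write_text(
        json.dumps(
            {
                "k_values": scan.k_values,
                "inertia": {str(k): scan.inertia[k] for k in scan.k_values},
                "selection": {"method": selection.method, "chosen_k": chosen_k,
                              "diagnostics": selection.diagnostics},
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    record("kscan", outdir / "kscan.json")
    assignments = pd.DataFrame({"patient_id": X.patient_ids, "cluster": names})
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    record("assignments", outdir / "assignments.tsv")
    log.info("chosen K=%d by %s", chosen_k, selection.method)
    done()

    # --- validation -----------------------------------------------------
    done = stage("validate")
    report = validate_clustering(
        cohort, schema, names, survival, markers=list(config.markers), encoder=model
    )
    (outdir / "validation.json").write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
    record("validation", outdir / "validation.json")
    report.profiles.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    record("profiles", outdir / "profiles.tsv")
    km = pd.concat([c.to_frame() for c in report.km_curves], ignore_index=True)
    km.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    record("km_curves", outdir / "km_curves.tsv")
    log.info(
        "log-rank p=%.3g -> %s", report.logrank.p_value,
        "clinical PSN" if report.is_clinical else "no clinical signal",
    )
    done()

    # --- embedding ------------------------------------------------------
    if config.embed:
        done = stage("embed")
        coords = tsne_embed(X, dims=config.embed_dims, seed=config.seed, perplexity=config.perplexity)
        coords = coords.assign(cluster=names)
        coords.to_csv(outdir / "embedding.tsv", sep="\t")
        record("embedding", outdir / "embedding.tsv")
        done()

    manifest.results = {
        "n": cohort.n,
        "M": schema.M,
        "n_features": model.n_features,
        "chosen_k": chosen_k,
        "selection_method": selection.method,
        "logrank_p": report.logrank.p_value,
        "is_clinical": report.is_clinical,
        "marker_p": {m: t.p_value for m, t in report.marker_tests.items()},
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest
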