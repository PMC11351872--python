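"""Figure helpers: KM curves, elbow/gap diagnostics, embedding scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterSelection, KScanResult
from .validation import KMCurve, TestResult


def plot_km(curves: list[KMCurve], logrank: TestResult | None = None, path=None):
    """Step-function survival curves per group with censoring ticks."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in curves:
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{curve.group} (n={curve.n})")
        if len(curve.censor_times):
            ax.plot(
                curve.censor_times,
                [curve.survival_at(ct) for ct in curve.censor_times],
                "|", color=ax.lines[-1].get_color(), markersize=6,
            )
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival probability")
    ax.set_ylim(0, 1.02)
    if logrank is not None:
        p = logrank.p_value
        ax.set_title(f"log-rank p {'< 0.0001' if p < 1e-4 else f'= {p:.3g}'}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_kscan(scan: KScanResult, selection: ClusterSelection | None = None, path=None):
    """Inertia-vs-K elbow curve (or gap curve with error bars)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if selection is not None and selection.method == "gap":
        d = selection.diagnostics
        ax.errorbar(d["k_values"], d["gap"], yerr=d["s_k"], marker="o")
        ax.set_ylabel("Gap(K)")
    else:
        ks = scan.k_values
        ax.plot(ks, [scan.inertia[k] for k in ks], marker="o")
        ax.set_ylabel("within-cluster sum of squares")
    if selection is not None:
        ax.axvline(selection.chosen_k, ls="--", color="grey")
        ax.set_title(f"chosen K = {selection.chosen_k} ({selection.method})")
    ax.set_xlabel("number of clusters K")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_embedding(coords: pd.DataFrame, path=None):
    """2D/3D scatter of the t-SNE view, coloured by cluster."""
    dims = [c for c in ("x", "y", "z") if c in coords.columns]
    fig = plt.figure(figsize=(5.5, 5))
    ax = fig.add_subplot(projection="3d" if len(dims) == 3 else None)
    groups = coords.groupby("cluster") if "cluster" in coords.columns else [("all", coords)]
    for name, sub in groups:
        ax.scatter(*[sub[d] for d in dims], s=6, label=str(name), alpha=0.7)
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
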