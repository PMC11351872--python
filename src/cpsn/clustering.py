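"""K-means subgrouping with unsupervised selection of the cluster number.

The number of subgroups K is treated as a hyperparameter scanned over a
range (2..10 by default). Two selectors are provided:

* the elbow method — the K maximizing the discrete second difference of
  the within-cluster sum of squares (inertia) curve, i.e. the point of
  maximal curvature;
* the gap statistic — comparing log inertia against B structureless
  reference datasets that preserve each variable's one-hot marginal but
  destroy co-occurrence across variables.

K-means runs ordinary Euclidean Lloyd updates on the 0/1 feature matrix
(centroids are per-state frequency vectors), k-means++ initialization,
best of ``n_init`` restarts. Reported labels are renumbered by descending
cluster size (ties by first patient index) so they are stable across
restart order; subgroup names "Cluster_1", "Cluster_2", ... follow that
numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .encoding import FeatureMatrix


@dataclass
class KScanResult:
    k_values: list[int]
    inertia: dict[int, float]
    assignments: dict[int, np.ndarray]
    seed: int
    n_init: int
    patient_ids: list[str] = field(default_factory=list)

    def labels(self, k: int) -> np.ndarray:
        return self.assignments[k]

    def cluster_names(self, k: int) -> list[str]:
        """Per-patient subgroup names ('Cluster_1' is the largest)."""
        return [f"Cluster_{lab + 1}" for lab in self.assignments[k]]


@dataclass
class ClusterSelection:
    method: str
    chosen_k: int
    diagnostics: dict


def _stable_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels by descending cluster size, ties by first occurrence."""
    uniq, counts = np.unique(labels, return_counts=True)
    first = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first[u]))
    mapping = {u: i for i, u in enumerate(order)}
    return np.array([mapping[u] for u in labels], dtype=int)


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_init: int) -> tuple[np.ndarray, float]:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return _stable_relabel(labels), float(km.inertia_)


def kmeans_scan(
    X: FeatureMatrix,
    k_values=range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> KScanResult:
    """Run K-means for every K in the scan range on the feature matrix."""
    k_values = sorted(int(k) for k in k_values)
    if X.n == 0:
        raise ValueError("empty feature matrix")
    if max(k_values) >= X.n:
        raise ValueError(f"max K ({max(k_values)}) must be < number of patients ({X.n})")
    data = X.matrix.astype(float)
    ss = np.random.SeedSequence(seed)
    child_seeds = {k: int(s.generate_state(1)[0] % (2**31)) for k, s in zip(k_values, ss.spawn(len(k_values)))}
    inertia, assignments = {}, {}
    for k in k_values:
        labels, w = _fit_kmeans(data, k, child_seeds[k], n_init)
        inertia[k] = w
        assignments[k] = labels
    return KScanResult(k_values, inertia, assignments, seed, n_init, list(X.patient_ids))


def elbow_select(scan: KScanResult) -> ClusterSelection:
    """Pick K at the elbow: maximal second difference of the inertia curve.

    For interior K the curvature is inertia(K−1) − 2·inertia(K) + inertia(K+1);
    a flat or perfectly linear curve has no elbow, which triggers a warning
    and falls back to the smallest scanned K.
    """
    ks = scan.k_values
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 scanned K values")
    w = np.array([scan.inertia[k] for k in ks])
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]
    interior = ks[1:-1]
    if np.allclose(curvature, 0):
        warnings.warn("inertia curve has no elbow (zero curvature); returning smallest K", stacklevel=2)
        chosen = ks[0]
    else:
        chosen = interior[int(np.argmax(curvature))]
    return ClusterSelection(
        method="elbow",
        chosen_k=int(chosen),
        diagnostics={
            "k_values": list(ks),
            "inertia": [float(x) for x in w],
            "interior_k": list(interior),
            "second_difference": [float(x) for x in curvature],
        },
    )


def _resample_marginals(X: np.ndarray, blocks: list[slice], rng: np.random.Generator) -> np.ndarray:
    """Structureless reference: per variable, redraw each patient's one-hot
    state independently from that variable's empirical state frequencies."""
    n = X.shape[0]
    ref = np.zeros_like(X)
    for block in blocks:
        probs = X[:, block].mean(axis=0)
        total = probs.sum()
        if total <= 0:
            continue
        states = rng.choice(block.stop - block.start, size=n, p=probs / total)
        ref[np.arange(n), block.start + states] = 1
    return ref


def _infer_blocks(feature_names: list[str]) -> list[slice]:
    blocks, start = [], 0
    prev = None
    for i, name in enumerate(feature_names):
        var = name.rsplit("=", 1)[0]
        if var != prev:
            if prev is not None:
                blocks.append(slice(start, i))
            start, prev = i, var
    blocks.append(slice(start, len(feature_names)))
    return blocks


def gap_statistic(
    X: FeatureMatrix,
    k_values=range(2, 11),
    B: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSelection:
    """Gap-statistic choice of K with marginal-resampled references.

    Gap(K) = mean_b log W_b(K) − log W(K), with W the within-cluster sum of
    squares; s_K = sd_b(log W_b)·sqrt(1 + 1/B). The chosen K is the smallest
    with Gap(K) ≥ Gap(K+1) − s_{K+1} (the largest scanned K if none
    qualifies). Reference datasets keep every variable's one-hot block
    structure and marginal state frequencies but break associations between
    variables, which is the natural null for indicator blocks (a uniform
    bounding box is meaningless for 0/1 unit rows).
    """
    if B < 2:
        raise ValueError("gap statistic needs B >= 2 reference datasets")
    k_values = sorted(int(k) for k in k_values)
    data = X.matrix.astype(float)
    blocks = _infer_blocks(list(X.feature_names))
    eps = 1e-12

    ss = np.random.SeedSequence(seed)
    data_seeds, ref_ss = ss.spawn(2)
    data_seed = int(data_seeds.generate_state(1)[0] % (2**31))

    log_w = {}
    for k in k_values:
        _, w = _fit_kmeans(data, k, data_seed, n_init)
        if w <= 0:
            warnings.warn(f"zero inertia at K={k}; log guarded with epsilon", stacklevel=2)
        log_w[k] = np.log(max(w, eps))

    ref_children = ref_ss.spawn(B)
    log_w_ref = np.zeros((B, len(k_values)))
    for b, child in enumerate(ref_children):
        rng = np.random.default_rng(child)
        ref = _resample_marginals(data, blocks, rng)
        kseed = int(child.generate_state(2)[1] % (2**31))
        for j, k in enumerate(k_values):
            _, w = _fit_kmeans(ref, k, kseed, n_init)
            log_w_ref[b, j] = np.log(max(w, eps))

    gap = log_w_ref.mean(axis=0) - np.array([log_w[k] for k in k_values])
    s_k = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1 + 1 / B)

    chosen = k_values[-1]
    for j in range(len(k_values) - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            chosen = k_values[j]
            break
    return ClusterSelection(
        method="gap",
        chosen_k=int(chosen),
        diagnostics={
            "k_values": list(k_values),
            "gap": [float(g) for g in gap],
            "s_k": [float(s) for s in s_k],
            "log_w": [float(log_w[k]) for k in k_values],
            "B": B,
        },
    )
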