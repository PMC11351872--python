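"""Patient similarity network: Euclidean distances, KNN retrieval, embedding.

The network is materialized as the full symmetric distance matrix over the
one-hot feature embedding. Because each variable contributes a unit
indicator block, two patients differing in q variables sit at distance
sqrt(2q); squared distances between complete rows are even integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cohort import CohortTable, PATIENT_ID_COLUMN
from .encoding import EncodingModel, FeatureMatrix, transform


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative patient-patient Euclidean distances."""

    patient_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.patient_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match patient ids")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.patient_ids, name=PATIENT_ID_COLUMN)
        return pd.DataFrame(self.d, index=idx, columns=list(self.patient_ids))

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))


@dataclass
class NeighborSet:
    """K nearest reference patients for one index patient, ascending by distance."""

    index_id: str
    neighbors: list[tuple[str, float]]

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.neighbors]

    @property
    def distances(self) -> list[float]:
        return [d for _, d in self.neighbors]


def pairwise_distances(X: FeatureMatrix) -> DistanceMatrix:
    """Full Euclidean distance matrix over the feature embedding rows."""
    if X.n == 0:
        raise ValueError("cannot build a similarity network from zero patients")
    d = squareform(pdist(X.matrix.astype(float), metric="euclidean"))
    return DistanceMatrix(list(X.patient_ids), d)


def knn_query(
    model: EncodingModel,
    X_ref: FeatureMatrix,
    raw_patient: CohortTable,
    k: int,
    lenient: bool = False,
) -> NeighborSet:
    """Retrieve the k reference patients most similar to an index patient.

    The index patient's raw record is encoded with the already-fitted model
    (no refitting), so retrieval uses exactly the reference cohort's bin
    edges. The caller tunes the breadth of the retrieved case set through
    ``k``; ties at equal distance break by reference-table order.
    """
    if raw_patient.n != 1:
        raise ValueError("knn_query expects a single-patient record")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X_ref.n:
        warnings.warn(f"k={k} exceeds cohort size {X_ref.n}; clamped", stacklevel=2)
        k = X_ref.n
    x = transform(model, raw_patient, lenient=lenient).matrix[0].astype(float)
    dists = np.sqrt(np.sum((X_ref.matrix.astype(float) - x) ** 2, axis=1))
    order = np.argsort(dists, kind="stable")[:k]
    return NeighborSet(
        index_id=raw_patient.patient_ids[0],
        neighbors=[(X_ref.patient_ids[i], float(dists[i])) for i in order],
    )


def tsne_embed(
    X: FeatureMatrix,
    dims: int = 2,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Low-dimensional t-SNE view of the network, for display only.

    Coordinates are deterministic for a fixed seed. Clustering is always
    performed in the original feature space, never on this embedding.
    """
    from sklearn.manifold import TSNE

    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if X.n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n > 3*perplexity (n={X.n}, perplexity={perplexity}); "
            "lower the perplexity for small cohorts"
        )
    coords = TSNE(
        n_components=dims,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
    ).fit_transform(X.matrix.astype(float))
    cols = ["x", "y", "z"][:dims]
    return pd.DataFrame(coords, index=pd.Index(X.patient_ids, name=PATIENT_ID_COLUMN), columns=cols)
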