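"""Graph clustering, 2-D projection and partition-quality metrics.

Cells are clustered by Leiden modularity optimization on a cosine k-nearest-
neighbor graph built directly on the embedding matrix (no intermediate PCA:
the embedding itself is the low-dimensional representation, and cosine is
the similarity the embedding model optimizes for).  Cluster labels are
canonically relabeled by descending cluster size, ties broken by the
lexicographically smallest member id, so the labeling depends only on the
partition and the cell ids — not on row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .embed import EmbeddingMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    ids: list[str]
    labels: np.ndarray
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels and ids must align")
        uniq = np.unique(self.labels)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must cover 0..K-1 with no gaps")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.ids, "cluster": self.labels})


def _knn_graph(vectors: np.ndarray, n_neighbors: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="cosine")
    nn.fit(vectors)
    dist, idx = nn.kneighbors(vectors)
    edges: dict[tuple[int, int], float] = {}
    n = vectors.shape[0]
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            a, b = (i, int(j)) if i < j else (int(j), i)
            w = max(1.0 - float(d), 1e-12)  # cosine similarity as edge weight
            prev = edges.get((a, b))
            if prev is None or w > prev:
                edges[(a, b)] = w
    g = ig.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    return g


def _canonical_relabel(membership: np.ndarray, ids: list[str]) -> np.ndarray:
    """Relabel clusters by (-size, smallest member id): row-order invariant."""
    uniq = np.unique(membership)
    keys = []
    for c in uniq:
        members = [ids[i] for i in np.flatnonzero(membership == c)]
        keys.append((-len(members), min(members), c))
    mapping = {c: new for new, (_, _, c) in enumerate(sorted(keys))}
    return np.array([mapping[c] for c in membership], dtype=int)


def leiden_cluster(
    E: EmbeddingMatrix,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden modularity clustering on the cosine kNN graph of embeddings."""
    n = len(E.ids)
    if n < n_neighbors + 1:
        raise ValueError(f"need >= n_neighbors+1 = {n_neighbors + 1} cells, got {n}")
    g = _knn_graph(E.vectors, n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = _canonical_relabel(np.asarray(part.membership), E.ids)
    logger.info("leiden_cluster: %d cells -> %d clusters at resolution %.2f",
                n, labels.max() + 1, resolution)
    return ClusterAssignment(ids=list(E.ids), labels=labels, resolution=resolution, seed=seed)


def umap_project(E: EmbeddingMatrix, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """Two-dimensional UMAP of the embeddings (cosine metric, seeded)."""
    if len(E.ids) < 3:
        raise ValueError("need >= 3 cells for a 2-D projection")
    import umap

    reducer = umap.UMAP(
        n_components=2,
        metric="cosine",
        n_neighbors=min(n_neighbors, len(E.ids) - 1),
        random_state=seed,
    )
    coords = reducer.fit_transform(E.vectors)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return pd.DataFrame({"cell_id": E.ids, "umap1": coords[:, 0], "umap2": coords[:, 1]})


def clustering_metrics(
    pred: ClusterAssignment,
    truth: pd.Series | dict | np.ndarray,
    E: EmbeddingMatrix | None = None,
) -> dict[str, float]:
    """ARI and NMI of predicted vs true labels, plus the cell-type
    silhouette index of the embedding against the *true* annotations."""
    if isinstance(truth, (pd.Series, dict)):
        t = pd.Series(truth)
        missing = [i for i in pred.ids if i not in t.index]
        if missing:
            raise ValueError(f"truth labels missing for ids: {missing[:5]}")
        truth_arr = t.loc[pred.ids].to_numpy()
    else:
        truth_arr = np.asarray(truth)
        if len(truth_arr) != len(pred.ids):
            raise ValueError("truth labels and prediction ids are misaligned")
    out = {
        "ARI": float(adjusted_rand_score(truth_arr, pred.labels)),
        "NMI": float(normalized_mutual_info_score(truth_arr, pred.labels)),
    }
    if E is not None:
        if list(E.ids) != list(pred.ids):
            raise ValueError("embedding ids and prediction ids are misaligned")
        if len(set(map(str, truth_arr))) > 1:
            out["silhouette"] = float(silhouette_score(E.vectors, truth_arr, metric="cosine"))
        else:
            out["silhouette"] = float("nan")
    return out


def resolution_sweep(
    E: EmbeddingMatrix,
    truth,
    resolutions: list[float] | None = None,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Leiden + metrics per resolution (default 0.2 to 2.0 in steps of 0.2)."""
    if resolutions is None:
        resolutions = default_resolutions()
    rows = []
    for r in resolutions:
        pred = leiden_cluster(E, resolution=r, n_neighbors=n_neighbors, seed=seed)
        m = clustering_metrics(pred, truth)
        rows.append({"resolution": r, "n_clusters": pred.n_clusters,
                     "ARI": m["ARI"], "NMI": m["NMI"]})
    return pd.DataFrame(rows)


def default_resolutions() -> list[float]:
    return [round(0.2 * k, 1) for k in range(1, 11)]
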