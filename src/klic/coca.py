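"""Cluster Of Clusters Analysis (COCA).

COCA integrates the clusterings found separately in M datasets sharing (some
of) the same observations.  The per-dataset partitions are stacked into a
binary Matrix Of Clusters (MOC) with one row per (dataset, cluster) pair and
one column per observation; consensus clustering of the MOC columns then
yields a consensus matrix, and the final global partition is read off by
average-linkage hierarchical clustering on the dissimilarity ``1 - Delta``.

COCA is deliberately unweighted: every cluster found in the first step has
the same influence on the global clustering, which is exactly the limitation
the weighted KLIC pipeline (:mod:`klic.pipeline`) addresses.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import evalio
from .consensus import (
    ConsensusMatrix,
    DatasetMatrix,
    Partition,
    ResamplingScheme,
    consensus_cluster,
    make_clusterer,
)

__all__ = ["MOCMatrix", "build_moc", "coca_cluster", "coca_select_k",
           "select_k_silhouette"]


@dataclass
class MOCMatrix:
    """Binary Matrix Of Clusters: one row per (dataset, cluster) pair.

    Column n carries the one-hot encoding of observation n's cluster in each
    dataset; columns of observations missing from a dataset are all-zero in
    that dataset's block of rows.
    """

    values: np.ndarray
    row_labels: tuple[tuple[int, int], ...]
    obs_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MOC must be a 2-D matrix")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("MOC entries must be binary")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row_labels length must match number of rows")
        if len(self.obs_ids) != self.values.shape[1]:
            raise ValueError("obs_ids length must match number of columns")

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]


def build_moc(partitions: Sequence[Partition], obs_ids: Sequence[str]) -> MOCMatrix:
    """Stack per-dataset partitions into the binary Matrix Of Clusters.

    ``partitions[m]`` holds dataset m's labels over the shared observation
    universe ``obs_ids`` with its ``included_mask`` marking the observations
    present in dataset m; excluded observations yield all-zero columns in
    that dataset's rows.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    n = len(obs_ids)
    for m, part in enumerate(partitions):
        if part.n_items != n:
            raise ValueError(
                f"partition {m} covers {part.n_items} observations, expected {n}")
    rows, row_labels = [], []
    for m, part in enumerate(partitions):
        for k in range(1, part.K + 1):
            rows.append(((part.labels == k) & part.included_mask).astype(float))
            row_labels.append((m, k))
    return MOCMatrix(np.array(rows), tuple(row_labels), tuple(str(o) for o in obs_ids))


def coca_cluster(
    moc: MOCMatrix,
    K: int,
    scheme: ResamplingScheme | None = None,
    inner_method: str = "kmeans",
) -> tuple[Partition, ConsensusMatrix]:
    """Consensus-cluster the MOC columns and extract the global partition.

    The N observations (MOC columns, viewed as K-bar-dimensional binary
    vectors) are consensus-clustered with the inner base clusterer; the final
    labels come from average-linkage hierarchical clustering on the
    dissimilarity ``1 - Delta``, cut at K clusters.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > moc.n_obs:
        raise ValueError(f"K={K} exceeds the number of observations {moc.n_obs}")
    if scheme is None:
        scheme = ResamplingScheme()
    feature_names = tuple(f"d{m}_c{k}" for m, k in moc.row_labels)
    data = DatasetMatrix(moc.values.T, obs_ids=moc.obs_ids, feature_names=feature_names)
    delta = consensus_cluster(data, K, scheme, clusterer=make_clusterer(inner_method))
    dist = 1.0 - delta.values
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=K, criterion="maxclust")
    return Partition(labels=labels, K=int(labels.max())), delta


def coca_select_k(
    moc: MOCMatrix,
    candidates,
    scheme: ResamplingScheme | None = None,
    inner_method: str = "kmeans",
    distance: np.ndarray | None = None,
) -> tuple[int, dict[int, Partition], dict[int, float]]:
    """Run COCA over candidate global K and select by average silhouette.

    Every candidate is scored against one shared, K-independent distance —
    by default the Euclidean distance between MOC columns (the vectors
    actually being clustered) — so the silhouette measures how well each
    candidate partition fits the integrated cluster-membership profiles.
    Returns (selected K, labels per K, average silhouette per K).
    """
    ks = sorted(int(k) for k in candidates)
    if not ks:
        raise ValueError("empty candidate range")
    if distance is None:
        distance = squareform(pdist(moc.values.T, metric="euclidean"))
    labels_by_k: dict[int, Partition] = {}
    for k in ks:
        labels_by_k[k], _ = coca_cluster(moc, k, scheme, inner_method)
    best_k = select_k_silhouette(labels_by_k, distance)
    silhouettes = {k: evalio.silhouette_widths(labels_by_k[k], distance)[1] for k in ks}
    return best_k, labels_by_k, silhouettes


def select_k_silhouette(
    labels_by_k: Mapping[int, Partition],
    distance: np.ndarray,
) -> int:
    """Choose K maximising the average silhouette width on a shared distance.

    Every candidate is scored (singleton clusters score 0 by convention);
    ties break to the smallest K.
    """
    if not labels_by_k:
        raise ValueError("labels_by_k is empty")
    best_k, best_score = None, -np.inf
    for k in sorted(labels_by_k):
        _, avg = evalio.silhouette_widths(labels_by_k[k], distance)
        if avg > best_score + 1e-15:
            best_k, best_score = k, avg
    return int(best_k)
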