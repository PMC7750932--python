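"""Resampled consensus clustering of a single dataset.

Consensus clustering (CC) repeatedly perturbs a dataset by subsampling
observations and/or features, reclusters each perturbed dataset, and records
how often every pair of observations lands in the same cluster.  The resulting
*consensus matrix* summarises the stability of the clustering: entries close
to 0 or 1 indicate pairs that are (almost) always separated or co-clustered,
while intermediate values flag unstable structure.  The proportion of
ambiguous entries also gives a simple criterion for choosing the number of
clusters K.

Consensus matrices built here double as kernel matrices downstream (see
:mod:`klic.mkl`): a co-clustering matrix is block-diagonal with all-ones
blocks and hence positive semi-definite, and nonnegative combinations of
PSD matrices stay PSD.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "DatasetMatrix",
    "Partition",
    "CoClusteringMatrix",
    "ResamplingScheme",
    "ConsensusMatrix",
    "Clusterer",
    "coclustering_matrix",
    "subsample",
    "consensus_matrix",
    "consensus_cluster",
    "select_k_monti",
    "cluster_data",
    "make_clusterer",
]

#: A base clusterer maps (data subset, K, rng) to integer labels in 1..K.
Clusterer = Callable[[np.ndarray, int, np.random.Generator], np.ndarray]


@dataclass
class DatasetMatrix:
    """An observations x features data table with stable observation IDs."""

    values: np.ndarray
    obs_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D observations x features matrix")
        self.obs_ids = tuple(str(o) for o in self.obs_ids)
        self.feature_names = tuple(str(f) for f in self.feature_names)
        n, p = self.values.shape
        if n < 2:
            raise ValueError("a dataset needs at least 2 observations")
        if len(self.obs_ids) != n:
            raise ValueError(f"{len(self.obs_ids)} obs_ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        if len(set(self.obs_ids)) != n:
            raise ValueError("duplicate observation IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values: np.ndarray, prefix: str = "obs") -> "DatasetMatrix":
        """Wrap a bare array with generated observation/feature names."""
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        width = len(str(n))
        obs = tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))
        feats = tuple(f"var{j + 1}" for j in range(p))
        return cls(values, obs, feats)


@dataclass
class Partition:
    """Cluster labels for N items, possibly restricted to an included subset.

    Labels take values in ``1..K`` for included items; values at excluded
    positions are ignored by every consumer.
    """

    labels: np.ndarray
    K: int
    included_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.included_mask is None:
            self.included_mask = np.ones(self.labels.shape[0], dtype=bool)
        else:
            self.included_mask = np.asarray(self.included_mask, dtype=bool)
        if self.included_mask.shape != self.labels.shape:
            raise ValueError("included_mask length must match labels")
        self.K = int(self.K)
        if self.K < 1:
            raise ValueError("K must be positive")
        inc = self.labels[self.included_mask]
        if inc.size and (inc.min() < 1 or inc.max() > self.K):
            raise ValueError("included labels must lie in 1..K")

    @property
    def n_items(self) -> int:
        return self.labels.shape[0]


@dataclass
class CoClusteringMatrix:
    """Binary connectivity matrix of a single clustering run."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("co-clustering matrix must be square")

    @property
    def included(self) -> np.ndarray:
        """Items present in this run (diagonal entry 1)."""
        return np.diag(self.values) > 0.5


@dataclass(frozen=True)
class ResamplingScheme:
    """Number of runs H and subsampling proportions for consensus clustering.

    Defaults follow the common practice of 1000 resamplings, each with 80% of
    the observations and all the features.
    """

    n_runs: int = 1000
    item_proportion: float = 0.8
    feature_proportion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for name in ("item_proportion", "feature_proportion"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering frequencies over resampled runs.

    ``values[i, j]`` is the fraction of runs in which items *i* and *j* were
    assigned to the same cluster, among runs where both were sampled;
    ``copair_counts[i, j]`` records how many runs co-sampled the pair.
    """

    values: np.ndarray
    n_runs: int
    K: int
    copair_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("consensus matrix must be square")
        if self.copair_counts is None:
            self.copair_counts = np.full((n, n), self.n_runs, dtype=int)
        else:
            self.copair_counts = np.asarray(self.copair_counts, dtype=int)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


def coclustering_matrix(partition: Partition, n_items: int) -> CoClusteringMatrix:
    """Binary matrix with entry (i, j) = 1 iff i and j share a cluster label.

    Excluded items give zero rows/columns (including the diagonal), so the
    matrix simultaneously encodes the clustering and the sampling indicator
    of a run.  The result is invariant to relabelling the clusters.
    """
    if partition.n_items != n_items:
        raise ValueError(
            f"partition has {partition.n_items} items, expected {n_items}"
        )
    inc = partition.included_mask
    same = partition.labels[:, None] == partition.labels[None, :]
    values = (same & inc[:, None] & inc[None, :]).astype(float)
    return CoClusteringMatrix(values)


def subsample(
    scheme: ResamplingScheme,
    n_items: int,
    n_features: int,
    run_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic without-replacement item/feature sample for one run.

    Sample sizes are ``ceil(p * N)`` and ``ceil(p * P)``; the draw depends
    only on ``(scheme.seed, run_index)``.
    """
    if run_index >= scheme.n_runs:
        raise ValueError(f"run_index {run_index} >= n_runs {scheme.n_runs}")
    n_sub = math.ceil(scheme.item_proportion * n_items)
    p_sub = math.ceil(scheme.feature_proportion * n_features)
    if n_sub < 2:
        raise ValueError("item subsample has fewer than 2 items; raise item_proportion")
    if p_sub < 1:
        raise ValueError("feature subsample is empty")
    rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, run_index]))
    items = np.sort(rng.choice(n_items, size=n_sub, replace=False))
    feats = np.sort(rng.choice(n_features, size=p_sub, replace=False))
    return items, feats


def consensus_matrix(runs: Sequence[CoClusteringMatrix], K: int = 0) -> ConsensusMatrix:
    """Average co-clustering matrices over runs, pair by pair.

    Entry (i, j) is the number of runs co-clustering the pair divided by the
    number of runs co-sampling it; pairs never co-sampled get 0.
    """
    if not runs:
        raise ValueError("need at least one run")
    n = runs[0].values.shape[0]
    sum_c = np.zeros((n, n))
    sum_i = np.zeros((n, n))
    for r, run in enumerate(runs):
        if run.values.shape != (n, n):
            raise ValueError(f"run {r} has shape {run.values.shape}, expected {(n, n)}")
        inc = run.included.astype(float)
        sum_c += run.values
        sum_i += np.outer(inc, inc)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sum_i > 0, sum_c / np.maximum(sum_i, 1), 0.0)
    return ConsensusMatrix(values, n_runs=len(runs), K=K, copair_counts=sum_i.astype(int))


def _kmeans_labels(x: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 10) -> np.ndarray:
    if x.shape[0] < k:
        raise ValueError(f"cannot fit {k} clusters to {x.shape[0]} points")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=300,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return km.fit_predict(x) + 1


def _hierarchical_labels(x: np.ndarray, k: int, method: str) -> np.ndarray:
    if x.shape[0] < k:
        raise ValueError(f"cannot cut {k} clusters from {x.shape[0]} points")
    z = linkage(x, method=method, metric="euclidean")
    return fcluster(z, t=k, criterion="maxclust")


def pam_labels(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Classic BUILD + SWAP: medoids are seeded greedily, then single-medoid
    swaps are applied while they reduce the total distance-to-nearest-medoid.
    Deterministic; intended for the small problems where PAM is practical.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"cannot fit {k} medoids to {n} points")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        gain = np.maximum(nearest[:, None] - dist.T, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    cost = dist[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for pos in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[pos] = cand
                c = dist[:, trial].min(axis=1).sum()
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
        if not improved:
            break
    return np.argmin(dist[:, medoids], axis=1) + 1


def make_clusterer(
    method: str = "kmeans",
    n_restarts: int = 10,
    metric: str = "euclidean",
) -> Clusterer:
    """Build a base clusterer callable for :func:`consensus_cluster`.

    Supported methods: ``kmeans`` (k-means++ with restarts), ``pam``
    (partitioning around medoids; ``metric`` may be e.g. ``correlation``),
    ``hier-average`` and ``hier-complete`` (agglomerative, Euclidean).
    """
    if method == "kmeans":
        return lambda x, k, rng: _kmeans_labels(x, k, rng, n_restarts)
    if method == "pam":
        return lambda x, k, rng: pam_labels(squareform(pdist(x, metric=metric)), k)
    if method in ("hier-average", "hier-complete"):
        link = method.split("-", 1)[1]
        return lambda x, k, rng: _hierarchical_labels(x, k, link)
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_data(
    data: DatasetMatrix,
    K: int,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = 10,
    metric: str = "euclidean",
) -> Partition:
    """Cluster a dataset once with a standard algorithm; labels in 1..K."""
    if K > data.n_obs:
        raise ValueError(f"K={K} exceeds the number of observations {data.n_obs}")
    clusterer = make_clusterer(method, n_restarts=n_restarts, metric=metric)
    labels = clusterer(data.values, K, np.random.default_rng(seed))
    return Partition(labels=labels, K=K)


def consensus_cluster(
    data: DatasetMatrix,
    K: int,
    scheme: ResamplingScheme,
    clusterer: Clusterer | None = None,
) -> ConsensusMatrix:
    """Run resampled consensus clustering on one dataset.

    For each of H runs, subsample observations/features, apply the base
    clusterer with K clusters, and accumulate the co-clustering and
    co-sampling counts; the consensus matrix is their pairwise ratio.
    Fully determined by ``scheme.seed``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if clusterer is None:
        clusterer = make_clusterer("kmeans")
    n, p = data.n_obs, data.n_features
    sum_c = np.zeros((n, n))
    sum_i = np.zeros((n, n))
    for h in range(scheme.n_runs):
        items, feats = subsample(scheme, n, p, h)
        rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, h, 1]))
        try:
            sub_labels = np.asarray(clusterer(data.values[np.ix_(items, feats)], K, rng))
        except Exception as exc:  # noqa: BLE001 - re-raise with run context
            raise RuntimeError(f"base clusterer failed on run {h}: {exc}") from exc
        if sub_labels.shape[0] != items.shape[0]:
            raise RuntimeError(f"base clusterer returned {sub_labels.shape[0]} labels "
                               f"for {items.shape[0]} items on run {h}")
        labels = np.ones(n, dtype=int)
        labels[items] = sub_labels
        mask = np.zeros(n, dtype=bool)
        mask[items] = True
        cc = coclustering_matrix(Partition(labels, K=K, included_mask=mask), n)
        sum_c += cc.values
        sum_i += np.outer(mask, mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sum_i > 0, sum_c / np.maximum(sum_i, 1), 0.0)
    return ConsensusMatrix(values, n_runs=scheme.n_runs, K=K,
                           copair_counts=sum_i.astype(int))


def ambiguity_proportion(
    consensus: ConsensusMatrix, band: tuple[float, float] = (0.1, 0.9)
) -> float:
    """Proportion of off-diagonal consensus entries strictly inside ``band``."""
    lo, hi = band
    v = consensus.values
    off = ~np.eye(v.shape[0], dtype=bool)
    inside = (v > lo) & (v < hi) & off
    return float(inside.sum() / off.sum())


def select_k_monti(
    consensus_by_k: Mapping[int, ConsensusMatrix],
    ambiguity_band: tuple[float, float] = (0.1, 0.9),
) -> int:
    """Choose K whose consensus matrix has the fewest ambiguous entries.

    The score of a candidate is the proportion of off-diagonal entries
    strictly inside the ambiguity band; ties break to the smallest K.
    """
    if not consensus_by_k:
        raise ValueError("consensus_by_k is empty")
    if len(consensus_by_k) < 2:
        raise ValueError("need at least two candidate K values")
    best_k, best_score = None, np.inf
    for k in sorted(consensus_by_k):
        score = ambiguity_proportion(consensus_by_k[k], ambiguity_band)
        if score < best_score - 1e-15:
            best_k, best_score = k, score
    return int(best_k)
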