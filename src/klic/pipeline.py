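"""The KLIC pipeline: consensus matrices as kernels for integrative clustering.

Kernel Learning Integrative Clustering runs resampled consensus clustering on
each dataset, identifies the resulting consensus matrices as kernel matrices
(they are positive semi-definite up to the small perturbation introduced by
observation subsampling, which a spectral shift repairs), and combines them
with localized multiple-kernel k-means.  The output is a global partition
together with an N x M weight matrix Theta whose row i distributes
observation i's unit weight over the datasets, so noisy datasets are
down-weighted per observation rather than globally.

Observations missing from a dataset simply carry weight zero there (and zero
rows/columns in that dataset's consensus matrix); each observation must be
present in at least one dataset.  When a range of candidate K values is
given, the full optimisation is run per candidate and the K with the highest
average silhouette width — computed on the distance induced by that
candidate's own combined kernel — is selected.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from . import evalio
from .consensus import (
    Clusterer,
    ConsensusMatrix,
    DatasetMatrix,
    Partition,
    ResamplingScheme,
    consensus_cluster,
    make_clusterer,
    select_k_monti,
)
from .mkl import (
    KernelMatrix,
    MKLState,
    WeightMatrix,
    combine_kernels,
    localized_mkl_kmeans,
    spectral_shift,
)

__all__ = ["KlicResult", "run_klic", "run_klic_from_kernels", "kernel_to_distance"]


@dataclass
class KlicResult:
    """Global partition, per-sample dataset weights and diagnostics."""

    labels: Partition
    weights: WeightMatrix
    combined_kernel: KernelMatrix
    k_selected: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    per_dataset_consensus: list[ConsensusMatrix] = field(default_factory=list)
    obs_ids: tuple[str, ...] = ()

    def mean_weights(self) -> np.ndarray:
        """Average weight per dataset over the observations present in it."""
        theta, mask = self.weights.values, self.weights.observed_mask
        counts = np.maximum(mask.sum(axis=0), 1)
        return theta.sum(axis=0) / counts

    def weight_summary_percent(self) -> list[float]:
        """Per-dataset mean weights as percentages (run-summary format)."""
        return [round(float(100.0 * w), 1) for w in self.mean_weights()]


def kernel_to_distance(kernel) -> np.ndarray:
    """Feature-space Euclidean distance induced by a PSD kernel.

    ``d_ij = sqrt(max(0, K_ii + K_jj - 2 K_ij))``; the clamp guards the tiny
    negative values that finite-precision eigenvalues can produce.
    """
    a = kernel.values if hasattr(kernel, "values") else np.asarray(kernel, dtype=float)
    diag = np.diag(a)
    d2 = np.maximum(diag[:, None] + diag[None, :] - 2.0 * a, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _candidate_list(n_clusters) -> list[int]:
    if isinstance(n_clusters, (int, np.integer)):
        return [int(n_clusters)]
    ks = sorted(int(k) for k in n_clusters)
    if not ks:
        raise ValueError("empty candidate K range")
    return ks


def _align_observations(datasets: Sequence[DatasetMatrix]) -> tuple[tuple[str, ...], np.ndarray]:
    """Union of observation IDs (order of first appearance) and presence mask."""
    union: list[str] = []
    seen: set[str] = set()
    for data in datasets:
        for obs in data.obs_ids:
            if obs not in seen:
                union.append(obs)
                seen.add(obs)
    mask = np.zeros((len(union), len(datasets)), dtype=bool)
    index = {obs: i for i, obs in enumerate(union)}
    for m, data in enumerate(datasets):
        mask[[index[o] for o in data.obs_ids], m] = True
    return tuple(union), mask


def _embed_kernel(values: np.ndarray, positions: np.ndarray, n_total: int) -> np.ndarray:
    full = np.zeros((n_total, n_total))
    full[np.ix_(positions, positions)] = values
    return full


def _run_mkl_over_candidates(
    kernels_by_k,
    candidates: list[int],
    observed_mask: np.ndarray,
    tol: float,
    max_iter: int,
    seed: int,
):
    """Run the localized MKL optimisation per candidate K and pick by silhouette."""
    results: dict[int, tuple[MKLState, Partition, KernelMatrix]] = {}
    silhouettes: dict[int, float] = {}
    for k in candidates:
        kernels = kernels_by_k(k)
        state, part = localized_mkl_kmeans(
            kernels, k, observed_mask=observed_mask, tol=tol, max_iter=max_iter, seed=seed)
        combined = combine_kernels(kernels, state.weights)
        _, avg = evalio.silhouette_widths(part, kernel_to_distance(combined))
        results[k] = (state, part, combined, kernels)
        silhouettes[k] = avg
    best_k = max(sorted(silhouettes), key=lambda k: (silhouettes[k], -k))
    return best_k, results, silhouettes


def run_klic(
    datasets: Sequence[DatasetMatrix],
    n_clusters,
    consensus_k=None,
    scheme: ResamplingScheme | None = None,
    clusterers: Sequence[Clusterer] | str = "kmeans",
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> KlicResult:
    """Full KLIC: per-dataset consensus clustering, PSD repair, localized MKL.

    The consensus (kernel-building) stage is run once per dataset, at
    ``consensus_k`` clusters (a scalar, one value per dataset, or None);
    ``n_clusters`` — a single global K or an iterable of candidates — only
    drives the multiple-kernel optimisation.  With ``consensus_k=None`` a
    scalar ``n_clusters`` is reused for the consensus stage, while for a
    candidate range each dataset's count is chosen by the consensus
    ambiguity heuristic (:func:`klic.consensus.select_k_monti`) over the
    same candidates; in studies where the per-dataset cluster counts are
    known they should be passed explicitly.  ``clusterers`` is either a
    method name applied to every dataset or one base clusterer per dataset.
    Observations are aligned by their IDs across datasets; gaps are allowed
    as long as every observation appears somewhere.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    obs_ids, observed_mask = _align_observations(datasets)
    n = len(obs_ids)
    if scheme is None:
        scheme = ResamplingScheme(seed=seed)
    if isinstance(clusterers, str):
        clusterers = [make_clusterer(clusterers)] * len(datasets)
    elif len(clusterers) != len(datasets):
        raise ValueError("need one base clusterer per dataset")

    candidates = _candidate_list(n_clusters)
    if consensus_k is None:
        per_dataset_k = None if len(candidates) > 1 else [candidates[0]] * len(datasets)
    elif isinstance(consensus_k, (int, np.integer)):
        per_dataset_k = [int(consensus_k)] * len(datasets)
    else:
        per_dataset_k = [int(k) for k in consensus_k]
        if len(per_dataset_k) != len(datasets):
            raise ValueError("need one consensus_k per dataset")

    index = {obs: i for i, obs in enumerate(obs_ids)}
    positions = [np.array([index[o] for o in d.obs_ids]) for d in datasets]

    # One scheme (and seed) for every dataset: the resampled observation
    # subsets are shared across datasets of equal size, and the pipeline is
    # equivariant under permutation of the dataset list.
    per_dataset: list[ConsensusMatrix] = []
    kernels: list[KernelMatrix] = []
    for m, data in enumerate(datasets):
        if per_dataset_k is None:
            by_k = {k: consensus_cluster(data, k, scheme, clusterer=clusterers[m])
                    for k in candidates}
            delta = by_k[select_k_monti(by_k)]
        else:
            delta = consensus_cluster(data, per_dataset_k[m], scheme,
                                      clusterer=clusterers[m])
        repaired = spectral_shift(delta.values, source_tag=f"consensus:dataset{m}")
        per_dataset.append(delta)
        kernels.append(KernelMatrix(_embed_kernel(repaired.values, positions[m], n),
                                    source_tag=repaired.source_tag))

    best_k, results, silhouettes = _run_mkl_over_candidates(
        lambda k: kernels, candidates, observed_mask, tol, max_iter, seed)
    state, part, combined, _ = results[best_k]
    return KlicResult(
        labels=part,
        weights=state.weights,
        combined_kernel=combined,
        k_selected=best_k,
        silhouette_by_k=silhouettes,
        objective_trace=state.objective_trace,
        per_dataset_consensus=per_dataset,
        obs_ids=obs_ids,
    )


def run_klic_from_kernels(
    kernels: Sequence,
    n_clusters,
    observed_mask: np.ndarray | None = None,
    obs_ids: Sequence[str] | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> KlicResult:
    """KLIC on precomputed similarity matrices, skipping the consensus stage.

    Accepts any symmetric near-PSD matrices (consensus matrices, RBF kernels,
    other similarities); each is passed through the spectral-shift repair
    before use.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    repaired = [spectral_shift(k.values if hasattr(k, "values") else k,
                               source_tag=getattr(k, "source_tag", f"kernel{m}"))
                for m, k in enumerate(kernels)]
    n = repaired[0].n_items
    for m, k in enumerate(repaired):
        if k.n_items != n:
            raise ValueError(f"kernel {m} has {k.n_items} items, expected {n}")
    if obs_ids is None:
        obs_ids = tuple(f"obs{i + 1}" for i in range(n))

    candidates = _candidate_list(n_clusters)
    best_k, results, silhouettes = _run_mkl_over_candidates(
        lambda k: repaired, candidates,
        observed_mask if observed_mask is None else np.asarray(observed_mask, dtype=bool),
        tol, max_iter, seed)
    state, part, combined, _ = results[best_k]
    return KlicResult(
        labels=part,
        weights=state.weights,
        combined_kernel=combined,
        k_selected=best_k,
        silhouette_by_k=silhouettes,
        objective_trace=state.objective_trace,
        per_dataset_consensus=[],
        obs_ids=tuple(str(o) for o in obs_ids),
    )
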