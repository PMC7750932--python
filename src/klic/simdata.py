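"""Synthetic Gaussian cluster benchmarks for integrative clustering.

The generator draws six equal-size clusters (by default) in which an
observation of cluster k has mean ``k * s`` in every relevant variable, unit
variance and no correlation; optional irrelevant variables are pure N(0, 1)
noise.  The separability parameter ``s`` moves the datasets from an
unrecoverable regime (s = 0, no structure) to cleanly separated clusters:
adjacent cluster means differ by ``s`` per relevant variable against unit
noise.  Collections of datasets share one true partition while drawing
independent noise, either at a common separability ("similar datasets") or
at per-dataset levels ("heterogeneous datasets"), which is the setting used
to study how integrative methods weight informative versus noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Sequence

import numpy as np

from .consensus import DatasetMatrix, Partition

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "generate_similar_collection",
    "generate_heterogeneous_collection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of the Gaussian cluster generator.

    Defaults give 6 clusters x 50 observations (N = 300) on 2 relevant
    variables; ``n_noise = 13`` reproduces the 15-variable setting with
    irrelevant features.
    """

    n_clusters: int = 6
    n_per_cluster: int = 50
    separability: float = 1.0
    n_relevant: int = 2
    n_noise: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_per_cluster < 1:
            raise ValueError("n_clusters and n_per_cluster must be positive")
        if self.n_relevant < 1:
            raise ValueError("need at least one relevant variable")
        if self.n_noise < 0:
            raise ValueError("n_noise must be nonnegative")
        if self.separability < 0:
            raise ValueError("separability must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.n_clusters * self.n_per_cluster

    @property
    def n_features(self) -> int:
        return self.n_relevant + self.n_noise


def _true_labels(config: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(1, config.n_clusters + 1), config.n_per_cluster)


def generate_dataset(config: SimulationConfig) -> tuple[DatasetMatrix, Partition]:
    """Draw one dataset and its true partition.

    Cluster k's observations are N(mean, I) with mean ``k * s`` in each of
    the relevant variables and 0 in the noise variables.  Deterministic
    given ``config.seed``.
    """
    labels = _true_labels(config)
    n, p = config.n_obs, config.n_features
    means = np.zeros((n, p))
    means[:, : config.n_relevant] = (labels * config.separability)[:, None]
    rng = np.random.default_rng(config.seed)
    values = means + rng.standard_normal((n, p))
    width = len(str(n))
    obs_ids = tuple(f"obs{i + 1:0{width}d}" for i in range(n))
    features = tuple(f"var{j + 1}" for j in range(config.n_relevant)) + tuple(
        f"noise{j + 1}" for j in range(config.n_noise))
    data = DatasetMatrix(values, obs_ids=obs_ids, feature_names=features)
    return data, Partition(labels=labels, K=config.n_clusters)


def _spawned_seeds(seed: int, count: int) -> list[int]:
    states = np.random.SeedSequence(seed).generate_state(count)
    return [int(s % (2**31 - 1)) for s in states]


def generate_similar_collection(
    n_datasets: int, config: SimulationConfig
) -> list[tuple[DatasetMatrix, Partition]]:
    """Independent datasets sharing one true partition and one separability."""
    if n_datasets < 2:
        raise ValueError("a collection needs at least 2 datasets")
    return [
        generate_dataset(replace(config, seed=s))
        for s in _spawned_seeds(config.seed, n_datasets)
    ]


def generate_heterogeneous_collection(
    s_levels: Sequence[float], config: SimulationConfig
) -> list[tuple[DatasetMatrix, Partition]]:
    """Datasets sharing one true partition but differing in separability.

    One dataset per entry of ``s_levels``, in the given order, so callers
    can index levels directly (e.g. no/low/medium/high separability).
    """
    if len(s_levels) < 1:
        raise ValueError("need at least one separability level")
    seeds = _spawned_seeds(config.seed, len(s_levels))
    return [
        generate_dataset(replace(config, separability=float(s), seed=seed))
        for s, seed in zip(s_levels, seeds)
    ]
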