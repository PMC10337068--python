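"""Seeded synthetic expression-like data with known cluster structure.

The generator emulates the shape of the transcriptomics matrices the
method targets — few samples, many features, a handful of features
carrying group structure — without modelling platform-specific noise
(probe effects, RMA artifacts). Clusters are spherical Gaussians with
equal covariance: informative feature f is assigned to one cluster
(round-robin) whose mean is shifted by ``separation`` on that feature,
so each informative feature separates its cluster from the rest by
exactly ``separation`` in expectation; all other features are i.i.d.
noise independent of the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import FeatureRanking

__all__ = ["SyntheticDataset", "make_clustered_data", "make_random_ranking"]


@dataclass
class SyntheticDataset:
    """A generated matrix with ground truth attached."""

    X: pd.DataFrame  # n samples x p features
    labels: np.ndarray  # n cluster ids
    informative: np.ndarray  # indices of the features carrying structure
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def informative_ids(self) -> list[str]:
        return [self.X.columns[j] for j in self.informative]


def make_clustered_data(
    n: int = 60,
    p: int = 200,
    n_informative: int = 10,
    n_clusters: int = 3,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    weights=None,
    seed: int = 0,
) -> SyntheticDataset:
    """Gaussian clusters separated only along ``n_informative`` features.

    ``weights`` optionally sets unequal cluster proportions (defaults to
    balanced). A single seed fans out to independent substreams for
    label assignment and noise, so enlarging one draw does not perturb
    the other.
    """
    if n_informative > p:
        raise ValueError(f"n_informative={n_informative} exceeds p={p}")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds n={n}")
    if n_clusters < 1 or n < 1 or p < 1:
        raise ValueError("n, p and n_clusters must be positive")
    if separation < 0 or noise_sd < 0:
        raise ValueError("separation and noise_sd must be nonnegative")
    ss = np.random.SeedSequence(seed)
    label_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    if weights is None:
        weights = np.full(n_clusters, 1.0 / n_clusters)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != n_clusters or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per cluster")
        weights = weights / weights.sum()
    counts = np.floor(weights * n).astype(int)
    counts[: n - counts.sum()] += 1  # distribute the remainder deterministically
    labels = np.repeat(np.arange(n_clusters), counts)
    label_rng.shuffle(labels)

    informative = np.arange(n_informative)
    # informative feature f shifts the mean of cluster f % n_clusters
    means = np.zeros((n_clusters, p))
    for f in informative:
        means[f % n_clusters, f] = separation

    X = means[labels] + noise_rng.normal(scale=noise_sd, size=(n, p))
    frame = pd.DataFrame(
        X,
        index=[f"sample{i}" for i in range(n)],
        columns=[f"gene{j}" for j in range(p)],
    )
    return SyntheticDataset(
        X=frame,
        labels=labels,
        informative=informative,
        seed=seed,
        params={
            "n": n,
            "p": p,
            "n_informative": n_informative,
            "n_clusters": n_clusters,
            "separation": separation,
            "noise_sd": noise_sd,
        },
    )


def make_random_ranking(p: int, seed: int = 0, feature_ids=None) -> FeatureRanking:
    """A uniformly random feature order with uninformative constant scores."""
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    if feature_ids is None:
        feature_ids = [f"gene{j}" for j in range(p)]
    else:
        feature_ids = [str(f) for f in feature_ids]
        if len(feature_ids) != p:
            raise ValueError("feature_ids length must equal p")
    return FeatureRanking(
        feature_ids=feature_ids,
        scores=np.zeros(p),
        score_sd=np.zeros(p),
        order=order,
    )
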