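"""Unsupervised evaluation of feature rankings.

Three instruments, all label-free from the ranking's point of view:

* k-means clustering accuracy (best one-to-one cluster-to-class
  matching via the Hungarian algorithm) and normalized mutual
  information, averaged over repeated k-means runs on nested top-d
  feature subsets;
* silhouette curves of kernel PCA embeddings built from top-d subsets,
  compared against seeded random feature orders;
* train/test explained-variance curves checking that a ranking learned
  on a training split generalizes to held-out samples.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.metrics.cluster import contingency_matrix, normalized_mutual_info_score

from .kernels import KernelSpec
from .kpca import explained_variance, fit, select_sigma
from .ranking import FeatureRanking

__all__ = [
    "clustering_accuracy",
    "normalized_mutual_information",
    "subset_kmeans_eval",
    "silhouette_curve",
    "train_test_variance_curve",
]

logger = logging.getLogger(__name__)


def _check_labels(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("empty labelings")
    return a, b


def clustering_accuracy(true_labels, pred_labels) -> float:
    """Best-matching clustering accuracy in [0, 1].

    Maximizes the fraction of agreeing samples over all one-to-one
    assignments of predicted clusters to true classes (optimal
    assignment on the contingency table, not greedy matching).
    """
    t, p = _check_labels(true_labels, pred_labels)
    C = contingency_matrix(t, p)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum() / t.shape[0])


def normalized_mutual_information(true_labels, pred_labels, average: str = "geometric") -> float:
    """NMI in [0, 1]; geometric-mean normalization by default.

    ``average`` may be ``"geometric"`` (I / sqrt(H_t H_p)) or
    ``"arithmetic"``. Two identical single-cluster labelings score 1;
    a constant prediction against a non-trivial truth scores 0.
    """
    t, p = _check_labels(true_labels, pred_labels)
    if average not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown average {average!r}")
    return float(normalized_mutual_info_score(t, p, average_method=average))


def _subset_columns(X: pd.DataFrame, ranking: FeatureRanking, d: int) -> pd.DataFrame:
    return X.loc[:, ranking.top(d)]


def subset_kmeans_eval(
    X: pd.DataFrame,
    true_labels,
    ranking: FeatureRanking,
    d_grid: Sequence[int],
    k: int,
    runs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/sd ACC and NMI of repeated k-means on nested top-d subsets.

    For each subset size d, k-means (k clusters, fresh random
    initialization per run) is run ``runs`` times on the top-d columns;
    each run is scored against ``true_labels``. Seeded per (d, run) for
    reproducibility.
    """
    true_labels = np.asarray(true_labels).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n={X.shape[0]}")
    if max(d_grid) > X.shape[1]:
        raise ValueError("d_grid exceeds the number of features")
    ss = np.random.SeedSequence(seed)
    rows = []
    for d, child in zip(d_grid, ss.spawn(len(list(d_grid)))):
        Xd = _subset_columns(X, ranking, d).to_numpy()
        run_seeds = child.generate_state(runs) % (2**31)
        acc = np.empty(runs)
        nmi = np.empty(runs)
        for r in range(runs):
            km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                        random_state=int(run_seeds[r])).fit(Xd)
            acc[r] = clustering_accuracy(true_labels, km.labels_)
            nmi[r] = normalized_mutual_information(true_labels, km.labels_)
        rows.append(
            {
                "d": d,
                "acc_mean": acc.mean(),
                "acc_sd": acc.std(ddof=1) if runs > 1 else 0.0,
                "nmi_mean": nmi.mean(),
                "nmi_sd": nmi.std(ddof=1) if runs > 1 else 0.0,
                "runs": runs,
            }
        )
    return pd.DataFrame(rows)


def _embed(X_sub: pd.DataFrame, q: int, sigma_strategy, sigma_grid):
    """Fit RBF KPCA on a feature subset, choosing sigma per strategy."""
    if isinstance(sigma_strategy, (int, float)):
        sigma = float(sigma_strategy)
    elif sigma_strategy == "per-subset":
        sigma = select_sigma(X_sub, grid=sigma_grid, q=q)
    else:
        raise ValueError(f"unknown sigma_strategy {sigma_strategy!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit(X_sub, KernelSpec("rbf", sigma), q=q)
    return model.training_scores(), sigma


def silhouette_curve(
    X: pd.DataFrame,
    ranking: FeatureRanking,
    subset_sizes: Sequence[int],
    n_clusters: int = 2,
    q: int = 2,
    sigma_strategy="per-subset",
    sigma_grid=None,
    random_rankings: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Silhouette of KPCA embeddings from top-d subsets, vs random orders.

    For each subset size the top-d features are kept, KPCA is refit
    (sigma re-selected per subset unless a fixed value is given), the
    q-dimensional embedding is clustered by k-means into ``n_clusters``
    groups and the mean silhouette coefficient of that embedding is
    recorded. The same curve is computed for ``random_rankings`` seeded
    random feature orders. Subset sizes smaller than ``n_clusters`` are
    skipped with a warning.
    """
    from .datasets import make_random_ranking

    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    ss = np.random.SeedSequence(seed)
    rank_seeds = ss.generate_state(random_rankings + 1) % (2**31)
    rankings = [("kpca-ig", ranking)] + [
        (f"random{r}", make_random_ranking(X.shape[1], seed=int(rank_seeds[r + 1]),
                                           feature_ids=list(X.columns)))
        for r in range(random_rankings)
    ]
    rows = []
    for name, rk in rankings:
        for d in subset_sizes:
            if d < n_clusters:
                warnings.warn(f"subset size {d} < n_clusters={n_clusters}; skipped")
                continue
            Xd = _subset_columns(X, rk, d)
            scores, sigma = _embed(Xd, q=q, sigma_strategy=sigma_strategy,
                                   sigma_grid=sigma_grid)
            km = KMeans(n_clusters=n_clusters, n_init=10,
                        random_state=int(rank_seeds[0])).fit(scores)
            sil = silhouette_score(scores, km.labels_)
            rows.append({"ranking": name, "d": d, "silhouette": sil, "sigma": sigma})
    return pd.DataFrame(rows)


def train_test_variance_curve(
    X: pd.DataFrame,
    subset_sizes: Sequence[int],
    q: int = 2,
    splits: int = 5,
    train_fraction: float = 0.75,
    sigma_strategy="per-subset",
    sigma_grid=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative explained variance of top-d KPCA on train vs test splits.

    Per split: features are ranked (KPCA-IG) on the training samples
    only; for each subset size, KPCA is fit on the training top-d
    columns and, independently, on the test samples restricted to the
    same columns, recording the cumulative explained variance of the
    first q components of each. The sigma chosen on the training subset
    is reused on the test side so the two spectra are comparable.
    """
    from .ranking import rank_features

    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = X.shape[0]
    n_train = max(2, int(round(train_fraction * n)))
    if n - n_train < 2:
        raise ValueError("test split too small; lower train_fraction")
    ss = np.random.SeedSequence(seed)
    rows = []
    for split, child in enumerate(ss.spawn(splits)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigma0 = (float(sigma_strategy)
                      if isinstance(sigma_strategy, (int, float))
                      else select_sigma(X_train, grid=sigma_grid, q=q))
            model = fit(X_train, KernelSpec("rbf", sigma0), q=q)
        rk = rank_features(model)
        for d in subset_sizes:
            cols = rk.top(min(d, X.shape[1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if isinstance(sigma_strategy, (int, float)):
                    sigma = float(sigma_strategy)
                else:
                    sigma = select_sigma(X_train.loc[:, cols], grid=sigma_grid, q=q)
                m_train = fit(X_train.loc[:, cols], KernelSpec("rbf", sigma), q=q)
                m_test = fit(X_test.loc[:, cols], KernelSpec("rbf", sigma), q=q)
            rows.append(
                {
                    "split": split,
                    "d": d,
                    "sigma": sigma,
                    "train_ev": float(explained_variance(m_train).sum()),
                    "test_ev": float(explained_variance(m_test).sum()),
                }
            )
    return pd.DataFrame(rows)
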