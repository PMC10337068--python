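"""Gradient-based variable importance for kernel PCA (KPCA-IG).

For a fitted model with dual coefficients A (n x q), the projected
gradient field of feature j, evaluated at every training point, is the
n x q matrix

    W^j = G^j (I - (1/n) 1 1^T) A,    G^j_ai = D_j k(x_a, x_i),

whose row a is the direction of steepest variation of the embedding at
sample a when coordinate j moves. For the RBF kernel the derivative
factors as ``G^j = -2 sigma * K * (x^j 1^T - 1 (x^j)^T)`` elementwise,
so the whole ranking needs no kernel re-evaluation; for the linear
kernel G^j has constant rows and the field collapses to a single
direction shared by all samples.

The importance of feature j is the mean over samples of the row norms
``||W^j_a||``; the reported spread is the (n-1)-denominator standard
deviation of those n norms. Features are ranked by descending mean
norm, ties broken by original column position.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kpca import KPCAModel

__all__ = [
    "FeatureRanking",
    "gradient_projection",
    "feature_score",
    "rank_features",
    "write_ranking",
]


@dataclass
class FeatureRanking:
    """Per-feature importance scores and the descending-score order.

    ``feature_ids``, ``scores`` and ``score_sd`` are in original column
    order; ``order`` is the permutation that sorts scores descending
    (ties keep original position). ``norms``, when present, holds the
    raw n x p per-sample norms for diagnostics.
    """

    feature_ids: list[str]
    scores: np.ndarray
    score_sd: np.ndarray
    order: np.ndarray
    norms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.score_sd = np.asarray(self.score_sd, dtype=float)
        self.order = np.asarray(self.order, dtype=int)

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    @property
    def ranked_features(self) -> list[str]:
        return [self.feature_ids[i] for i in self.order]

    def top(self, d: int) -> list[str]:
        """Names of the d highest-scoring features."""
        return self.ranked_features[:d]

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Sorted table with columns rank, feature_id, score, sd."""
        if scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.p + 1),
                "feature_id": self.ranked_features,
                "score": self.scores[self.order] * scale,
                "sd": self.score_sd[self.order] * scale,
            }
        )


def _centered_coefs(model: KPCAModel) -> np.ndarray:
    A = model.dual_coefs
    return A - A.mean(axis=0, keepdims=True)


def gradient_projection(model: KPCAModel, j: int) -> np.ndarray:
    """Projected gradient field W^j (n x q) of feature j at the training points."""
    if not 0 <= j < model.p:
        raise IndexError(f"feature index {j} out of range for p={model.p}")
    HA = _centered_coefs(model)
    if model.kernel.family == "rbf":
        xj = model.X[:, j]
        G = -2.0 * model.kernel.sigma * model.K * (xj[:, None] - xj[None, :])
        return G @ HA
    # linear kernel: D_j k(x, x_i) = x_i[j], independent of the evaluation point
    w = model.X[:, j] @ HA
    return np.tile(w, (model.n, 1))


def feature_score(field: np.ndarray) -> tuple[float, float]:
    """Mean and sd (n-1 denominator) of the per-sample row norms of W^j."""
    field = np.asarray(field, dtype=float)
    norms = np.linalg.norm(field, axis=1)
    sd = float(norms.std(ddof=1)) if norms.size > 1 else 0.0
    return float(norms.mean()), sd


def _norms_block(model: KPCAModel, cols: np.ndarray, HA: np.ndarray) -> np.ndarray:
    """Per-sample norms (n x b) for a block of feature columns."""
    Xb = model.X[:, cols]  # n x b
    if model.kernel.family == "rbf":
        D = Xb[:, None, :] - Xb[None, :, :]  # n x n x b
        G = (-2.0 * model.kernel.sigma) * model.K[:, :, None] * D
        W = np.einsum("aib,ik->abk", G, HA)  # n x b x q
        return np.linalg.norm(W, axis=2)
    w = Xb.T @ HA  # b x q, shared by every sample
    return np.tile(np.linalg.norm(w, axis=1), (model.n, 1))


def rank_features(
    model: KPCAModel,
    block_size: int = 256,
    keep_norms: bool = False,
) -> FeatureRanking:
    """Score every feature and return the descending ranking.

    Features are processed in blocks of ``block_size`` columns to bound
    the n x n x block working memory; the result is identical to the
    one-shot computation. ``keep_norms=True`` retains the full n x p
    per-sample-norm matrix for diagnostics.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    HA = _centered_coefs(model)
    p = model.p
    scores = np.empty(p)
    sds = np.empty(p)
    all_norms = np.empty((model.n, p)) if keep_norms else None
    for start in range(0, p, block_size):
        cols = np.arange(start, min(start + block_size, p))
        norms = _norms_block(model, cols, HA)
        scores[cols] = norms.mean(axis=0)
        sds[cols] = norms.std(axis=0, ddof=1) if model.n > 1 else 0.0
        if all_norms is not None:
            all_norms[:, cols] = norms
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        feature_ids=list(model.feature_ids),
        scores=scores,
        score_sd=sds,
        order=order,
        norms=all_norms,
    )


def write_ranking(
    ranking: FeatureRanking,
    path=None,
    scale: float = 1.0,
    top: int | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the sorted ranking as TSV and return the emitted table.

    ``scale`` multiplies score and sd for display (e.g. 1000 to print
    milli-units); ``annotations`` is an optional two-column
    (feature_id, symbol) table merged into the output.
    """
    table = ranking.to_frame(scale=scale)
    if annotations is not None:
        ann = annotations.iloc[:, :2].copy()
        ann.columns = ["feature_id", "symbol"]
        table = table.merge(ann, on="feature_id", how="left")
    if top is not None:
        table = table.head(top)
    if path is None:
        table.to_csv(sys.stdout, sep="\t", index=False)
    else:
        table.to_csv(path, sep="\t", index=False)
    return table
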