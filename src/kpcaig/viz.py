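"""Plots: sample map, per-variable arrow field, score distribution.

The arrow field draws, at every sample's position in a 2D kernel PCA
plot, the projected gradient of one chosen variable — the direction in
which that sample's embedding moves as the variable increases. Arrows
pointing coherently across a cluster boundary indicate a variable whose
expression differs between the groups.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .kpca import KPCAModel, explained_variance
from .ranking import FeatureRanking, gradient_projection

__all__ = ["sample_plot", "variable_arrow_field", "score_distribution_plot"]


def _component_scores(model: KPCAModel, components: tuple[int, int]) -> np.ndarray:
    c1, c2 = components
    if not (0 <= c1 < model.q and 0 <= c2 < model.q):
        raise ValueError(
            f"components {components} out of range for q={model.q} (0-based)"
        )
    return model.training_scores()[:, [c1, c2]]


def sample_plot(
    model: KPCAModel,
    components: tuple[int, int] = (0, 1),
    labels=None,
    path=None,
    ax=None,
):
    """Scatter of training samples on two kernel principal components."""
    S = _component_scores(model, components)
    ev = explained_variance(model)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 5))
    if labels is not None:
        labels = np.asarray(labels)
        for g in np.unique(labels):
            m = labels == g
            ax.scatter(S[m, 0], S[m, 1], s=25, label=str(g), alpha=0.8)
        ax.legend(title="group", frameon=False)
    else:
        ax.scatter(S[:, 0], S[:, 1], s=25, color="tab:blue", alpha=0.8)
    c1, c2 = components
    ax.set_xlabel(f"KPC{c1 + 1} ({100 * ev[c1]:.1f}% variance)")
    ax.set_ylabel(f"KPC{c2 + 1} ({100 * ev[c2]:.1f}% variance)")
    if own_fig and path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax


def variable_arrow_field(
    model: KPCAModel,
    j: int,
    components: tuple[int, int] = (0, 1),
    arrow_scale: float | None = None,
    labels=None,
    subsample: int | None = None,
    path=None,
    ax=None,
):
    """Overlay feature j's projected gradient arrows on the sample plot.

    Anchors are the sample scores on the chosen components; directions
    are the matching columns of the projected gradient field W^j. With
    ``arrow_scale=None`` the longest arrow is normalized to 10% of the
    axis range; zero-length directions draw no arrow. ``subsample``
    deterministically thins the anchors for large n.
    """
    S = _component_scores(model, components)
    W = gradient_projection(model, j)[:, list(components)]
    ax = sample_plot(model, components=components, labels=labels, ax=ax)
    idx = np.arange(model.n)
    if subsample is not None and subsample < model.n:
        idx = np.linspace(0, model.n - 1, subsample).astype(int)
    lengths = np.linalg.norm(W, axis=1)
    if arrow_scale is None:
        span = max(np.ptp(S[:, 0]), np.ptp(S[:, 1])) or 1.0
        arrow_scale = 0.1 * span / lengths.max() if lengths.max() > 0 else 1.0
    for i in idx:
        if lengths[i] == 0:
            continue
        ax.annotate(
            "",
            xy=(S[i, 0] + arrow_scale * W[i, 0], S[i, 1] + arrow_scale * W[i, 1]),
            xytext=(S[i, 0], S[i, 1]),
            arrowprops={"arrowstyle": "->", "color": "crimson", "lw": 0.9},
        )
    ax.set_title(f"{model.feature_ids[j]}")
    fig = ax.get_figure()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax


def score_distribution_plot(ranking: FeatureRanking, path=None, ax=None):
    """Importance scores against rank (descending), extremes annotated."""
    if ranking.p == 0:
        raise ValueError("empty ranking")
    sorted_scores = ranking.scores[ranking.order]
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, ranking.p + 1), sorted_scores, lw=1.2, color="tab:blue")
    ax.set_xlabel("rank")
    ax.set_ylabel("importance score")
    ax.annotate(f"max = {sorted_scores[0]:.4g}", xy=(1, sorted_scores[0]),
                xytext=(5, -2), textcoords="offset points", fontsize=8)
    ax.annotate(f"min = {sorted_scores[-1]:.4g}",
                xy=(ranking.p, sorted_scores[-1]),
                xytext=(-5, 5), textcoords="offset points",
                ha="right", fontsize=8)
    if own_fig and path is not None:
        ax.get_figure().savefig(path, bbox_inches="tight")
        plt.close(ax.get_figure())
    return ax
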