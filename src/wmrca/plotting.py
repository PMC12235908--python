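"""Diagnostic plots: consensus heatmaps, CDF/delta-area curves, tracking
plots, per-index bar charts, voting summaries, confusion matrices and ROC
curves.  Every function draws on a provided or fresh Axes and optionally
saves to a path; all figures are static matplotlib."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .consensus import CdfCurve, ClusterAssignment, ConsensusMatrix
from .indices import IndexProfile, decide_best_k
from .voting import VotingResult


def _finish(fig, path: str | Path | None):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def consensus_heatmap(cm: ConsensusMatrix, assignment: ClusterAssignment | None = None,
                      path: str | Path | None = None):
    """Consensus matrix heatmap, samples ordered by cluster when given."""
    order = np.arange(cm.n_samples)
    if assignment is not None:
        order = np.argsort(assignment.to_array(cm.sample_ids), kind="stable")
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm.M[np.ix_(order, order)], vmin=0, vmax=1, cmap="Blues",
                   interpolation="nearest")
    ax.set_title(f"Consensus matrix, K={cm.K}")
    ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="consensus")
    return _finish(fig, path)


def cdf_curves(cdfs: dict[int, CdfCurve], path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    for k in sorted(cdfs):
        ax.plot(cdfs[k].grid, cdfs[k].values, label=f"K={k}")
    ax.set_xlabel("consensus index"); ax.set_ylabel("CDF")
    ax.legend(); ax.set_title("Consensus CDF")
    return _finish(fig, path)


def delta_area_plot(delta: dict[int, float], path: str | Path | None = None):
    ks = sorted(delta)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ks, [delta[k] for k in ks], marker="o")
    ax.set_xlabel("K"); ax.set_ylabel("relative change in area under CDF")
    ax.set_title("Delta area")
    return _finish(fig, path)


def tracking_plot(table: pd.DataFrame, path: str | Path | None = None):
    """Cluster membership of each sample across K (one row per K)."""
    ks = sorted(table["K"].unique())
    samples = list(dict.fromkeys(table["sample_id"]))
    mat = np.zeros((len(ks), len(samples)), dtype=int)
    lookup = {(r.sample_id, r.K): r.cluster for r in table.itertuples()}
    for i, k in enumerate(ks):
        for j, s in enumerate(samples):
            mat[i, j] = lookup[(s, k)]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(ks) + 1.5))
    ax.imshow(mat, aspect="auto", cmap="tab10", interpolation="nearest")
    ax.set_yticks(range(len(ks)), [f"K={k}" for k in ks])
    ax.set_xlabel("samples"); ax.set_title("Cluster tracking")
    return _finish(fig, path)


def index_bar_chart(profile: IndexProfile, path: str | Path | None = None):
    """Bar chart of one index over K with the winning K highlighted."""
    best = decide_best_k(profile)
    colors = ["crimson" if k == best else "steelblue" for k in profile.k_grid]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar([str(k) for k in profile.k_grid], np.nan_to_num(profile.values), color=colors)
    ax.set_xlabel("K"); ax.set_title(profile.index_name)
    return _finish(fig, path)


def voting_bar_chart(voting: VotingResult, path: str | Path | None = None):
    ks = sorted(voting.vote_totals)
    colors = ["crimson" if k == voting.selected_k else "steelblue" for k in ks]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.bar([str(k) for k in ks], [voting.vote_totals[k] for k in ks], color=colors)
    ax.axhline(voting.theta, ls="--", color="gray", label=f"theta={voting.theta:g}")
    ax.set_xlabel("K"); ax.set_ylabel("weighted votes"); ax.legend()
    ax.set_title(f"Weighted majority vote (selected K={voting.selected_k})")
    return _finish(fig, path)


def confusion_heatmap(table: pd.DataFrame, path: str | Path | None = None):
    """Heatmap of a class × class confusion table (counts)."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(table.to_numpy(), cmap="Blues")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45)
    ax.set_yticks(range(table.shape[0]), table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            ax.text(j, i, str(table.iat[i, j]), ha="center", va="center")
    ax.set_xlabel("true class"); ax.set_ylabel("predicted")
    fig.colorbar(im, ax=ax)
    return _finish(fig, path)


def roc_plot(roc: pd.DataFrame, auc: float, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc["fpr"], roc["tpr"], marker=".", label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", color="gray")
    ax.set_xlabel("false positive rate"); ax.set_ylabel("true positive rate")
    ax.legend(); ax.set_title("ROC")
    return _finish(fig, path)
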