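"""Report figures: PR curves, MCC heatmaps, CV boxes, importance bars.

All functions take the report objects produced by :mod:`mvstack.evaluation`
and :mod:`mvstack.interpretation` and return a matplotlib Figure; pass
``path`` to also save it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig


def plot_pr_curves(report, split: str = "test", path=None):
    """PR curves with per-model AP in the legend and the random-AP line."""
    fig, ax = plt.subplots(figsize=(6.5, 5))
    for name, by_split in sorted(report.pr_curves.items()):
        if split not in by_split:
            continue
        pts = np.asarray(by_split[split])
        ap = report.ap_by_model_and_split[name][split]
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AP={ap:.2f})", lw=1.2)
    ax.axhline(
        report.random_ap_by_split[split], color="red", ls="--", lw=1, label="random AP"
    )
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title(f"Precision-Recall curves ({split} set)")
    ax.legend(fontsize=7, loc="upper right")
    return _finish(fig, path)


def plot_mcc_heatmap(report, split: str = "train", path=None):
    """Symmetric model-agreement heatmap (base learners, Stacked, labels)."""
    M = report.mcc_matrices[split]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(M)), M.columns, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(M)), M.index, fontsize=8)
    for i in range(len(M)):
        for j in range(len(M)):
            ax.text(j, i, f"{M.iat[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="MCC")
    ax.set_title(f"Prediction agreement ({split} set)")
    return _finish(fig, path)


def plot_cv_boxes(cv, path=None):
    """Per-model box summary of train vs validation fold AP."""
    per_fold = cv.per_fold
    models = per_fold["model"].drop_duplicates().tolist()
    fig, ax = plt.subplots(figsize=(1.1 * len(models) + 2, 4.5))
    width = 0.35
    for offset, (col, color) in enumerate(
        [("train_ap", "tab:blue"), ("validation_ap", "tab:orange")]
    ):
        data = [per_fold.loc[per_fold["model"] == m, col] for m in models]
        ax.boxplot(
            data,
            positions=np.arange(len(models)) + (offset - 0.5) * width,
            widths=width,
            patch_artist=True,
            boxprops={"facecolor": color, "alpha": 0.6},
            medianprops={"color": "black"},
        )
    ax.set_xticks(range(len(models)), models, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("Average precision")
    ax.set_title("Cross-validation AP (blue: train folds, orange: validation fold)")
    return _finish(fig, path)


def plot_meta_weights(importance, path=None):
    """Sorted normalized meta-learner weights as horizontal bars."""
    w = importance.meta_weights
    if w is None:
        raise ValueError("no linear meta weights available")
    fig, ax = plt.subplots(figsize=(5.5, 0.4 * len(w) + 1.5))
    ax.barh(w["name"][::-1], w["normalized"][::-1], color="tab:blue")
    ax.axvline(0.0, color="red", lw=1)
    ax.set_xlabel("Normalized meta-learner weight")
    ax.set_title("Base-learner contributions")
    return _finish(fig, path)


def plot_permutation_importance(importance, top: int = 10, path=None):
    """Top-N permutation importances with per-repeat spread, red zero line."""
    tbl = importance.top_features(top)
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(tbl) + 1.5))
    ypos = np.arange(len(tbl))[::-1]
    for yy, (_, row) in zip(ypos, tbl.iterrows()):
        reps = np.asarray(row["repeats"], dtype=float)
        ax.scatter(reps, np.full_like(reps, yy), s=10, alpha=0.5, color="tab:blue")
        ax.plot([row["median"]], [yy], marker="|", ms=14, color="black")
    ax.axvline(0.0, color="red", lw=1)
    ax.set_yticks(ypos, tbl["feature"], fontsize=8)
    ax.set_xlabel(f"Importance (baseline - permuted {importance.metric})")
    ax.set_title(f"Top {len(tbl)} permutation feature importances")
    return _finish(fig, path)
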