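"""Two-level interpretability for a fitted stacked model.

Level 1 — which base learner matters: the meta learner's regression
weights, normalized by the maximum absolute weight so the top learner's
importance is exactly +/-1, then ranked.

Level 2 — which original feature matters: permutation feature importance
through the *entire* fitted pipeline. The baseline metric (average
precision by default, on the training set) is computed once; then each
original feature column is shuffled and the metric recomputed through
filter -> base learners -> meta learner without any refitting. Importance
is baseline minus permuted, repeated ``n_repeats`` times per feature with
the median reported. Features discarded by the microbial filter can never
reach a model, so their importance is exactly zero by construction and is
reported as such (keeping reports comparable across filter settings).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MultiViewDataset
from .evaluation import average_precision
from .stacking import StackedResults, derive_seed


@dataclasses.dataclass
class ImportanceReport:
    """Ranked meta weights + per-feature permutation importances."""

    meta_weights: pd.DataFrame | None  # name, raw, normalized, rank
    perm_importance: pd.DataFrame  # feature, view, repeats (list), median
    n_repeats: int
    metric: str
    seed: int

    def top_features(self, n: int = 10) -> pd.DataFrame:
        return (
            self.perm_importance.sort_values("median", ascending=False)
            .head(n)
            .reset_index(drop=True)
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "metric": self.metric,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "meta_weights": (
                None
                if self.meta_weights is None
                else self.meta_weights.round(10).to_dict(orient="records")
            ),
            "permutation_importance": [
                {
                    "feature": r["feature"],
                    "view": r["view"],
                    "median": round(float(r["median"]), 10),
                    "repeats": [round(float(v), 10) for v in r["repeats"]],
                }
                for r in self.perm_importance.to_dict(orient="records")
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def normalized_meta_weights(model: StackedResults) -> pd.DataFrame:
    """Meta-learner weights scaled by the max absolute weight, ranked.

    Requires a linear meta learner; for a tree-ensemble meta model the
    weight notion does not exist and the permutation path should be used.
    """
    if not model.meta.is_linear:
        raise ValueError(
            "meta learner is not linear: no regression weights to report; "
            "use permutation_importance instead"
        )
    raw = model.meta.coef_
    denom = np.max(np.abs(raw))
    norm = raw / denom if denom > 0 else raw
    out = pd.DataFrame(
        {"name": model.base_names, "raw": raw, "normalized": norm}
    ).sort_values("normalized", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def permutation_importance(
    model: StackedResults,
    ds: MultiViewDataset,
    n_repeats: int = 10,
    seed: int = 0,
    metric: str = "average_precision",
) -> ImportanceReport:
    """Pipeline-level permutation importance of every original feature.

    For each feature and repeat, that single column of the original view is
    shuffled (seeded), the full fitted pipeline is re-applied without
    retraining, and the importance is ``baseline - permuted`` metric.
    Deterministic for a fixed (model, seed).
    """
    if metric != "average_precision":
        raise ValueError("only the average_precision metric is supported")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = ds.labels.to_numpy()
    baseline = average_precision(y, model.predict_proba(ds))

    # features killed by the fitted filter never reach a model
    reachable: dict[str, set] = {}
    for view, frame in ds.views.items():
        if model.filter_state is not None and view in ("microbial",):
            reachable[view] = set(model.filter_state.kept_features)
        else:
            reachable[view] = set(frame.columns)

    rows = []
    for view, frame in ds.views.items():
        for feature in frame.columns:
            if feature not in reachable[view]:
                rows.append(
                    {
                        "feature": feature,
                        "view": view,
                        "repeats": [0.0] * n_repeats,
                        "median": 0.0,
                    }
                )
                continue
            repeats = []
            for r in range(n_repeats):
                rng = np.random.default_rng(derive_seed(seed, "perm", view, feature, r))
                permuted = frame.copy()
                permuted[feature] = rng.permutation(permuted[feature].to_numpy())
                views = dict(ds.views)
                views[view] = permuted
                mutated = MultiViewDataset(
                    views=views, labels=ds.labels, feature_meta=dict(ds.feature_meta)
                )
                repeats.append(baseline - average_precision(y, model.predict_proba(mutated)))
            rows.append(
                {
                    "feature": feature,
                    "view": view,
                    "repeats": repeats,
                    "median": float(np.median(repeats)),
                }
            )

    try:
        weights = normalized_meta_weights(model)
    except ValueError:
        weights = None
    return ImportanceReport(
        meta_weights=weights,
        perm_importance=pd.DataFrame(rows),
        n_repeats=n_repeats,
        metric=metric,
        seed=seed,
    )
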