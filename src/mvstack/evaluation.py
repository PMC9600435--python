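"""Imbalance-aware evaluation: PR/AP, MCC agreement, CV summaries.

Average precision (the step-sum summarization of the precision-recall
curve) is the headline metric throughout because both cohorts are
imbalanced and ROC-style summaries are over-optimistic there; the AP of an
uninformative ranker equals the positive-class prevalence, which is the
reference line drawn on every PR plot. Matthews correlation between the
thresholded predictions of every pair of models (and the labels) measures
classifier diversity — low mutual agreement with high label agreement is
exactly the regime in which a meta learner has something to combine.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    precision_recall_curve,
)

from .dataset import MultiViewDataset
from .preprocess import compute_class_weights, fit_view_filter
from .stacking import (
    MICROBIAL_VIEW,
    StackedGeneralization,
    StackingConfig,
    _design_matrices,
    _fit_one,
    build_meta_features,
    derive_seed,
    positive_proba,
    soft_vote,
    stratified_fold_assignment,
)

SOFTVOTE = "SoftVote"
STACKED = "Stacked"
LABELS = "labels"


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y


def average_precision(labels, scores) -> float:
    """Step-sum AP over descending score thresholds (ties = one threshold)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return float(average_precision_score(y, s))


def random_ap(labels) -> float:
    """Expected AP of an uninformative ranker: the positive prevalence."""
    y = _check_labels(labels)
    return float(y.sum() / len(y))


def pr_curve(labels, scores) -> list[tuple[float, float]]:
    """(recall, precision) points with recall non-decreasing."""
    precision, recall, _ = precision_recall_curve(_check_labels(labels), scores)
    return list(zip(recall[::-1].tolist(), precision[::-1].tolist()))


def mcc(a, b) -> float:
    """Matthews correlation between two binary vectors (a = reference).

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    denominator — e.g. one vector predicting a single class — yields 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(a, b))


def mcc_matrix(predicted_labels: Mapping[str, np.ndarray], labels) -> pd.DataFrame:
    """Symmetric MCC matrix over every model pair plus the labels row."""
    vecs = {name: np.asarray(v) for name, v in predicted_labels.items()}
    vecs[LABELS] = np.asarray(labels)
    names = list(vecs)
    n = len(next(iter(vecs.values())))
    for name, v in vecs.items():
        if len(v) != n:
            raise ValueError(f"prediction vector {name!r} has wrong length")
    M = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            val = mcc(vecs[a], vecs[b])
            M.loc[a, b] = M.loc[b, a] = val
    return M


@dataclasses.dataclass
class EvaluationReport:
    """AP per model per split, PR curves, MCC matrices, random-AP lines."""

    ap_by_model_and_split: dict[str, dict[str, float]]  # model -> split -> AP
    pr_curves: dict[str, dict[str, list[tuple[float, float]]]]
    mcc_matrices: dict[str, pd.DataFrame]  # split -> matrix
    random_ap_by_split: dict[str, float]

    def ap_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.ap_by_model_and_split).T.sort_index()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ap": {
                m: {s: round(v, 10) for s, v in d.items()}
                for m, d in sorted(self.ap_by_model_and_split.items())
            },
            "random_ap": {s: round(v, 10) for s, v in sorted(self.random_ap_by_split.items())},
            "mcc": {
                split: {
                    "names": M.index.tolist(),
                    "values": [[round(float(x), 10) for x in row] for row in M.to_numpy()],
                }
                for split, M in sorted(self.mcc_matrices.items())
            },
            "pr_curves": {
                m: {s: [[round(r, 10), round(p, 10)] for r, p in pts] for s, pts in d.items()}
                for m, d in sorted(self.pr_curves.items())
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_split(results, ds: MultiViewDataset) -> tuple[dict, dict, pd.DataFrame]:
    """Score one split: per-model AP + PR curves + MCC matrix.

    Models = every refit base learner, the soft-vote baseline and the
    stacked classifier; MCC is computed on labels thresholded at 0.5.
    """
    y = ds.labels.to_numpy()
    base = results.base_probabilities(ds)
    scores = {name: base[name].to_numpy() for name in base.columns}
    _, scores[SOFTVOTE] = soft_vote(base)
    scores[STACKED] = results.predict_proba(ds)
    ap = {name: average_precision(y, s) for name, s in scores.items()}
    curves = {name: pr_curve(y, s) for name, s in scores.items()}
    hard = {name: (s >= 0.5).astype(int) for name, s in scores.items()}
    return ap, curves, mcc_matrix(hard, y)


def evaluate_models(
    results, train: MultiViewDataset, test: MultiViewDataset | None = None
) -> EvaluationReport:
    """Full report on the training split and (optionally) the test split."""
    ap_by_model: dict[str, dict[str, float]] = {}
    curves_by_model: dict[str, dict] = {}
    mcc_by_split = {}
    rand = {}
    splits = {"train": train}
    if test is not None:
        splits["test"] = test
    for split, ds in splits.items():
        ap, curves, M = evaluate_split(results, ds)
        mcc_by_split[split] = M
        rand[split] = random_ap(ds.labels)
        for name in ap:
            ap_by_model.setdefault(name, {})[split] = ap[name]
            curves_by_model.setdefault(name, {})[split] = curves[name]
    return EvaluationReport(
        ap_by_model_and_split=ap_by_model,
        pr_curves=curves_by_model,
        mcc_matrices=mcc_by_split,
        random_ap_by_split=rand,
    )


# ---------------------------------------------------------------------------
# cross-validated train/validation performance


@dataclasses.dataclass
class CVPerformance:
    """Per-model per-fold train/validation AP plus medians."""

    per_fold: pd.DataFrame  # columns: model, fold, train_ap, validation_ap

    def medians(self) -> pd.DataFrame:
        med = self.per_fold.groupby("model")[["train_ap", "validation_ap"]].median()
        return med.rename(columns={"train_ap": "train", "validation_ap": "validation"})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_fold": self.per_fold.round(10).to_dict(orient="records"),
            "medians": self.medians().round(10).to_dict(orient="index"),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def cv_performance(
    train: MultiViewDataset,
    config: StackingConfig | None = None,
    include_stacked: bool = True,
) -> CVPerformance:
    """k-fold train/validation AP for every base learner (+Stacked, SoftVote).

    For each outer fold: preprocessing and every base learner are fit on
    the k-1 training folds; AP is scored on those same folds (train) and on
    the held-out fold (validation). The stacked row is produced by a nested
    out-of-fold construction entirely inside the k-1 training folds, so the
    held-out fold is never touched during its fit.
    """
    cfg = config or StackingConfig()
    y = train.labels.to_numpy()
    folds = stratified_fold_assignment(y, cfg.k, derive_seed(cfg.seed, "cv-outer"))
    ids = train.sample_ids
    rows = []
    for f in np.unique(folds):
        tr_ds = train.subset(ids[folds != f])
        va_ds = train.subset(ids[folds == f])
        y_tr = tr_ds.labels.to_numpy()
        y_va = va_ds.labels.to_numpy()

        filter_state = None
        if cfg.filter_microbial and MICROBIAL_VIEW in train.views:
            filter_state = fit_view_filter(
                tr_ds.views[MICROBIAL_VIEW], y_tr, alpha=cfg.alpha, correction=cfg.correction
            )
        cw = compute_class_weights(y_tr)
        specs = list(cfg.specs) if cfg.specs is not None else None
        from .learners import default_suite

        if specs is None:
            specs = default_suite(train.view_names, seed=cfg.seed)
        views_tr, cats = _design_matrices(tr_ds, filter_state, None)
        views_va, _ = _design_matrices(va_ds, filter_state, cats)

        P_tr = {}
        P_va = {}
        for spec in specs:
            Xtr, cat_mask = views_tr[spec.view]
            Xva, _ = views_va[spec.view]
            model = _fit_one(spec, Xtr, y_tr, cw, cat_mask, ("cv", int(f)))
            P_tr[spec.name] = positive_proba(model, Xtr)
            P_va[spec.name] = positive_proba(model, Xva)
            rows.append(
                {
                    "model": spec.name,
                    "fold": int(f),
                    "train_ap": average_precision(y_tr, P_tr[spec.name]),
                    "validation_ap": average_precision(y_va, P_va[spec.name]),
                }
            )
        _, sv_tr = soft_vote(pd.DataFrame(P_tr))
        _, sv_va = soft_vote(pd.DataFrame(P_va))
        rows.append(
            {
                "model": SOFTVOTE,
                "fold": int(f),
                "train_ap": average_precision(y_tr, sv_tr),
                "validation_ap": average_precision(y_va, sv_va),
            }
        )
        if include_stacked:
            inner_cfg = dataclasses.replace(
                cfg, seed=derive_seed(cfg.seed, "cv-inner", int(f)), specs=tuple(specs)
            )
            res = StackedGeneralization(tr_ds, inner_cfg).fit()
            rows.append(
                {
                    "model": STACKED,
                    "fold": int(f),
                    "train_ap": average_precision(y_tr, res.predict_proba(tr_ds)),
                    "validation_ap": average_precision(y_va, res.predict_proba(va_ds)),
                }
            )
    return CVPerformance(per_fold=pd.DataFrame(rows))


def overfit_gap(report: CVPerformance) -> pd.Series:
    """Median train AP minus median validation AP, per model (report order)."""
    med = report.medians()
    order = report.per_fold["model"].drop_duplicates().tolist()
    gap = (med["train"] - med["validation"]).reindex(order)
    gap.name = "overfit_gap"
    return gap


def builtin_cv_summary(meta_features, labels) -> pd.DataFrame:  # pragma: no cover
    """Convenience: fold-wise prevalence of the out-of-fold construction."""
    y = pd.Series(np.asarray(labels), index=meta_features.values.index)
    return y.groupby(meta_features.fold_of_sample).mean().rename("prevalence").to_frame()
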