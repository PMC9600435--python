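"""Multi-view stacked generalization: the core model.

The training set is split into k stratified folds; in k sequential rounds
each base learner is trained on k-1 folds and predicts the positive-class
probability of the held-out fold. Only these out-of-fold predictions are
stacked, column per base learner, into the meta-feature matrix the meta
learner is trained on — the meta learner never sees a probability produced
by a model that was trained on that sample, which is what keeps it from
simply rewarding the most overfitted base learner. Probabilities (not hard
labels) are stacked. The meta learner is an elastic-net logistic regression
tuned by exhaustive grid search over (penalty strength, l1-ratio) with
stratified k-fold cross-validation and average precision as the selection
metric; a random-forest meta learner and a soft-vote baseline are available
for comparison. For test-time prediction every base learner is refit on the
full preprocessed training set and the fitted meta model is applied to
their probability outputs.

Usage follows the model/results convention::

    model = StackedGeneralization(train_ds, StackingConfig(seed=7))
    res = model.fit()
    print(res.summary())
    p = res.predict_proba(test_ds)
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .dataset import CLINICAL_VIEW, MICROBIAL_VIEW, MultiViewDataset
from .learners import (
    BaseLearnerSpec,
    default_suite,
    encode_clinical,
    make_estimator,
    positive_proba,
)
from .preprocess import (
    ClassWeights,
    FilterState,
    compute_class_weights,
    fit_view_filter,
)

META_LEARNERS = ("elasticnet", "random-forest")


def derive_seed(seed: int, *tags) -> int:
    """Deterministically fan one pipeline seed out to sub-components."""
    digest = hashlib.blake2b(repr((seed,) + tags).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclasses.dataclass
class StackingConfig:
    """Everything that parameterizes one stacked fit.

    ``alpha``/``correction`` control the ANOVA pre-filter of the microbial
    view; ``k`` the stratified fold count for both the out-of-fold stage and
    the meta grid search; the elastic-net grid spans penalty strengths
    ``Cs`` x mixing ratios ``l1_ratios``.
    """

    seed: int = 0
    k: int = 5
    alpha: float = 0.05
    correction: str = "fdr_bh"
    filter_microbial: bool = True
    meta_learner: str = "elasticnet"
    Cs: Sequence[float] = tuple(np.logspace(-3, 3, 7))
    l1_ratios: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)
    scoring: str = "average_precision"
    specs: Sequence[BaseLearnerSpec] | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.meta_learner not in META_LEARNERS:
            raise ValueError(f"meta_learner must be one of {META_LEARNERS}")
        if not self.Cs or not self.l1_ratios:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclasses.dataclass
class MetaFeatureMatrix:
    """n_train x m out-of-fold positive-class probabilities.

    Entry (i, j) comes from a model of spec j trained on the folds that
    exclude sample i's fold; per-fold models are discarded once their
    out-of-fold column segment is produced.
    """

    values: pd.DataFrame  # index = sample ids, columns = learner names
    fold_of_sample: pd.Series  # 1..k

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("meta-feature matrix contains missing entries")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("meta-features must be probabilities in [0, 1]")

    @property
    def column_names(self) -> list[str]:
        return self.values.columns.tolist()


class StackingError(RuntimeError):
    """Stage-tagged failure inside the stacking pipeline."""


# ---------------------------------------------------------------------------
# design-matrix preparation


def _design_matrices(
    ds: MultiViewDataset,
    filter_state: FilterState | None,
    clinical_categories: dict[str, list] | None,
):
    """Per-view numeric design matrices after fitted preprocessing.

    Returns ``views[name] = (X, categorical_mask)`` plus the clinical
    category levels actually used (fitted here when none were passed).
    """
    out = {}
    fitted_categories = clinical_categories
    if MICROBIAL_VIEW in ds.views:
        micro = ds.views[MICROBIAL_VIEW]
        X = filter_state.transform(micro) if filter_state is not None else micro
        out[MICROBIAL_VIEW] = (X.to_numpy(dtype=float), None)
    if CLINICAL_VIEW in ds.views:
        X, mask, cats = encode_clinical(ds.views[CLINICAL_VIEW], clinical_categories)
        if fitted_categories is None:
            fitted_categories = cats
        out[CLINICAL_VIEW] = (X, mask)
    return out, fitted_categories


def _fit_one(spec: BaseLearnerSpec, X, y, class_weights, cat_mask, seed_tag):
    est = make_estimator(
        dataclasses.replace(spec, seed=derive_seed(spec.seed, spec.name, *seed_tag)),
        class_weights=class_weights,
        categorical_features=cat_mask if spec.supports_categorical else None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message="Variables are collinear")
        est.fit(X, y)
    return est


# ---------------------------------------------------------------------------
# out-of-fold meta features


def stratified_fold_assignment(labels, k: int, seed: int) -> np.ndarray:
    """Fold index (1..k) per sample under stratified shuffled k-fold."""
    y = np.asarray(labels)
    if min(np.bincount(y)) < k:
        raise StackingError(f"k={k} exceeds the minority class count")
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        folds[val_idx] = f
    return folds


def build_meta_features(
    train: MultiViewDataset,
    specs: Sequence[BaseLearnerSpec],
    k: int = 5,
    seed: int = 0,
    filter_state: FilterState | None = None,
    class_weights: ClassWeights | None = None,
    clinical_categories: dict[str, list] | None = None,
    folds: np.ndarray | None = None,
) -> MetaFeatureMatrix:
    """Out-of-fold probability matrix over stratified folds.

    ``folds`` may pin an explicit fold assignment (1..k per sample);
    otherwise stratified shuffled folds are drawn from ``seed``. Fitted
    preprocessing (``filter_state``) is applied to every view before any
    base learner sees it; when omitted the microbial filter is fit here on
    the full training view. Deterministic for a fixed seed.
    """
    y = train.labels.to_numpy()
    if filter_state is None and MICROBIAL_VIEW in train.views:
        filter_state = fit_view_filter(train.views[MICROBIAL_VIEW], y)
    if class_weights is None:
        class_weights = compute_class_weights(y)
    views, clinical_categories = _design_matrices(train, filter_state, clinical_categories)
    for spec in specs:
        if spec.view not in views:
            raise StackingError(f"spec {spec.name!r} assigned to unknown view {spec.view!r}")

    if folds is None:
        folds = stratified_fold_assignment(y, k, derive_seed(seed, "folds"))
    folds = np.asarray(folds)
    oof = pd.DataFrame(
        np.nan, index=train.sample_ids, columns=[s.name for s in specs], dtype=float
    )
    for f in np.unique(folds):
        fit_idx = folds != f
        val_idx = ~fit_idx
        for spec in specs:
            X, cat_mask = views[spec.view]
            try:
                model = _fit_one(
                    spec, X[fit_idx], y[fit_idx], class_weights, cat_mask, ("fold", int(f))
                )
                oof.loc[val_idx, spec.name] = positive_proba(model, X[val_idx])
            except Exception as exc:  # noqa: BLE001 - re-tagged with context
                raise StackingError(
                    f"base learner {spec.name!r} failed on fold {f}: {exc}"
                ) from exc
    return MetaFeatureMatrix(
        values=oof, fold_of_sample=pd.Series(folds, index=train.sample_ids)
    )


# ---------------------------------------------------------------------------
# meta learner


@dataclasses.dataclass
class MetaLearner:
    """Fitted meta model plus the grid point the search selected."""

    model: object
    kind: str
    chosen_params: dict
    cv_score: float

    @property
    def is_linear(self) -> bool:
        return self.kind == "elasticnet"

    @property
    def coef_(self) -> np.ndarray:
        if not self.is_linear:
            raise AttributeError("non-linear meta learner has no coefficient vector")
        return np.ravel(self.model.coef_)

    @property
    def intercept_(self) -> float:
        return float(np.ravel(self.model.intercept_)[0])


def fit_meta_learner(
    meta: MetaFeatureMatrix | pd.DataFrame | np.ndarray,
    labels,
    Cs: Sequence[float] = tuple(np.logspace(-3, 3, 7)),
    l1_ratios: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    k: int = 5,
    scoring: str = "average_precision",
    seed: int = 0,
    kind: str = "elasticnet",
) -> MetaLearner:
    """Grid-searched elastic-net logistic regression on the meta features.

    The (C, l1_ratio) point maximizing mean cross-validated ``scoring`` is
    refit on all meta rows. ``kind='random-forest'`` swaps in a seeded
    random forest with its ecosystem defaults instead (no grid).
    """
    X = meta.values.to_numpy() if isinstance(meta, MetaFeatureMatrix) else np.asarray(meta)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise StackingError("degenerate labels for meta learner")
    if not np.isfinite(X).all():
        raise StackingError("non-finite meta-features")

    if kind == "random-forest":
        rf = RandomForestClassifier(random_state=derive_seed(seed, "meta-rf"), n_jobs=1)
        rf.fit(X, y)
        return MetaLearner(model=rf, kind=kind, chosen_params={}, cv_score=float("nan"))
    if kind != "elasticnet":
        raise ValueError(f"unknown meta learner kind {kind!r}")

    base = LogisticRegression(
        solver="saga",
        max_iter=10000,
        random_state=derive_seed(seed, "meta-lr"),
    )
    # a float l1_ratio selects the elastic-net penalty family
    grid = {"C": [float(c) for c in Cs], "l1_ratio": [float(r) for r in l1_ratios]}
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, "meta-cv"))
    search = GridSearchCV(base, grid, scoring=scoring, cv=cv, n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(X, y)
    return MetaLearner(
        model=search.best_estimator_,
        kind=kind,
        chosen_params=dict(search.best_params_),
        cv_score=float(search.best_score_),
    )


# ---------------------------------------------------------------------------
# soft vote


def soft_vote(base_probs: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Soft-voting baseline over base-learner probabilities.

    The score is the column mean of the positive-class probabilities; the
    label is the argmax of the summed class probabilities, i.e. 1 iff the
    mean exceeds 0.5, with ties resolved to the negative class.
    """
    P = np.asarray(base_probs, dtype=float)
    if P.ndim != 2 or P.shape[1] == 0 or P.shape[0] == 0:
        raise ValueError("base probability matrix must be non-empty 2-D")
    if (P < 0).any() or (P > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    scores = P.mean(axis=1)
    labels = (scores > 0.5).astype(int)
    return labels, scores


# ---------------------------------------------------------------------------
# model / results


class StackedGeneralization:
    """Multi-view stacked-generalization model over a training dataset.

    ``fit()`` orchestrates: microbial-view filter fit -> out-of-fold
    meta-feature construction -> meta-learner grid search -> refit of every
    base learner on the full preprocessed training set, and returns a
    :class:`StackedResults`.
    """

    def __init__(self, train: MultiViewDataset, config: StackingConfig | None = None):
        self.train = train
        self.config = config or StackingConfig()

    @classmethod
    def from_frames(
        cls,
        clinical: pd.DataFrame,
        microbial: pd.DataFrame,
        labels: pd.Series,
        config: StackingConfig | None = None,
        feature_meta=None,
    ) -> "StackedGeneralization":
        """Build from aligned DataFrames (index = sample id) and labels."""
        from .dataset import FeatureMeta

        if feature_meta is None:
            feature_meta = {}
            for c in clinical.columns:
                kind = (
                    "categorical"
                    if isinstance(clinical[c].dtype, pd.CategoricalDtype)
                    or clinical[c].dtype == object
                    else "numeric"
                )
                feature_meta[c] = FeatureMeta(CLINICAL_VIEW, kind, True)
            for c in microbial.columns:
                feature_meta[c] = FeatureMeta(MICROBIAL_VIEW, "numeric", False)
        ds = MultiViewDataset(
            views={CLINICAL_VIEW: clinical, MICROBIAL_VIEW: microbial},
            labels=labels.astype("int8"),
            feature_meta=feature_meta,
        )
        return cls(ds, config)

    def fit(self) -> "StackedResults":
        cfg = self.config
        train = self.train
        y = train.labels.to_numpy()
        try:
            filter_state = None
            if cfg.filter_microbial and MICROBIAL_VIEW in train.views:
                filter_state = fit_view_filter(
                    train.views[MICROBIAL_VIEW], y, alpha=cfg.alpha, correction=cfg.correction
                )
        except Exception as exc:
            raise StackingError(f"preprocessing stage failed: {exc}") from exc

        class_weights = compute_class_weights(y)
        specs = list(cfg.specs) if cfg.specs is not None else default_suite(
            train.view_names, seed=cfg.seed
        )

        meta_features = build_meta_features(
            train,
            specs,
            k=cfg.k,
            seed=cfg.seed,
            filter_state=filter_state,
            class_weights=class_weights,
        )
        try:
            meta = fit_meta_learner(
                meta_features,
                y,
                Cs=cfg.Cs,
                l1_ratios=cfg.l1_ratios,
                k=cfg.k,
                scoring=cfg.scoring,
                seed=cfg.seed,
                kind=cfg.meta_learner,
            )
        except StackingError:
            raise
        except Exception as exc:
            raise StackingError(f"meta-learner stage failed: {exc}") from exc

        views, clinical_categories = _design_matrices(train, filter_state, None)
        fitted_bases = {}
        for spec in specs:
            X, cat_mask = views[spec.view]
            try:
                fitted_bases[spec.name] = _fit_one(
                    spec, X, y, class_weights, cat_mask, ("refit",)
                )
            except Exception as exc:
                raise StackingError(f"refit of {spec.name!r} failed: {exc}") from exc

        return StackedResults(
            config=cfg,
            specs=specs,
            filter_state=filter_state,
            class_weights=class_weights,
            clinical_categories=clinical_categories,
            meta_features=meta_features,
            meta=meta,
            fitted_bases=fitted_bases,
            train_sample_ids=train.sample_ids.tolist(),
        )


@dataclasses.dataclass
class StackedResults:
    """Fitted stacked model: preprocessing state, refit bases, meta model."""

    config: StackingConfig
    specs: list[BaseLearnerSpec]
    filter_state: FilterState | None
    class_weights: ClassWeights
    clinical_categories: dict[str, list] | None
    meta_features: MetaFeatureMatrix
    meta: MetaLearner
    fitted_bases: dict[str, object]
    train_sample_ids: list

    @property
    def base_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def base_probabilities(self, ds: MultiViewDataset) -> pd.DataFrame:
        """n x m positive-class probabilities from the refit base learners."""
        views, _ = _design_matrices(ds, self.filter_state, self.clinical_categories)
        cols = {}
        for spec in self.specs:
            X, _ = views[spec.view]
            cols[spec.name] = positive_proba(self.fitted_bases[spec.name], X)
        return pd.DataFrame(cols, index=ds.sample_ids)

    def predict_proba(self, ds: MultiViewDataset) -> np.ndarray:
        """End-to-end positive-class probability per sample."""
        P = self.base_probabilities(ds).to_numpy()
        proba = self.meta.model.predict_proba(P)
        classes = list(self.meta.model.classes_)
        return proba[:, classes.index(1)]

    def predict(self, ds: MultiViewDataset, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(ds) >= threshold).astype(int)

    def soft_vote(self, ds: MultiViewDataset) -> tuple[np.ndarray, np.ndarray]:
        """Soft-vote baseline labels and scores from the refit bases."""
        return soft_vote(self.base_probabilities(ds))

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        cfg = self.config
        lines = [
            "Multi-view stacked generalization",
            "=" * 46,
            f"training samples     {len(self.train_sample_ids)}",
            f"base learners        {len(self.specs)}",
            f"folds (k)            {cfg.k}",
            f"meta learner         {cfg.meta_learner}",
        ]
        if self.filter_state is not None:
            lines.append(
                f"microbial filter     {len(self.filter_state.kept_features)} of "
                f"{len(self.filter_state.input_features)} features kept "
                f"(alpha={self.filter_state.alpha}, {self.filter_state.correction})"
            )
        if self.meta.chosen_params:
            lines.append(f"chosen grid point    {self.meta.chosen_params}")
            lines.append(f"CV {cfg.scoring:<18}{self.meta.cv_score:.3f}")
        lines.append("-" * 46)
        if self.meta.is_linear:
            w = self.meta.coef_
            denom = np.max(np.abs(w)) or 1.0
            lines.append(f"{'base learner':<14}{'view':<11}{'weight':>9}{'norm.':>9}")
            order = np.argsort(-w / denom)
            for i in order:
                s = self.specs[i]
                lines.append(f"{s.name:<14}{s.view:<11}{w[i]:>9.4f}{w[i] / denom:>9.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def fit_stacked(train: MultiViewDataset, config: StackingConfig | None = None) -> StackedResults:
    """Fit the full stacked pipeline on a training dataset."""
    return StackedGeneralization(train, config).fit()


def predict_proba(model: StackedResults, ds: MultiViewDataset) -> np.ndarray:
    """Positive-class probabilities of a fitted stacked model on ``ds``."""
    return model.predict_proba(ds)
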