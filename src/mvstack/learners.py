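"""Base-learner suite: per-view classifier specs and estimator factory.

The default suite mirrors a deliberately heterogeneous set of model
families — linear (SGD with logistic and modified-Huber losses), instance
based (KNN), neural (MLP), generative (QDA) and tree ensembles (RF, HGBC).
Histogram gradient boosting is the only family that natively handles
missing values and categorical features, so it is the one assigned to the
clinical view (HGBC_clin) in addition to its microbial instance (HGBC_otu);
every other family runs on the filtered microbial view only.

Base learners run with their ecosystem defaults — no per-base tuning — and
every stochastic family is seeded from the pipeline seed. Families that
support per-class weights receive the data-space balanced weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .dataset import CLINICAL_VIEW, MICROBIAL_VIEW
from .preprocess import ClassWeights

FAMILIES = (
    "sgd-logistic",
    "sgd-modified-huber",
    "k-nearest-neighbours",
    "multilayer-perceptron",
    "quadratic-discriminant",
    "random-forest",
    "histogram-gradient-boosting",
    "dummy-prior",  # uninformative reference model, used in null checks
)


@dataclasses.dataclass(frozen=True)
class BaseLearnerSpec:
    """One base model: family, assigned view and capability flags."""

    name: str
    family: str
    view: str
    supports_missing: bool = False
    supports_categorical: bool = False
    use_class_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def default_suite(views, seed: int = 0) -> list[BaseLearnerSpec]:
    """The stock 7-or-8 learner suite over the microbial (+clinical) views."""
    views = list(views)
    known = {MICROBIAL_VIEW, CLINICAL_VIEW}
    unknown = set(views) - known
    if unknown:
        raise ValueError(f"unknown view name(s) {sorted(unknown)}; expected {sorted(known)}")
    if MICROBIAL_VIEW not in views:
        raise ValueError("default suite requires the microbial view")

    def spec(name, family, view, **kw):
        return BaseLearnerSpec(name=name, family=family, view=view, seed=seed, **kw)

    suite = [
        spec("SGD_LL", "sgd-logistic", MICROBIAL_VIEW, use_class_weights=True),
        spec("SGD_HL", "sgd-modified-huber", MICROBIAL_VIEW, use_class_weights=True),
        spec("KNN", "k-nearest-neighbours", MICROBIAL_VIEW),
        spec("MLP", "multilayer-perceptron", MICROBIAL_VIEW),
        spec("QDA", "quadratic-discriminant", MICROBIAL_VIEW),
        spec("RF", "random-forest", MICROBIAL_VIEW, use_class_weights=True),
        spec(
            "HGBC_otu",
            "histogram-gradient-boosting",
            MICROBIAL_VIEW,
            supports_missing=True,
            use_class_weights=True,
        ),
    ]
    if CLINICAL_VIEW in views:
        suite.append(
            spec(
                "HGBC_clin",
                "histogram-gradient-boosting",
                CLINICAL_VIEW,
                supports_missing=True,
                supports_categorical=True,
                use_class_weights=True,
            )
        )
    return suite


def make_estimator(
    spec: BaseLearnerSpec,
    class_weights: ClassWeights | None = None,
    categorical_features=None,
):
    """Instantiate the scikit-learn estimator for a spec.

    ``categorical_features`` (boolean mask or column list) is honoured only
    by the histogram-gradient-boosting family.
    """
    cw = class_weights.as_dict() if (class_weights and spec.use_class_weights) else None
    fam = spec.family
    if fam == "sgd-logistic":
        return SGDClassifier(loss="log_loss", class_weight=cw, random_state=spec.seed)
    if fam == "sgd-modified-huber":
        # modified-Huber decision values are mapped to [0, 1] probabilities
        # by clipping to [-1, 1] (sklearn's built-in predict_proba mapping)
        return SGDClassifier(loss="modified_huber", class_weight=cw, random_state=spec.seed)
    if fam == "k-nearest-neighbours":
        return KNeighborsClassifier()
    if fam == "multilayer-perceptron":
        return MLPClassifier(random_state=spec.seed)
    if fam == "quadratic-discriminant":
        # small covariance shrinkage: per-class covariances are singular
        # whenever kept features outnumber a fold's minority class
        return QuadraticDiscriminantAnalysis(reg_param=0.1)
    if fam == "random-forest":
        return RandomForestClassifier(class_weight=cw, random_state=spec.seed, n_jobs=1)
    if fam == "histogram-gradient-boosting":
        return HistGradientBoostingClassifier(
            class_weight=cw,
            random_state=spec.seed,
            categorical_features=categorical_features,
        )
    if fam == "dummy-prior":
        return DummyClassifier(strategy="prior")
    raise ValueError(f"unknown model family {fam!r}")  # pragma: no cover


def positive_proba(model, X) -> np.ndarray:
    """Positive-class probability column of a fitted binary classifier.

    Falls back to the prior of the single seen class when a degenerate fold
    contained one class only. KNN probabilities are neighbour-vote
    fractions; modified-Huber scores arrive already mapped to [0, 1].
    """
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    if 1 in classes:
        out = proba[:, classes.index(1)]
    else:
        out = np.zeros(len(proba))
    return np.clip(np.nan_to_num(out, nan=0.5), 0.0, 1.0)


def encode_clinical(frame: pd.DataFrame, categories: dict[str, list] | None = None):
    """Encode a mixed clinical table for histogram gradient boosting.

    Categorical columns become integer codes (missing/unseen level -> NaN,
    i.e. the missing category); numeric columns pass through as float.
    Returns (matrix, categorical mask, fitted category levels).
    """
    cols = []
    mask = []
    fitted: dict[str, list] = {}
    for col in frame.columns:
        s = frame[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            levels = (
                categories[col]
                if categories is not None and col in categories
                else sorted(s.dropna().astype(str).unique())
            )
            fitted[col] = list(levels)
            codes = pd.Categorical(s.astype("string").astype(object), categories=levels).codes
            vals = np.where(codes < 0, np.nan, codes).astype(float)
            mask.append(True)
        else:
            vals = s.to_numpy(dtype=float)
            mask.append(False)
        cols.append(vals)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return X, np.asarray(mask, dtype=bool), fitted
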