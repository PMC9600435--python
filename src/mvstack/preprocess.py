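"""Training-time feature filtering for the microbial view.

The microbial (OTU) abundance table is huge, sparse and heavily skewed, so
before any base learner sees it it is, in order:

1. stripped of zero-variance (constant) columns,
2. power-transformed (Yeo-Johnson, which tolerates the zeros that dominate
   abundance tables) and standardized to zero mean / unit variance,
3. filtered by a one-way ANOVA F-test between the two label groups with a
   multiple-testing correction (Benjamini-Hochberg FDR by default), keeping
   features whose adjusted p-value is at most ``alpha``.

All state is estimated on training rows only; applying the fitted state to
new data never consults labels. The clinical view passes through untouched.

Class imbalance is handled by data-space weighting rather than resampling:
:func:`compute_class_weights` returns the balanced weights ``n / (K * n_c)``
that are passed to every base learner supporting per-class weights.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.preprocessing import PowerTransformer
from statsmodels.stats.multitest import multipletests

#: multiple-testing corrections accepted by :func:`anova_filter`
CORRECTIONS = {"fdr_bh", "bonferroni", "none"}


class PreprocessError(ValueError):
    """Raised on contract violations in the filtering pipeline."""


def remove_zero_variance(view: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Drop constant columns; return (filtered table, keep-mask).

    A column is kept iff it has at least two distinct values. Column order
    is preserved. Raises if nothing survives.
    """
    if view.isna().any().any():
        raise PreprocessError("zero-variance filter expects a complete numeric view")
    nunique = view.nunique(axis=0)
    mask = nunique >= 2
    if not mask.any():
        raise PreprocessError("empty view after filtering: all columns constant")
    return view.loc[:, mask], mask


def fit_power_transform(view: pd.DataFrame) -> PowerTransformer:
    """Fit a per-column Yeo-Johnson transform with post-standardization.

    Fitted on training rows only; each transformed training column then has
    sample mean ~ 0 and unit sample variance. Constant columns must have
    been removed first.
    """
    if (view.nunique(axis=0) < 2).any():
        raise PreprocessError("constant column passed to power transform")
    pt = PowerTransformer(method="yeo-johnson", standardize=True)
    pt.fit(view.to_numpy(dtype=float))
    return pt


def apply_power_transform(view: pd.DataFrame, params: PowerTransformer) -> pd.DataFrame:
    """Apply fitted transform parameters; deterministic, label-free."""
    out = params.transform(view.to_numpy(dtype=float))
    return pd.DataFrame(out, index=view.index, columns=view.columns)


@dataclasses.dataclass
class FilterState:
    """Fitted preprocessing state for one numeric view.

    Holds the zero-variance mask, the fitted power-transform parameters and
    the per-feature ANOVA table (F, raw p, adjusted p, kept flag). Only
    ``kept_features`` reach the base learners.
    """

    input_features: list[str]
    variance_mask: pd.Series
    transform_params: PowerTransformer | None
    anova_stats: pd.DataFrame  # index = non-constant features; F, p, p_adj, kept
    alpha: float
    correction: str

    @property
    def kept_features(self) -> list[str]:
        return self.anova_stats.index[self.anova_stats["kept"]].tolist()

    def transform(self, view: pd.DataFrame) -> pd.DataFrame:
        """Filter + transform new rows using training-time state only."""
        missing = [c for c in self.input_features if c not in view.columns]
        if missing:
            raise PreprocessError(f"view lacks fitted feature columns: {missing[:5]}")
        sub = view[self.variance_mask.index[self.variance_mask]]
        if self.transform_params is not None:
            sub = apply_power_transform(sub, self.transform_params)
        return sub[self.kept_features]

    def to_json(self, path: str | Path | None = None) -> str:
        """Audit-friendly JSON: feature -> F, p, adjusted p, kept flag."""
        payload = {
            "alpha": self.alpha,
            "correction": self.correction,
            "n_input_features": len(self.input_features),
            "n_kept": len(self.kept_features),
            "features": {
                name: {
                    "F": _jsonable(row["F"]),
                    "p": _jsonable(row["p"]),
                    "p_adj": _jsonable(row["p_adj"]),
                    "kept": bool(row["kept"]),
                }
                for name, row in self.anova_stats.iterrows()
            },
            "dropped_zero_variance": self.variance_mask.index[
                ~self.variance_mask
            ].tolist(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)


def anova_filter(
    view: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> FilterState:
    """One-way ANOVA F-test per feature with multiple-testing correction.

    Features whose *adjusted* p-value is at most ``alpha`` are kept. A
    feature identical across both groups has no between-group variance and
    is assigned F = 0, p = 1 (hence always filtered out at any usual alpha).
    ``method='none'`` with ``alpha=1`` keeps every non-constant feature.
    """
    if not 0 < alpha <= 1:
        raise PreprocessError("alpha must be in (0, 1]")
    if method not in CORRECTIONS:
        raise PreprocessError(f"unknown correction {method!r}; use one of {sorted(CORRECTIONS)}")
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise PreprocessError("both classes must have >= 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = f_classif(view.to_numpy(dtype=float), y)
    # no between-group variance (or constant feature) -> uninformative
    F = np.where(np.isfinite(F), F, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)

    if method == "none":
        p_adj = p.copy()
    else:
        p_adj = multipletests(p, alpha=alpha, method=method)[1]
    stats = pd.DataFrame(
        {"F": F, "p": p, "p_adj": p_adj, "kept": p_adj <= alpha},
        index=view.columns,
    )
    return FilterState(
        input_features=view.columns.tolist(),
        variance_mask=pd.Series(True, index=view.columns),
        transform_params=None,
        anova_stats=stats,
        alpha=alpha,
        correction=method,
    )


def fit_view_filter(
    view: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> FilterState:
    """Full training-time pipeline for one numeric view.

    zero-variance removal -> Yeo-Johnson + standardize -> ANOVA filter.
    Returns a :class:`FilterState` whose :meth:`~FilterState.transform`
    reproduces the identical mapping on any new rows.
    """
    nonconst, mask = remove_zero_variance(view)
    pt = fit_power_transform(nonconst)
    transformed = apply_power_transform(nonconst, pt)
    state = anova_filter(transformed, labels, alpha=alpha, method=correction)
    if not state.anova_stats["kept"].any():
        # nothing significant (e.g. a signal-free cohort): the filter's job
        # is dimensionality reduction, not deciding whether to model at
        # all, so fall back to plain variable ranking by raw p-value
        n_fallback = min(10, len(state.anova_stats))
        warnings.warn(
            f"no feature passed the ANOVA filter at alpha={alpha} ({correction}); "
            f"falling back to the {n_fallback} smallest raw p-values",
            stacklevel=2,
        )
        top = state.anova_stats["p"].nsmallest(n_fallback).index
        state.anova_stats.loc[top, "kept"] = True
    state.input_features = view.columns.tolist()
    state.variance_mask = mask
    state.transform_params = pt
    return state


@dataclasses.dataclass
class ClassWeights:
    """Balanced data-space class weights ``w_c = n / (2 * n_c)``.

    The rarer class receives the larger weight, biasing training toward the
    costly minority class without resampling.
    """

    weight_per_class: dict[int, float]

    def as_dict(self) -> dict[int, float]:
        return dict(self.weight_per_class)


def compute_class_weights(labels: pd.Series | np.ndarray) -> ClassWeights:
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if len(counts) != 2:
        raise PreprocessError("class weights need both classes present")
    n = len(y)
    weights = {int(c): n / (2.0 * int(counts[c])) for c in (0, 1)}
    return ClassWeights(weight_per_class=weights)
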