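"""Multi-view dataset container, delimited-text I/O and the train/test split.

A *view* is a named block of features measured on the same samples: here a
small mixed-type clinical table and a large non-negative microbial (OTU)
abundance table. Views are stored as pandas DataFrames indexed by sample id
and kept row-aligned at all times; labels are a binary {0, 1} vector with the
positive class mapped from a user-supplied label value.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

CLINICAL_VIEW = "clinical"
MICROBIAL_VIEW = "microbial"

#: file values accepted as a missing entry (next to an empty field)
_NA_VALUES = ["", "NA"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural contract."""


@dataclasses.dataclass
class FeatureMeta:
    """Per-feature record: owning view, value kind and missingness policy."""

    view: str
    kind: str  # "numeric" | "categorical"
    allow_missing: bool = False


@dataclasses.dataclass
class MultiViewDataset:
    """Sample-aligned named feature views plus binary labels.

    Parameters
    ----------
    views
        Mapping view-name -> DataFrame (rows = samples, columns = features).
        All views must share an identical index (same order).
    labels
        Binary pandas Series indexed like the views; 1 = positive class.
    feature_meta
        Mapping feature-name -> :class:`FeatureMeta`. Every column of every
        view must be present and belong to exactly one view.
    """

    views: dict[str, pd.DataFrame]
    labels: pd.Series
    feature_meta: dict[str, FeatureMeta]

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if not self.views:
            raise DatasetError("dataset needs at least one view")
        ids = self.sample_ids
        if ids.has_duplicates:
            raise DatasetError("duplicate sample ids")
        for name, frame in self.views.items():
            if not frame.index.equals(ids):
                raise DatasetError(f"view {name!r} rows misaligned with sample ids")
        if not self.labels.index.equals(ids):
            raise DatasetError("labels misaligned with sample ids")
        values = set(pd.unique(self.labels))
        if not values <= {0, 1}:
            raise DatasetError(f"labels must be binary 0/1, got {sorted(values)}")
        if len(values) < 2:
            # a tiny held-out subset can be single-class; fitting and
            # metric operations on it will raise their own errors
            warnings.warn("dataset contains a single label class", stacklevel=2)
        seen: dict[str, str] = {}
        for name, frame in self.views.items():
            for col in frame.columns:
                if col in seen:
                    raise DatasetError(
                        f"feature {col!r} occurs in views {seen[col]!r} and {name!r}"
                    )
                seen[col] = name
                meta = self.feature_meta.get(col)
                if meta is None:
                    raise DatasetError(f"feature {col!r} has no metadata")
                if meta.view != name:
                    raise DatasetError(f"feature {col!r} metadata names wrong view")
                if not meta.allow_missing and frame[col].isna().any():
                    raise DatasetError(
                        f"feature {col!r} contains missing values but allow_missing is off"
                    )
        micro = self.views.get(MICROBIAL_VIEW)
        if micro is not None:
            arr = micro.to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                raise DatasetError("microbial view must be finite")
            if (arr < 0).any():
                raise DatasetError("microbial abundances must be non-negative")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return next(iter(self.views.values())).index

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def view_names(self) -> list[str]:
        return list(self.views)

    def subset(self, ids) -> "MultiViewDataset":
        """Row-subset every view and the labels to ``ids`` (order kept)."""
        return MultiViewDataset(
            views={k: v.loc[ids] for k, v in self.views.items()},
            labels=self.labels.loc[ids],
            feature_meta=dict(self.feature_meta),
        )

    def drop_features(self, names) -> "MultiViewDataset":
        """Remove named features everywhere (leakage-guard exclusion list)."""
        names = set(names)
        return MultiViewDataset(
            views={
                k: v.drop(columns=[c for c in v.columns if c in names])
                for k, v in self.views.items()
            },
            labels=self.labels,
            feature_meta={k: m for k, m in self.feature_meta.items() if k not in names},
        )

    # -- I/O --------------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write one delimited table per view plus a labels table.

        Missing entries are written as empty fields; loading the directory
        back with :func:`read_dataset_dir` round-trips values, column order
        and the missingness pattern exactly.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in self.views.items():
            p = out / f"{name}.csv"
            frame.to_csv(p, index_label="sample_id")
            paths[name] = p
        p = out / "labels.csv"
        self.labels.rename("label").to_csv(p, index_label="sample_id")
        paths["labels"] = p
        # sidecar schema so the directory is self-describing on re-load
        schema = {
            name: {"view": m.view, "kind": m.kind, "allow_missing": m.allow_missing}
            for name, m in self.feature_meta.items()
        }
        p = out / "schema.json"
        p.write_text(json.dumps(schema, indent=1, sort_keys=True))
        paths["schema"] = p
        return paths


def _read_table(path: str | Path, id_column: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    id_col = id_column if id_column is not None else frame.columns[0]
    if id_col not in frame.columns:
        raise DatasetError(f"id column {id_col!r} not found in {path.name}")
    if frame[id_col].duplicated().any():
        dupes = frame[id_col][frame[id_col].duplicated()].tolist()
        raise DatasetError(f"duplicate sample ids in {path.name}: {dupes[:5]}")
    return frame.set_index(id_col).rename_axis("sample_id")


def _map_labels(raw: pd.Series, positive_label) -> pd.Series:
    if raw.isna().any():
        raise DatasetError("missing label values")
    levels = pd.unique(raw)
    if len(levels) > 2:
        raise DatasetError(f"label column has {len(levels)} distinct values, expected 2")
    if len(levels) < 2:
        raise DatasetError("label column contains a single class")
    if positive_label not in set(levels):
        raise DatasetError(f"positive label {positive_label!r} absent from label column")
    return (raw == positive_label).astype("int8")


def load_multiview(
    clinical_table: str | Path,
    microbial_table: str | Path,
    label_column: str,
    positive_label,
    schema: Mapping[str, Mapping] | None = None,
    id_column: str | None = None,
    labels_table: str | Path | None = None,
) -> MultiViewDataset:
    """Load a two-view dataset from delimited text tables.

    Samples are joined on the shared identifier column (inner join); rows
    present in only one table are dropped. The label column must live in
    exactly one of the two view tables — or in a dedicated ``labels_table``
    — and is mapped to {0, 1} with ``positive_label`` -> 1. No imputation
    is performed: missing entries (empty field or literal ``NA``) are
    preserved as missing markers.

    ``schema`` optionally declares per-clinical-feature kinds, e.g.
    ``{"sex": {"kind": "categorical"}, "age": {"allow_missing": True}}``;
    categorical features are never inferred from content. Without a schema,
    clinical columns are numeric and allow missing values.
    """
    clin = _read_table(clinical_table, id_column)
    micro = _read_table(microbial_table, id_column)

    if labels_table is not None:
        label_src = _read_table(labels_table, id_column)
        if label_column not in label_src.columns:
            raise DatasetError(f"label column {label_column!r} not in labels table")
    else:
        in_clin = label_column in clin.columns
        in_micro = label_column in micro.columns
        if in_clin == in_micro:
            raise DatasetError(
                f"label column {label_column!r} must be present in exactly one table"
            )
        label_src = clin if in_clin else micro

    shared = clin.index.intersection(micro.index)
    if labels_table is not None:
        shared = shared.intersection(label_src.index)
    if len(shared) == 0:
        raise DatasetError("no overlapping samples between the two tables")
    labels = _map_labels(label_src.loc[shared, label_column], positive_label)
    clin = clin.loc[shared].drop(columns=[label_column], errors="ignore")
    micro = micro.loc[shared].drop(columns=[label_column], errors="ignore")

    schema = dict(schema or {})
    feature_meta: dict[str, FeatureMeta] = {}
    for col in clin.columns:
        decl = dict(schema.get(col, {}))
        kind = decl.get("kind", "numeric")
        allow_missing = bool(decl.get("allow_missing", True))
        if kind == "categorical":
            clin[col] = clin[col].astype("category")
        else:
            clin[col] = pd.to_numeric(clin[col])
        feature_meta[col] = FeatureMeta(CLINICAL_VIEW, kind, allow_missing)
    micro = micro.astype(float)
    for col in micro.columns:
        feature_meta[col] = FeatureMeta(MICROBIAL_VIEW, "numeric", False)

    return MultiViewDataset(
        views={CLINICAL_VIEW: clin, MICROBIAL_VIEW: micro},
        labels=labels,
        feature_meta=feature_meta,
    )


def read_dataset_dir(
    data_dir: str | Path, schema: Mapping[str, Mapping] | None = None
) -> MultiViewDataset:
    """Load a directory written by :meth:`MultiViewDataset.write`.

    Uses the sidecar ``schema.json`` when present (explicit ``schema``
    wins); labels come from ``labels.csv``.
    """
    data_dir = Path(data_dir)
    if schema is None and (data_dir / "schema.json").exists():
        schema = json.loads((data_dir / "schema.json").read_text())
    labels = data_dir / "labels.csv"
    return load_multiview(
        data_dir / "clinical.csv",
        data_dir / "microbial.csv",
        label_column="label",
        positive_label=1,
        schema=schema,
        id_column="sample_id",
        labels_table=labels if labels.exists() else None,
    )


@dataclasses.dataclass
class SplitResult:
    """Disjoint train/test partition of a :class:`MultiViewDataset`."""

    train: MultiViewDataset
    test: MultiViewDataset
    seed: int
    test_fraction: float


def split_train_test(
    ds: MultiViewDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> SplitResult:
    """Random train/test split, stratified on the labels by default.

    The held-out fraction is rounded up to whole samples; with
    stratification the per-class test counts are within one sample of
    proportional allocation. Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if ds.n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    strat = ds.labels if stratify else None
    if stratify and ds.labels.value_counts().min() < 2:
        raise DatasetError("each class needs >= 2 samples for a stratified split")
    train_ids, test_ids = train_test_split(
        ds.sample_ids,
        test_size=test_fraction,
        random_state=seed,
        stratify=strat,
        shuffle=True,
    )
    return SplitResult(
        train=ds.subset(train_ids),
        test=ds.subset(test_ids),
        seed=seed,
        test_fraction=test_fraction,
    )
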