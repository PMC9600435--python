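"""End-to-end experiment runner.

One config drives the whole study shape: split the cohort 80/20, fit the
stacked model (with every base learner and the soft-vote baseline), score
training and test splits, summarize cross-validation, and write the two
interpretability reports plus figures. One global seed fans out
deterministically to the split, the folds, every stochastic learner and
the permutation draws, so rerunning an identical config reproduces every
numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import plots
from .dataset import MultiViewDataset, load_multiview, split_train_test
from .evaluation import cv_performance, evaluate_models, overfit_gap
from .interpretation import permutation_importance
from .simulate import cohort_presets, generate
from .stacking import StackedGeneralization, StackingConfig, derive_seed

log = logging.getLogger("mvstack")


@dataclasses.dataclass
class RunConfig:
    """Everything one experiment needs; loadable from YAML."""

    # data: either a synthetic preset name, or paths to the two view tables
    preset: str | None = "ibd-like-small"
    clinical_table: str | None = None
    microbial_table: str | None = None
    label_column: str | None = None
    positive_label: object = None
    schema: dict | None = None
    excluded_features: tuple = ()  # leakage guard, dropped before any fitting

    seed: int = 0
    test_fraction: float = 0.2
    stratify: bool = True
    k: int = 5
    alpha: float = 0.05
    correction: str = "fdr_bh"
    meta_learner: str = "elasticnet"
    n_repeats: int = 10
    run_cv: bool = True
    run_importance: bool = True
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.setdefault("preset", None)
        if "excluded_features" in raw:
            raw["excluded_features"] = tuple(raw["excluded_features"])
        return cls(**raw)

    def load_dataset(self) -> MultiViewDataset:
        if self.preset is not None:
            presets = cohort_presets()
            if self.preset not in presets:
                raise ValueError(
                    f"unknown preset {self.preset!r}; choose from {sorted(presets)}"
                )
            cfg = dataclasses.replace(presets[self.preset], seed=derive_seed(self.seed, "data"))
            ds = generate(cfg)
        else:
            if not (self.clinical_table and self.microbial_table and self.label_column):
                raise ValueError("either a preset or both view tables must be given")
            ds = load_multiview(
                self.clinical_table,
                self.microbial_table,
                label_column=self.label_column,
                positive_label=self.positive_label,
                schema=self.schema,
            )
        if self.excluded_features:
            ds = ds.drop_features(self.excluded_features)
        return ds


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and write all reports under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage=data loading dataset (preset=%s)", config.preset)
    ds = config.load_dataset()

    log.info("stage=split 80/20 split, seed=%d", config.seed)
    split = split_train_test(
        ds,
        test_fraction=config.test_fraction,
        seed=derive_seed(config.seed, "split"),
        stratify=config.stratify,
    )
    _json_dump(
        {
            "seed": config.seed,
            "test_fraction": config.test_fraction,
            "train_ids": split.train.sample_ids.tolist(),
            "test_ids": split.test.sample_ids.tolist(),
            "train_positives": int(split.train.labels.sum()),
            "test_positives": int(split.test.labels.sum()),
        },
        out / "split_manifest.json",
    )

    stack_cfg = StackingConfig(
        seed=config.seed,
        k=config.k,
        alpha=config.alpha,
        correction=config.correction,
        meta_learner=config.meta_learner,
    )
    log.info("stage=fit stacked fit (k=%d, alpha=%s)", config.k, config.alpha)
    results = StackedGeneralization(split.train, stack_cfg).fit()
    (out / "model_summary.txt").write_text(results.summary() + "\n")
    if results.filter_state is not None:
        results.filter_state.to_json(out / "filter_state.json")
    _json_dump(
        {
            "chosen_meta_params": results.meta.chosen_params,
            "cv_score": None
            if not np.isfinite(results.meta.cv_score)
            else round(results.meta.cv_score, 10),
            "class_weights": {
                str(k): round(v, 10) for k, v in results.class_weights.as_dict().items()
            },
            "base_learners": [dataclasses.asdict(s) for s in results.specs],
        },
        out / "model_manifest.json",
    )

    log.info("stage=evaluate scoring train and test splits")
    report = evaluate_models(results, split.train, split.test)
    report.to_json(out / "evaluation_report.json")
    report.ap_table().to_csv(out / "ap_table.csv")

    cv = None
    if config.run_cv:
        log.info("stage=cv %d-fold train/validation summary", config.k)
        cv = cv_performance(split.train, stack_cfg)
        cv.to_json(out / "cv_summary.json")
        overfit_gap(cv).to_csv(out / "overfit_gap.csv")

    importance = None
    if config.run_importance:
        log.info("stage=importance permutation importance (n_repeats=%d)", config.n_repeats)
        importance = permutation_importance(
            results,
            split.train,
            n_repeats=config.n_repeats,
            seed=derive_seed(config.seed, "perm"),
        )
        importance.to_json(out / "importance_report.json")

    if config.make_figures:
        log.info("stage=figures rendering report figures")
        plots.plot_pr_curves(report, "train", out / "pr_train.png")
        plots.plot_pr_curves(report, "test", out / "pr_test.png")
        plots.plot_mcc_heatmap(report, "train", out / "mcc_train.png")
        plots.plot_mcc_heatmap(report, "test", out / "mcc_test.png")
        if cv is not None:
            plots.plot_cv_boxes(cv, out / "cv_boxes.png")
        if importance is not None and importance.meta_weights is not None:
            plots.plot_meta_weights(importance, out / "meta_weights.png")
        if importance is not None:
            plots.plot_permutation_importance(importance, 10, out / "perm_importance.png")

    log.info("stage=done outputs in %s", out)
    return out
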