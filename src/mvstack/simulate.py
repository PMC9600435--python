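"""Synthetic two-view cohort generator.

Emulates the statistical structure the pipeline assumes without any
external data: a large sparse, non-negative, heavily right-skewed
microbial abundance view (zero-inflated log-normal); a small mixed-type
clinical view with numeric and categorical features and missing values
inserted completely at random; configurable class imbalance; and disjoint
planted informative feature subsets per view, so that the two views carry
complementary signal. Labels are drawn first and features conditional on
them, which keeps every planted effect auditable.

Cohort presets mirror the two study populations — a pediatric inflammatory
bowel disease cohort (535 samples, 17% positive, 6737 OTU features, 7
clinical features) and an adult colorectal cancer cohort (291 samples, 41%
positive, 5982 OTU features, 9 clinical features) — plus "-small" variants
(120 samples, 300 OTU features) sized so a full pipeline fits in seconds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import CLINICAL_VIEW, MICROBIAL_VIEW, FeatureMeta, MultiViewDataset

#: categorical levels used for clinical factors
_LEVELS = ["A", "B", "C"]


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``microbial_effect`` controls the class signal of informative microbial
    features on two coupled channels, mirroring how disease-associated taxa
    actually differ: a mean shift of the log abundance (in units of its
    standard deviation) and an equal shift of the presence log-odds (so
    carriage prevalence moves with abundance). ``clinical_effect`` is the
    standardized mean shift for informative numeric clinical features and
    the level-probability tilt for informative categorical ones.
    """

    n_samples: int = 120
    positive_fraction: float = 0.25
    n_microbial: int = 300
    n_informative_microbial: int = 20
    microbial_effect: float = 2.0
    sparsity: float = 0.7
    n_clinical_numeric: int = 2
    n_clinical_categorical: int = 5
    n_informative_clinical: int = 2
    clinical_effect: float = 1.5
    missing_rate_clinical: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("need n_samples >= 10")
        for frac in (self.positive_fraction, self.sparsity, self.missing_rate_clinical):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_informative_microbial > self.n_microbial:
            raise ValueError("informative microbial count exceeds total")
        if self.n_informative_clinical > self.n_clinical_numeric + self.n_clinical_categorical:
            raise ValueError("informative clinical count exceeds total")
        n_pos = round(self.n_samples * self.positive_fraction)
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ValueError("each class needs >= 2 samples")


def generate(config: SyntheticConfig) -> MultiViewDataset:
    """Draw one multi-view dataset; fully deterministic given the seed.

    Labels get exactly ``round(n * positive_fraction)`` positives. The
    informative clinical set fills numeric slots first, then categorical
    ones; informative microbial features alternate the sign of their
    log-scale shift so the planted signal is not a single global axis.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_pos = round(n * cfg.positive_fraction)
    y = np.zeros(n, dtype="int8")
    y[rng.choice(n, size=n_pos, replace=False)] = 1

    ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    # Microbial view: zero-inflated log-normal abundances. Informative
    # features co-vary through one latent "dysbiosis" axis z (class shift
    # of microbial_effect plus unit sample noise), as disease-associated
    # taxa shift as a community, not independently; each loads on z with
    # alternating sign in both its log abundance and its presence
    # log-odds, so carriage prevalence moves with abundance. The shared
    # axis keeps per-feature effects detectable while capping how
    # separable the view is in aggregate.
    base_mu = rng.normal(0.0, 1.0, size=cfg.n_microbial)
    loadings = np.zeros(cfg.n_microbial)
    signs = np.where(np.arange(cfg.n_informative_microbial) % 2 == 0, 1.0, -1.0)
    loadings[: cfg.n_informative_microbial] = signs
    z = cfg.microbial_effect * y + rng.normal(0.0, 1.0, size=n)
    structure = np.outer(z, loadings)
    log_x = rng.normal(base_mu[None, :] + structure, 1.0)
    abundance = np.exp(log_x)
    if cfg.sparsity >= 1:
        abundance[:] = 0.0
    elif cfg.sparsity > 0:
        base_logit_zero = np.log(cfg.sparsity / (1.0 - cfg.sparsity))
        p_zero = 1.0 / (1.0 + np.exp(-(base_logit_zero - structure)))
        abundance[rng.random((n, cfg.n_microbial)) < p_zero] = 0.0
    microbial = pd.DataFrame(
        abundance, index=ids, columns=[f"OTU_{j:05d}" for j in range(cfg.n_microbial)]
    )

    # clinical view: numeric then categorical, informative slots first
    informative_numeric = min(cfg.n_informative_clinical, cfg.n_clinical_numeric)
    informative_categorical = cfg.n_informative_clinical - informative_numeric
    clinical = {}
    feature_meta: dict[str, FeatureMeta] = {}
    for j in range(cfg.n_clinical_numeric):
        effect = cfg.clinical_effect if j < informative_numeric else 0.0
        name = f"clin_num_{j}"
        clinical[name] = rng.normal(effect * y, 1.0)
        feature_meta[name] = FeatureMeta(CLINICAL_VIEW, "numeric", True)
    for j in range(cfg.n_clinical_categorical):
        name = f"clin_cat_{j}"
        base_p = np.array([0.5, 0.3, 0.2])
        if j < informative_categorical:
            # tilt probability mass toward the last level for positives
            tilt = min(0.45, 0.15 * cfg.clinical_effect)
            pos_p = np.array([0.5 - tilt, 0.3 - tilt / 3, 0.2 + tilt + tilt / 3])
            pos_p = pos_p / pos_p.sum()
        else:
            pos_p = base_p
        draws = np.where(
            y == 1,
            rng.choice(len(_LEVELS), size=n, p=pos_p),
            rng.choice(len(_LEVELS), size=n, p=base_p),
        )
        clinical[name] = pd.Categorical.from_codes(draws, categories=_LEVELS)
        feature_meta[name] = FeatureMeta(CLINICAL_VIEW, "categorical", True)
    clinical_df = pd.DataFrame(clinical, index=ids)

    # MCAR missingness, clinical view only
    if cfg.missing_rate_clinical > 0 and len(clinical_df.columns):
        mask = rng.random(clinical_df.shape) < cfg.missing_rate_clinical
        for i_col, col in enumerate(clinical_df.columns):
            clinical_df.loc[mask[:, i_col], col] = np.nan

    for col in microbial.columns:
        feature_meta[col] = FeatureMeta(MICROBIAL_VIEW, "numeric", False)

    return MultiViewDataset(
        views={CLINICAL_VIEW: clinical_df, MICROBIAL_VIEW: microbial},
        labels=pd.Series(y, index=ids, name="label"),
        feature_meta=feature_meta,
    )


def null_config(base: SyntheticConfig | None = None, seed: int = 0) -> SyntheticConfig:
    """No-signal variant: all planted effects zero, labels pure noise."""
    base = base or SyntheticConfig()
    return dataclasses.replace(
        base, microbial_effect=0.0, clinical_effect=0.0, seed=seed
    )


def cohort_presets() -> dict[str, SyntheticConfig]:
    """Named cohort-shaped configurations.

    ``ibd-like``/``crc-like`` match the two study cohorts' sample counts,
    imbalance and view dimensionalities; the ``-small`` variants keep the
    imbalance and signal structure at desk scale (120 samples, 300 OTUs).
    """
    ibd = SyntheticConfig(
        n_samples=535,
        positive_fraction=0.17,
        n_microbial=6737,
        n_informative_microbial=40,
        microbial_effect=2.0,
        sparsity=0.7,
        n_clinical_numeric=1,
        n_clinical_categorical=6,
        n_informative_clinical=2,
        clinical_effect=1.5,
        missing_rate_clinical=0.06,  # ~223 missing cells of 535 x 7
        seed=0,
    )
    crc = SyntheticConfig(
        n_samples=291,
        positive_fraction=0.41,
        n_microbial=5982,
        n_informative_microbial=40,
        microbial_effect=2.0,
        sparsity=0.7,
        n_clinical_numeric=2,
        n_clinical_categorical=7,
        n_informative_clinical=2,
        clinical_effect=1.5,
        missing_rate_clinical=0.002,  # ~5 missing cells of 291 x 9
        seed=0,
    )
    ibd_small = dataclasses.replace(
        ibd, n_samples=120, n_microbial=300, n_informative_microbial=20
    )
    crc_small = dataclasses.replace(
        crc, n_samples=120, n_microbial=300, n_informative_microbial=20
    )
    return {
        "ibd-like": ibd,
        "crc-like": crc,
        "ibd-like-small": ibd_small,
        "crc-like-small": crc_small,
    }
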