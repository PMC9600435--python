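import dataclasses

import numpy as np
import pandas as pd
import pytest

import mvstack as mv


def make_two_view(n=24, n_micro=8, n_pos=None, seed=0, missing=False):
    """Hand-rolled tiny two-view dataset for structural tests."""
    rng = np.random.default_rng(seed)
    n_pos = n_pos if n_pos is not None else n // 3
    y = np.array([1] * n_pos + [0] * (n - n_pos), dtype="int8")
    rng.shuffle(y)
    ids = pd.Index([f"P{i:03d}" for i in range(n)], name="sample_id")
    micro = pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(n, n_micro)) + y[:, None] * rng.uniform(0, 1, n_micro),
        index=ids,
        columns=[f"OTU_{j}" for j in range(n_micro)],
    )
    clin = pd.DataFrame(
        {
            "age": rng.normal(40 + 5 * y, 8.0),
            "sex": pd.Categorical(rng.choice(["F", "M"], size=n)),
        },
        index=ids,
    )
    if missing:
        clin.iloc[0, 0] = np.nan
        clin.iloc[1, 1] = np.nan
    meta = {
        "age": mv.FeatureMeta(mv.CLINICAL_VIEW, "numeric", True),
        "sex": mv.FeatureMeta(mv.CLINICAL_VIEW, "categorical", True),
    }
    for c in micro.columns:
        meta[c] = mv.FeatureMeta(mv.MICROBIAL_VIEW, "numeric", False)
    return mv.MultiViewDataset(
        views={mv.CLINICAL_VIEW: clin, mv.MICROBIAL_VIEW: micro},
        labels=pd.Series(y, index=ids, name="label"),
        feature_meta=meta,
    )


@pytest.fixture
def tiny_ds():
    return make_two_view(n=24, seed=3, missing=True)


@pytest.fixture(scope="session")
def small_cohort():
    """One crc-shaped small synthetic cohort shared across tests."""
    cfg = dataclasses.replace(mv.cohort_presets()["crc-like-small"], seed=11)
    return mv.generate(cfg)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """One fitted stacked model on the small cohort's training split."""
    split = mv.split_train_test(small_cohort, 0.2, seed=11)
    results = mv.fit_stacked(split.train, mv.StackingConfig(seed=11))
    return split, results
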