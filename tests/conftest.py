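"""Shared fixtures: small hand-built feature matrices and simulated data."""

import numpy as np
import pandas as pd
import pytest

from debatch import FeatureMatrix, simulate


def make_fm(
    values,
    batches,
    is_qc=None,
    orders=None,
    covariates=None,
    scale_flag="log2",
    feature_names=None,
):
    """Build a FeatureMatrix from a plain array + batch labels."""
    values = np.asarray(values, float)
    n = values.shape[0]
    idx = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    cols = pd.Index(
        feature_names or [f"F{j + 1:03d}" for j in range(values.shape[1])],
        name="feature_id",
    )
    batches = pd.Series(list(batches), index=idx)
    if orders is None:
        order = np.zeros(n, int)
        for b in batches.unique():
            mask = (batches == b).to_numpy()
            order[mask] = np.arange(1, mask.sum() + 1)
        orders = order
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=idx)
    return FeatureMatrix(
        intensities=pd.DataFrame(values, index=idx, columns=cols),
        batch=batches,
        injection_order=pd.Series(orders, index=idx),
        is_qc=pd.Series(
            [False] * n if is_qc is None else list(is_qc), index=idx
        ),
        covariates=cov,
        scale_flag=scale_flag,
    )


@pytest.fixture
def toy_two_batch():
    """Single feature, batch means 2 and 12, equal within-batch spread."""
    return make_fm([[1], [2], [3], [11], [12], [13]], ["A"] * 3 + ["B"] * 3)


@pytest.fixture
def small_simulated():
    """Default generator output: 3 batches, complete, with batch effects."""
    fm, truth = simulate(seed=11)
    return fm, truth


@pytest.fixture
def random_two_batch():
    """Seeded 2-batch, 5-feature dataset with unequal batch sizes."""
    rng = np.random.default_rng(42)
    values = rng.normal(10, 1, (13, 5))
    values[:6] += rng.normal(0, 2, 5)  # batch-A offsets
    values[6:] *= 1.0
    return make_fm(values, ["A"] * 6 + ["B"] * 7)
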