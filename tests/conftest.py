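"""Shared fixtures: a small simulated dataset and its fitted design matrix."""

import pandas as pd
import pytest

from chromtx.model import FeatureTransform, make_split
from chromtx.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """600-gene synthetic dataset at the default study conditions."""
    return simulate_dataset(n=600, seed=42)


@pytest.fixture(scope="session")
def small_plan(small_dataset):
    return make_split(list(small_dataset.gene_ids), seed=7)


@pytest.fixture(scope="session")
def small_design(small_dataset, small_plan):
    """(transform, X, y) fitted on the small dataset's D1."""
    ds = small_dataset
    ft = FeatureTransform().fit(ds.binned, ds.y, small_plan.d1_ids)
    return ft, ft.transform(ds.binned), ds.y
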