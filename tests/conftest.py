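"""Shared fixtures: one small synthetic study reused across the suite."""

import numpy as np
import pandas as pd
import pytest

import prolifsig as ps


@pytest.fixture(scope="session")
def study():
    return ps.simulate_study(seed=11)


@pytest.fixture(scope="session")
def reference(study):
    return study.reference


@pytest.fixture(scope="session")
def ranks(study, reference):
    return reference.rank_samples(study.cohort_expression)


@pytest.fixture(scope="session")
def labels(study):
    return ps.classify_cohort(study.clinical)


@pytest.fixture(scope="session")
def dc_labels(labels):
    return labels[labels.isin(["DC", "NDC"])]


@pytest.fixture(scope="session")
def tiny_reference():
    """A 5-gene, 9-sample reference with distinct integer expression."""
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(1, 6)]
    vals = rng.permuted(np.arange(1, 46, dtype=float).reshape(5, 9), axis=1)
    expr = pd.DataFrame(vals, index=genes,
                        columns=[f"R{i}" for i in range(1, 10)])
    return ps.ReferencePopulation(expr)
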