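import numpy as np
import pytest

from linecross import (
    CohortSpec,
    PipelineConfig,
    build_cmatrix,
    standard_cohorts,
)


@pytest.fixture
def classic6_cohorts():
    """P1, P2, F1, F2, BC1, BC2 skeletons."""
    return standard_cohorts(["P1", "P2", "F1", "F2", "BC1", "BC2"])


@pytest.fixture
def classic6_cmatrix(classic6_cohorts):
    return build_cmatrix(classic6_cohorts, model_set="reduced")


@pytest.fixture
def toy4_dataset():
    """Four-cohort toy: P1, P2, F1, F2 with unit SEs."""
    labels = ["P1", "P2", "F1", "F2"]
    means = [10.0, 2.0, 9.0, 7.0]
    cohorts = standard_cohorts(labels)
    for c, m in zip(cohorts, means):
        c.mean = m
        c.se = 1.0
    return cohorts


@pytest.fixture
def config():
    return PipelineConfig()
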