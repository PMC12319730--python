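import numpy as np
import pytest

import pipefpr as pf


@pytest.fixture(scope="session")
def null_cohort() -> pf.Cohort:
    """Single-pipeline cohort: both groups of any draw share the pipeline."""
    spec = pf.PipelineSpec(label="spm-a")
    config = pf.CohortConfig(pipelines=(spec,), n_subjects=200, seed=123)
    return pf.generate_cohort(config)


@pytest.fixture(scope="session")
def two_style_cohort() -> pf.Cohort:
    """Small cohort with one SPM-like and one FSL-like pipeline."""
    spm = pf.PipelineSpec(label="spm-a", software_style="SPM-like")
    fsl = pf.PipelineSpec(label="fsl-a", software_style="FSL-like")
    config = pf.CohortConfig(pipelines=(spm, fsl), n_subjects=12, seed=7)
    return pf.generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
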