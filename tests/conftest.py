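import pytest
from hypothesis import settings

from xcical.config import PipelineConfig
from xcical.pipeline import run_pipeline
from xcical.simulate import CohortConfig, simulate_chip, simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 3 sets x 20 females, 200 X genes."""
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    probes, truth = default_cohort
    chip = simulate_chip(truth)
    return run_pipeline(probes, truth.annotation(), truth.subject_training,
                        truth.escape_training, chip, PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end checks."""
    cfg = CohortConfig(seed=7, n_females_per_set=8, n_x_genes=80,
                       n_autosomal_probes=800, n_subject_training=40,
                       n_escape_training=12)
    return simulate_cohort(cfg)
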