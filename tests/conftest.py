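import pytest

from clonaging.config import RunConfig
from clonaging.pipeline import run_pipeline
from clonaging.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (18 mice, 100 clones each)."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free cohort with analytic read counts (infinite-depth limit)."""
    cfg = CohortConfig(seed=1, facs_noise=0.0, exact_counts=True)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def report(cohort):
    """Full pipeline run on the default cohort."""
    counts, panel, mice, _ = cohort
    return run_pipeline(RunConfig(seed=1), counts, panel, mice)
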