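import logging

import pytest

from mobisias.pipeline import ProcessedCohort, process_bundle
from mobisias.synth import CohortConfig, GapConfig, MapConfig, NoiseConfig, generate_cohort

# profile-clamping warnings are expected in bulk cohort generation
logging.getLogger("mobisias.synth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> ProcessedCohort:
    """20 participants x 14 days, sigma=10 m, no gaps (recovery conditions)."""
    cfg = CohortConfig(
        n_participants=20, n_days=14,
        noise=NoiseConfig(jitter_sigma_m=10.0, gaps=GapConfig.none()),
    )
    return process_bundle(generate_cohort(cfg, 7))


@pytest.fixture(scope="session")
def tiny_cohort() -> ProcessedCohort:
    """6 participants x 5 days with default noise, for mechanics tests."""
    cfg = CohortConfig(n_participants=6, n_days=5, map=MapConfig(n_houses=10))
    return process_bundle(generate_cohort(cfg, 3))
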