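import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sepsiscreen.synthetic import CohortConfig, generate_cohort, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_cases=2000, exact_counts=True, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Fully documented cohort (no missingness): (cases, outcomes)."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def gappy_study():
    """Cohort with documentation gaps and contamination: (cases, outcomes, log)."""
    cfg = CohortConfig(n_cases=3000, exact_counts=True, implausible_rate=0.02, seed=21)
    return simulate_study(cfg)
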