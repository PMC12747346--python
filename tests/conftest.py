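from pathlib import Path

import numpy as np
import pytest

from dropload.cohort import CohortDesign, make_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_dir() -> Path:
    """Two-subject in-repo fixture: trial files plus subject table."""
    return DATA_DIR / "micro"


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-calibration cohort with traces, shared across tests."""
    design = CohortDesign(
        seed=11,
        group_sizes={"I": 4, "II": 4, "III": 4},
        settle_s=0.3,
    )
    return make_cohort(design)
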