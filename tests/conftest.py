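import numpy as np
import pytest

from wearlab.config import SimulationConfig
from wearlab.pipeline import make_fixtures
from wearlab.simulate import generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 participants x 10 days, minute streams rendered, missingness applied."""
    return make_fixtures("tiny", seed=20220905)


@pytest.fixture(scope="session")
def tiny_complete_cohort():
    """4 x 12 days with no missingness, no reversed sleeper, minutes rendered."""
    cfg = SimulationConfig(
        n_participants=4, n_days=12, seed=77, n_reversed_cycle=0,
        missing_rates={"survey": 0, "hrv": 0, "sleep": 0, "steps": 0},
    )
    return generate_cohort(cfg, render_minutes=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240617)
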