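import numpy as np
import pandas as pd
import pytest

from vwmstats.simulate import StudySimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_study_trials() -> pd.DataFrame:
    """A reduced study (8 + 8 participants, pre/post reproduction only)."""
    cfg = StudySimConfig(
        n_experimental=8,
        n_control=8,
        tasks=("orientation_reproduction", "change_detection"),
        include_training=False,
        include_practice=True,
        seed=11,
    )
    return simulate_study(cfg)
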