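import numpy as np
import pandas as pd
import pytest

import reliance_lab as rl


@pytest.fixture(scope="session")
def default_dataset() -> rl.StudyDataset:
    """One default-design synthetic cohort (223 participants x 24 trials)."""
    return rl.simulate_study(rl.DesignConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> rl.StudyDataset:
    """A small cohort for cheap structural checks."""
    return rl.simulate_study(rl.DesignConfig(n_participants=12, n_trials=8,
                                             n_incorrect_advice=2, seed=5))


@pytest.fixture(scope="session")
def reference_fixture() -> pd.DataFrame:
    """Trials table realising the published reliance-pattern counts (5352 cases)."""
    return rl.pattern_fixture_trials()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
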