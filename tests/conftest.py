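import numpy as np
import pandas as pd
import pytest

from covis.synth import GenParams, build_design, simulate_behavior


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    """Minimal balanced design: one repeat of each of the 20 trial types."""
    return build_design(n_per_type=1, n_blocks=1, seed=0)


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    """The full 640-trial / 4-block study design."""
    return build_design(n_per_type=32, n_blocks=4, seed=0)


@pytest.fixture()
def gp() -> GenParams:
    return GenParams(seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def medium_behavior() -> pd.DataFrame:
    """160 trials of behavior from a mid-range observer."""
    design = build_design(n_per_type=8, n_blocks=4, seed=3)
    return simulate_behavior(design, GenParams(seed=3))
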