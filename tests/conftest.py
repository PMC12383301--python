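import warnings

import numpy as np
import pytest

from stip.reference import make_profiles
from stip.simulate import SimConfig, simulate_plate


@pytest.fixture(autouse=True)
def _quiet_triplicate_warnings():
    # small constructed plates legitimately use duplicates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def reference_profiles():
    """Kinetic profiles rebuilt from the reference cohort metrics."""
    return make_profiles()


@pytest.fixture(scope="session")
def default_plate():
    """One simulated default plate (all channels), fixed seed."""
    return simulate_plate(SimConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path
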