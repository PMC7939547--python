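import numpy as np
import pytest

from cortemp import ModelParams, SynthConfig, generate_recording, median_params


@pytest.fixture(scope="session")
def medians() -> ModelParams:
    return median_params()


@pytest.fixture(scope="session")
def recording_96h():
    """One deterministic 96-h synthetic recording (hypnogram + noisy temp)."""
    return generate_recording(SynthConfig(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211)


def random_hypnogram(rng: np.random.Generator, n: int, epoch_s: float = 4.0):
    """Uniform random state sequence; used by loop-oracle tests."""
    from cortemp import Hypnogram

    states = rng.choice(np.array(["W", "N", "R"]), size=n)
    return Hypnogram(states, epoch_s=epoch_s)
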