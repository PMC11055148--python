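import numpy as np
import pytest

from fretcast.simulate import GaitSimSpec, generate_subject, split_train_test


def tiled_periodic(period: int, n: int, seed: int = 0) -> np.ndarray:
    """A signal with bit-exact integer-sample period (one cycle, tiled)."""
    rng = np.random.default_rng(seed)
    t = np.arange(period)
    one = (np.sin(2 * np.pi * t / period)
           + 0.3 * np.sin(4 * np.pi * t / period + rng.uniform(0, np.pi)))
    reps = -(-n // period)
    return np.tile(one, reps)[:n]


@pytest.fixture(scope="session")
def subject_series() -> np.ndarray:
    """One default synthetic subject (600 samples, quasi-periodic)."""
    return generate_subject(GaitSimSpec(seed=1))


@pytest.fixture(scope="session")
def train_test(subject_series):
    return split_train_test(subject_series)
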