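import numpy as np
import pytest

from akibench import SimConfig, simulate
from akibench.synthetic_ehr import generate_population


@pytest.fixture(scope="session")
def small_bundle():
    """Complete (pre-missingness) bundle, noise-free for exact labelling."""
    return generate_population(SimConfig(n_patients=250, seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Realistic bundle with default noise and missingness applied."""
    return simulate(SimConfig(n_patients=800, seed=23))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def random_series():
    """Factory for fuzzed creatinine series over days 1-7."""
    from akibench.series import MeasurementSeries

    def make(rng, n_min=5, n_max=15, span_h=168.0):
        n = int(rng.integers(n_min, n_max + 1))
        offsets = rng.uniform(0.0, span_h, n)
        values = rng.uniform(0.3, 3.0, n)
        return MeasurementSeries(offsets, values)

    return make
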