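import numpy as np
import pytest

from specrestore.dataset import SpectrumSet, WavenumberAxis
from specrestore.synthetic import SyntheticConfig, make_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_axis():
    return WavenumberAxis(np.linspace(950.0, 3700.0, 128))


@pytest.fixture
def small_config():
    """Desk-scale synthetic configuration used across the suite."""
    return SyntheticConfig(n_points=128, seed=3)


@pytest.fixture
def quiet_config():
    """No noise, no baseline, no scatter: LQ == clean exactly."""
    return SyntheticConfig(
        n_points=128,
        seed=3,
        noise_sigma0=0.0,
        baseline_scale=0.0,
        oscillation_amplitude=0.0,
        scatter_range=(1.0, 1.0),
        amplitude_jitter=0.0,
    )


@pytest.fixture
def tiny_paired(small_config):
    return make_paired_dataset(2, 8, small_config)


@pytest.fixture
def random_spectra(rng, small_axis):
    rows = rng.normal(size=(5, small_axis.n_points))
    labels = np.array(["a", "a", "b", "b", "b"])
    return SpectrumSet(axis=small_axis, intensities=rows, sample_labels=labels)
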