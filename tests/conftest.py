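import numpy as np
import pytest

from seedspec import SpectraTable, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced study design: 3 varieties x 15 seeds, 48 bands."""
    return SyntheticSpec(
        n_classes=3,
        n_per_class=15,
        n_bands=48,
        wl_start=1000.0,
        wl_end=1600.0,
        informative_centers=[[1100.0, 1250.0], [1250.0, 1400.0], [1400.0, 1520.0]],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture
def flat_table():
    """Deterministic 4-sample, 6-band table for exact-value checks."""
    values = np.array(
        [
            [0.2, 0.4, 0.6, 0.8, 1.0, 0.5],
            [2.0, 4.0, 8.0, 6.0, 2.0, 1.0],
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            [0.1, 0.3, 0.2, 0.9, 0.7, 0.4],
        ]
    )
    return SpectraTable(
        values=values,
        wavelengths=np.array([900.0, 1000.0, 1100.0, 1200.0, 1300.0, 1400.0]),
        labels=np.array([0, 1, 0, 1]),
        sample_ids=["a", "b", "c", "d"],
    )
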