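import numpy as np
import pytest

from lanchester_abc import Battle, Model, SynthConfig, generate_dataset


@pytest.fixture
def example_battle() -> Battle:
    """A canonical battle: blue 15000/3000 (ratio 0.2), red 10000/1000 (0.1)."""
    return Battle(
        id="b1", year=1705, size_blue=15_000, size_red=10_000, cas_blue=3000, cas_red=1000
    )


@pytest.fixture(scope="session")
def small_dataset():
    """30 fatigue-generated battles with known ground truth."""
    cfg = SynthConfig(true_model=Model.FATIGUE, true_mu=2.0, true_sigma=0.5, n_battles=30, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
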