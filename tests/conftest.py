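import numpy as np
import pytest

from editscape import SimulationDesign, generate_calls, generate_reference


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        n_subjects_per_dataset=50,
        n_regions=2,
        n_sites=40,
        depth_mean=100.0,
        n_datasets=2,
        n_planted_region=6,
        n_planted_ad=6,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_reference(small_design):
    return generate_reference(small_design)


@pytest.fixture(scope="session")
def small_callset(small_design, small_reference):
    return generate_calls(small_design, small_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
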