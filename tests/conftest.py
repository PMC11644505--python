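import numpy as np
import pytest

from tuberspec.synthetic_field import FieldConfig, generate_field


@pytest.fixture(scope="session")
def small_field_config() -> FieldConfig:
    """A reduced trial (2 years x 1 plot x 3 varieties x 5 plants) that keeps
    the two-year day structure but runs fast enough for orchestration tests."""
    return FieldConfig(
        plots_per_year=1,
        varieties=("Spunta", "Agria", "Rudolf"),
        plants_per_variety_per_plot=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_field(small_field_config):
    return generate_field(small_field_config)


@pytest.fixture(scope="session")
def default_field():
    """One full-size synthetic trial (360 plants) shared across tests."""
    return generate_field(FieldConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
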