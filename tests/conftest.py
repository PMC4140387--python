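import numpy as np
import pytest

from lcasim import DesignCell, ParameterSet, build_population_spec, generate_dataset


@pytest.fixture(scope="session")
def spec2_high_j4():
    """2-class, high-quality, 4-indicator population (no covariate)."""
    return build_population_spec(DesignCell(2, 500, 4, "high", "none"))


@pytest.fixture(scope="session")
def spec2_high_j8():
    return build_population_spec(DesignCell(2, 500, 8, "high", "none"))


@pytest.fixture(scope="session")
def spec3_low_j5():
    return build_population_spec(DesignCell(3, 500, 5, "low", "none"))


@pytest.fixture(scope="session")
def spec2_cov_large_j8():
    """2-class, high-quality, 8 indicators, large covariate effect (OR = 4)."""
    return build_population_spec(DesignCell(2, 500, 8, "high", "large"))


@pytest.fixture()
def small_dataset(spec2_high_j8):
    return generate_dataset(spec2_high_j8, 400, seed=123)


@pytest.fixture()
def true_start(spec2_high_j8):
    return ParameterSet.from_spec(spec2_high_j8)
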