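import numpy as np
import pytest

from slopesim import (
    DesignCondition,
    DEFAULT_BASE_PARAMS,
    resolve_params,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_condition() -> DesignCondition:
    """A cheap design used by most fitting tests."""
    return DesignCondition(
        n_waves=3, class_size=5, n_classrooms=10, prop_treatment=0.5,
        icc=0.2, effect_label="medium", condition_index=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_condition):
    params = resolve_params(small_condition, DEFAULT_BASE_PARAMS)
    rng = np.random.default_rng(20230)
    return simulate_dataset(small_condition, params, rng)
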