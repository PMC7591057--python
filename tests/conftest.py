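import math

import pytest

from metastatic_bottleneck import (
    BottleneckPrior,
    GrowthLaw,
    OutcomeParams,
    demo_params,
)


@pytest.fixture(scope="session")
def growth100() -> GrowthLaw:
    """Fast-growing tumor (100-day doubling) for kinetics tests."""
    return GrowthLaw(doubling_time_days=100.0)


@pytest.fixture(scope="session")
def growth150() -> GrowthLaw:
    return GrowthLaw(doubling_time_days=150.0)


@pytest.fixture(scope="session")
def params_lognormal() -> OutcomeParams:
    """Reference fitted-regime parameter set (log-normal frailty)."""
    return demo_params()


@pytest.fixture(scope="session")
def params_point(growth150) -> OutcomeParams:
    """Point-bottleneck variant at the most common median severity."""
    return OutcomeParams(
        delta0=6.0,
        delta1=5.5,
        a=1.0,
        h=1.0,
        prior=BottleneckPrior.point(17.0),
        growth=growth150,
    )
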