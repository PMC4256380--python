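import numpy as np
import pytest

from pcasim.parameters import ModelParameters, StepFunction, base_case
from pcasim.states import RiskGroup, Strategy


@pytest.fixture(scope="session")
def base():
    return base_case()


@pytest.fixture(scope="session")
def base_gated():
    """Base case with the low-risk metastatic pathway gated off."""
    return base_case(low_risk_mcrpc=0.0)


def make_simple_params(
    p_rec: float = 0.05,
    p_mcrpc: float = 0.07,
    p_pca: float = 0.27,
    p_od: float = 0.03,
    as_frac: float = 0.0,
    dt: float = 0.08,
    cohort_size: int = 2000,
    max_cycles: int = 45,
    horizon="lifetime",
) -> ModelParameters:
    """A single-risk-group parameter set for small controlled experiments."""
    alloc = {Strategy.RP: 1.0 - as_frac}
    if as_frac > 0:
        alloc[Strategy.AS] = as_frac
    return ModelParameters(
        cohort_size=cohort_size,
        risk_fractions={RiskGroup.LOW: 1.0},
        allocations={RiskGroup.LOW: alloc},
        recurrence={RiskGroup.LOW: {Strategy.RP: p_rec}},
        delayed_treatment=StepFunction(((1, None, dt),), "as-entry"),
        overall_death=StepFunction(((1, None, p_od),)),
        recurrence_to_mcrpc={RiskGroup.LOW: p_mcrpc},
        mcrpc_to_pca_death=p_pca,
        horizon=horizon,
        max_cycles=max_cycles,
    ).validate()


@pytest.fixture
def simple_params():
    return make_simple_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
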