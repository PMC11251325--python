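import pytest

from tndpower import DesignParams, derive

# Constant-hazard reference conditions: tau = 100 days, lambda_i = 0.001/day,
# lambda_n = 0.002/day, so Lambda_I = 0.1 and Lambda_N = 0.2; one-sided
# alpha = 0.025, target power 80%.
HAZARDS = dict(lambda_i=0.001, lambda_n=0.002, tau=100.0)


def scenario(ve: float, coverage: float, **kwargs) -> DesignParams:
    return DesignParams(ve=ve, coverage=coverage, **HAZARDS, **kwargs)


@pytest.fixture
def ve95_cov30():
    """High-effectiveness scenario: VE=95%, 30% coverage."""
    return scenario(0.95, 0.3)


@pytest.fixture
def ve95_cov10():
    """Sparse scenario: VE=95%, 10% coverage (few vaccinated positives)."""
    return scenario(0.95, 0.1)


@pytest.fixture
def derived_ve95_cov30(ve95_cov30):
    return derive(ve95_cov30)
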