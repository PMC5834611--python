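import numpy as np
import pytest

from hemeco.kinetics import DEFAULT_RATES, ThreeStateRates


@pytest.fixture
def default_rates() -> ThreeStateRates:
    """Default rates consistent with the printed k1, kCO and k_m2."""
    return DEFAULT_RATES


@pytest.fixture
def sink_rates() -> ThreeStateRates:
    """Rates with a negligible dissociation term (strict sink regime)."""
    return ThreeStateRates(k1=25.0, k_m1=5000.0, k2=54.0, k_m2=1e-5)


def seeds(n: int, base: int = 1000) -> list[int]:
    """Fixed, reproducible seed list for recovery ensembles."""
    return [base + i for i in range(n)]
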