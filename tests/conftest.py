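import numpy as np
import pytest

from cagefold.kinetics import SchemeRates

#: Published reference rate constants used throughout as generator truth.
K1_REF = 1.4e-4
K_MINUS1_REF = 7.3e-3
KA_REF = 3571.0


@pytest.fixture
def reference_rates() -> SchemeRates:
    return SchemeRates(k1=K1_REF, k_minus1=K_MINUS1_REF, Ka=KA_REF)


@pytest.fixture
def fast_binding_rates() -> SchemeRates:
    """Reference folding rates with explicit fast binding and slow turnover."""
    return SchemeRates(
        k1=K1_REF, k_minus1=K_MINUS1_REF, k2=KA_REF * 200.0, k_minus2=200.0, kcat=0.1
    )


@pytest.fixture
def substrate_grid() -> np.ndarray:
    return np.geomspace(10e-6, 500e-6, 8)
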