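import numpy as np
import pytest

from fdrkit import RawPValueSet

# The five-feature worked example: raw p-values and the published columns
# (Z, BH adjusted p, BH FDR, Gaussian lower bound) at printed precision.
TABLE1_P = np.array([0.005, 0.049, 0.050, 0.051, 0.700])
TABLE1_Z = np.array([2.807, 1.969, 1.960, 1.951, 0.385])
TABLE1_ADJ = np.array([0.025, 0.064, 0.064, 0.064, 0.700])
TABLE1_FDR = np.array([0.025, 0.122, 0.083, 0.064, 0.700])
TABLE1_LB = np.array([0.019, 0.126, 0.128, 0.130, 0.481])


@pytest.fixture
def table1_pset() -> RawPValueSet:
    return RawPValueSet(TABLE1_P.copy())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
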