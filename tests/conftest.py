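import numpy as np
import pytest

from adcdar.chem import (
    AntibodySpec,
    ConjugateDesign,
    DrugSpec,
    lookup_linker,
)
from adcdar.extinction import ExtinctionSet

# Published extinction coefficients (M^-1 cm^-1) used throughout the tests.
EABS252, EABS280 = 74_311.0, 209_409.0
ED252, ED280 = 25_600.0, 4_410.0

TRASTUZUMAB_FORMULA_MW = 145_423.0
TRASTUZUMAB_MEASURED_MW = 147_836.9
MICROPLATE_PATH_CM = 0.56


@pytest.fixture(scope="session")
def printed_extinctions() -> ExtinctionSet:
    return ExtinctionSet(eAb252=EABS252, eAb280=EABS280, eD252=ED252, eD280=ED280)


@pytest.fixture(scope="session")
def trastuzumab() -> AntibodySpec:
    return AntibodySpec(
        "trastuzumab",
        mw_formula_Da=TRASTUZUMAB_FORMULA_MW,
        mw_measured_Da=TRASTUZUMAB_MEASURED_MW,
    )


@pytest.fixture(scope="session")
def dm1() -> DrugSpec:
    return DrugSpec("DM1", mw_Da=738.29, lambda_max_nm=252.0)


@pytest.fixture(scope="session")
def smcc_design(trastuzumab, dm1) -> ConjugateDesign:
    return ConjugateDesign(
        antibody=trastuzumab, drug=dm1, linker=lookup_linker("SMCC")
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
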