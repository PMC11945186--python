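import numpy as np
import pytest

from tofasim import (
    DosingRegimen,
    FAST_SOLVER,
    IR_TABLET,
    build_reference_adult,
    simulate,
    tofacitinib,
)


@pytest.fixture(scope="session")
def ref_adult():
    return build_reference_adult()


@pytest.fixture(scope="session")
def compound():
    return tofacitinib()


@pytest.fixture(scope="session")
def single_dose_5mg(ref_adult, compound):
    """Reference 5 mg IR single-dose simulation to elimination completeness."""
    return simulate(ref_adult, compound, DosingRegimen(5.0, IR_TABLET), 120.0)


@pytest.fixture(scope="session")
def single_dose_5mg_fast(ref_adult, compound):
    """Coarse-solver 24 h profile used as a cheap fitting/NCA target."""
    return simulate(
        ref_adult, compound, DosingRegimen(5.0, IR_TABLET), 24.0, solver=FAST_SOLVER
    )
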