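import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from effluxlim import AssayGeometry, Compound


@pytest.fixture(scope="session")
def geometry() -> AssayGeometry:
    return AssayGeometry()


@pytest.fixture(scope="session")
def neutral_compound() -> Compound:
    return Compound(name="neutral400", mw=400.0, log_p0_experimental=-3.0)


@pytest.fixture(scope="session")
def concentration_grid() -> np.ndarray:
    """Eight concentrations covering 0.3-30x the default cytosolic Km of 5 uM."""
    return np.logspace(np.log10(0.3 * 5.0), np.log10(30.0 * 5.0), 8)
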