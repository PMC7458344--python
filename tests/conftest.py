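import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from immunoconcord.io import load_tcell_signature_fixture
from immunoconcord.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def signature_fixture():
    """Packaged 38-gene x 28-patient normalized log expression + HI/LOW labels."""
    return load_tcell_signature_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=60, seed=11))
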