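import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plastokit.simulate import PlastomeSimSpec, make_plastome


@pytest.fixture(scope="session")
def default_plastome():
    """One simulated plastome (seed 0) shared read-only across tests."""
    record, features, truth = make_plastome(PlastomeSimSpec(seed=0))
    return record, features, truth
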