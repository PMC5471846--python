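import logging
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

# site-clipping messages are expected with realistic UTR length draws
logging.getLogger("compartmir.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One wildtype synthetic dataset under the default study conditions."""
    from compartmir import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_report():
    """One full wildtype pipeline run (deterministic stump mode)."""
    from compartmir import RunConfig, SimConfig, run_full

    return run_full(RunConfig(sim=SimConfig(rng_seed=7), threshold_stump=True))
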