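import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle_utils importable

from selexmotif import GroundTruthModel, pwm_from_consensus, simulate_experiment
from selexmotif.simulate import SiteModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def planted_experiment():
    """One simulated SELEX experiment with a planted GGCGTG motif (soft PWM),
    shared by recovery tests.  50k reads x 3 cycles, fixed seed."""
    site = SiteModel(pwm_from_consensus("GGCGTG", 0.85), name="planted")
    model = GroundTruthModel(
        components=[(1.0, site)],
        selection_strength=5.0,
        cycles=3,
        reads_per_cycle=50_000,
        rng_seed=101,
    )
    return model, simulate_experiment(model)
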