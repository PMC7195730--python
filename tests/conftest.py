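import numpy as np
import pytest

from rxcoverage.synthetic import CoverageTrajectory, SimConfig, generate_population


@pytest.fixture(scope="session")
def small_bundle():
    """800-patient population exercising every record type."""
    cfg = SimConfig(n_patients=800, rng_seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def statin_cfg():
    """Single-class study conditions used for recovery checks."""
    return SimConfig(
        n_patients=5000,
        trajectories={"STATIN": CoverageTrajectory(60.0, 0.2, 0.0, -0.12)},
        rng_seed=101,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
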