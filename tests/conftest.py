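import numpy as np
import pytest
from hypothesis import settings

from picketqa.replication import ReplicationConfig, run_calibration
from picketqa.simulate import BeamModel, JitterModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cfg() -> ReplicationConfig:
    """Small deterministic study: 6 pairs, one session, no noise or jitter."""
    return ReplicationConfig(
        n_pairs=6,
        n_sessions=1,
        beam=BeamModel.noiseless(),
        jitter=JitterModel.off(),
        single_bank_first_pair=1,
        both_bank_first_pair=1,
    )


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_cfg):
    """(simulator, NominalValues, CalibrationSet) of the noiseless study."""
    sim = noiseless_cfg.simulator(seed=3)
    nominal, calset = run_calibration(sim, noiseless_cfg)
    return sim, nominal, calset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
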