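import numpy as np
import pytest

from ddtcycle import CheckpointParams, DDTModel, EMGModel, simulate_imt


@pytest.fixture
def cp_slow() -> CheckpointParams:
    """Reference checkpoint: mean 5 h, sd ~1.12 h."""
    return CheckpointParams(0.2, 0.1)


@pytest.fixture
def ddt2_hl() -> DDTModel:
    """Two-checkpoint model with a high-CV (H) and a low-CV (L) component."""
    return DDTModel([CheckpointParams(0.25, 1.0), CheckpointParams(0.1, 0.05)])


@pytest.fixture
def emg_model() -> EMGModel:
    return EMGModel(rate=0.5, gauss_mean=10.0, gauss_sd=1.5)


@pytest.fixture
def imts_ddt1(cp_slow) -> np.ndarray:
    return simulate_imt(DDTModel([cp_slow]), 500, seed=11)


@pytest.fixture
def imts_ddt2(ddt2_hl) -> np.ndarray:
    return simulate_imt(ddt2_hl, 500, seed=12)
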