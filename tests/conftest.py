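import numpy as np
import pytest

from picpipe.datamodel import Condition, Phase, RampTrial
from picpipe.simulate import PoolConfig, simulate_trial, target_triangle_pct


@pytest.fixture
def clean_ramp_trial() -> RampTrial:
    """A perfectly tracked 20 s triangular ramp at 200 Hz, peak 50 N*m."""
    fs, peak = 200.0, 50.0
    t = np.arange(0, 20 + 0.5 / fs, 1 / fs)
    target = target_triangle_pct(t) / 100.0 * peak
    return RampTrial(
        participant_id="P01",
        condition=Condition.CONTROL,
        phase=Phase.BEFORE,
        torque_raw=target.copy(),
        fs=fs,
        peak_torque=peak,
        target_path=target,
    )


@pytest.fixture
def noiseless_pool_config() -> PoolConfig:
    """Linear rate model, no noise anywhere: the exact-oracle regime."""
    return PoolConfig(
        units_per_trial=8,
        isi_cv=0.0,
        drive_noise_pct=0.0,
        torque_noise_pct=0.0,
        pic_amplitude=0.0,
        gain_jitter=0.0,
        condition_effects={},
    )


@pytest.fixture
def noiseless_trial(noiseless_pool_config):
    rng = np.random.default_rng(11)
    return simulate_trial(
        noiseless_pool_config, "P01", Condition.CONTROL, Phase.BEFORE, rng
    )
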