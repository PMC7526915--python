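import numpy as np
import pytest

from ticpr import DetectorConfig, EpisodeScenario, ImpedanceSignal, generate_episode


@pytest.fixture(scope="session")
def default_config() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def no_interp_config() -> DetectorConfig:
    return DetectorConfig(refine_peak=False)


@pytest.fixture
def sinusoid_signal():
    """Factory: unit-amplitude sinusoid episodes at 250 Hz."""

    def make(period_s: float, duration_s: float = 2.0, phase: float = np.pi / 2):
        fs = 250.0
        t = np.arange(int(round(duration_s * fs))) / fs
        return ImpedanceSignal(np.sin(2 * np.pi * t / period_s + phase), fs=fs)

    return make


@pytest.fixture(scope="session")
def clean_episode():
    """Noiseless, jitter-free 110-cpm episode with continuous compressions."""
    scenario = EpisodeScenario(
        duration_s=60.0,
        rate_cpm_mean=110.0,
        rate_cpm_jitter_sd=0.0,
        ccf_target=1.0,
        ventilation_amp_ohm=0.0,
        drift_amp_ohm=0.0,
        noise_sd_ohm=0.0,
        seed=11,
    )
    return generate_episode(scenario)
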