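import numpy as np
import pytest

from ppgecg import RunConfig, SimConfig, generate_subject
from ppgecg.siggen import _draw_ptts, generate_beat_train


def clean_config(**over) -> SimConfig:
    """Noise-free simulation settings for oracle tests."""
    base = dict(
        duration_s=60.0,
        noise_baseline_amp=0.0,
        noise_gauss_sd=0.0,
        artifact_rate=0.0,
        seed=123,
    )
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def runcfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free subject: the primary end-to-end oracle substrate."""
    return generate_subject(clean_config(duration_s=120.0), bp_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject at the default noise preset."""
    return generate_subject(SimConfig(seed=11), bp_noise_sd=3.0)


@pytest.fixture()
def beat_train():
    cfg = clean_config(hr_mean=75, hr_sd=5, seed=7)
    r = generate_beat_train(cfg)
    return cfg, r, _draw_ptts(r, cfg)
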