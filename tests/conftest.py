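import numpy as np
import pytest

from shemon.synth import EcgSynthConfig, synth_ecg


@pytest.fixture(scope="session")
def clean_ecg_60s():
    """60 s clean sinus ECG at 60 bpm with exact beat ground truth."""
    return synth_ecg(EcgSynthConfig(hr_bpm=60, hr_sd=0.0, rsa_depth=0.0,
                                    resp_mod_depth=0.0, noise_sd=0.0,
                                    wander_amp=0.0, duration_s=60, seed=11))


@pytest.fixture(scope="session")
def modulated_ecg_120s():
    """2 min ECG with 15 breaths/min amplitude modulation (depth 0.2)."""
    return synth_ecg(EcgSynthConfig(hr_bpm=70, rr_brpm=15, resp_mod_depth=0.2,
                                    duration_s=120, seed=12))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
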