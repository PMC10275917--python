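import numpy as np
import pytest
from hypothesis import settings

from bluetitsong import SynthSongConfig, synth_song

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def clean_config():
    """A song config with every jitter source switched off."""
    return SynthSongConfig(
        freq_jitter_sd=0.0, duration_jitter_sd=0.0, amp_jitter_sd=0.0, noise_level=0.0
    )


@pytest.fixture
def clean_song(clean_config, rng):
    return synth_song(clean_config, rng)
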