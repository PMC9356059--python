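import numpy as np
import pytest

from rhythmtag import config as cfg
from rhythmtag import envspec, stimgen
from rhythmtag.containers import Evoked


@pytest.fixture(scope="session")
def inventory():
    return stimgen.build_inventory()


@pytest.fixture(scope="session")
def voice_en():
    return stimgen.voice_params("english")


@pytest.fixture(scope="session")
def seq_audio(inventory, voice_en):
    """One rendered 30 s English-voice sequence (plan seed 1)."""
    plan = stimgen.plan_sequence(inventory, seed=1)
    return stimgen.render_sequence(plan, inventory, voice_en)


@pytest.fixture(scope="session")
def voc_audio(seq_audio):
    return stimgen.vocode(seq_audio, seed=3)


@pytest.fixture(scope="session")
def seq_env_spectrum(seq_audio):
    env = envspec.hilbert_envelope(seq_audio)
    return envspec.envelope_spectrum(env, seq_audio.sample_rate_hz,
                                     source_id="english-seed1")


def make_evoked(data: np.ndarray, fs: int = cfg.EEG_FS,
                ch_names=None, **kw) -> Evoked:
    """Wrap a (channels x time) array as an Evoked for spectral tests."""
    data = np.atleast_2d(data)
    if ch_names is None:
        ch_names = cfg.channel_names(data.shape[0])
    kw.setdefault("n_epochs_averaged", 8)
    return Evoked(data=data, fs_hz=fs, ch_names=list(ch_names), **kw)
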