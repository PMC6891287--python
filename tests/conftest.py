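import numpy as np
import pytest

from cspcwt.io_gal import EEGRecording, EventAnnotations


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_recording():
    """Two-channel, three-sample recording with HS active on samples 1-2."""
    rec = EEGRecording(
        data=np.array([[1.0, 2.0, 3.0], [-1.5, 0.25, 4.0]]),
        fs=500.0,
        channel_names=["C3", "Cz"],
    )
    labels = np.zeros((6, 3), dtype=int)
    labels[0, 1:] = 1
    return rec, EventAnnotations(labels=labels)


@pytest.fixture(scope="session")
def designed_fir():
    """The default 7-30 Hz equiripple band-pass (design is ~1 s, share it)."""
    from cspcwt.preprocess import design_bandpass

    return design_bandpass()


@pytest.fixture(scope="session")
def default_bank():
    from cspcwt.scalogram import MorseBankSpec, build_morse_bank

    return build_morse_bank(MorseBankSpec())
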