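import numpy as np
import pytest

from connet.signals import ChannelInfo, EpochSet, Recording


def make_channels(labels, tissue="grey"):
    return [ChannelInfo.from_label(lbl, tissue=tissue) for lbl in labels]


def make_recording(data, fs=256.0, labels=None, epoch_start=0.0):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"LA{i + 1:02d}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, channels=make_channels(labels),
                     epoch_start=epoch_start)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Three channels: 10 Hz, 60 Hz, and their sum, 4 s at 512 Hz."""
    fs = 512.0
    t = np.arange(int(4 * fs)) / fs
    s10 = np.sin(2 * np.pi * 10 * t)
    s60 = np.sin(2 * np.pi * 60 * t)
    return make_recording(np.stack([s10, s60, s10 + s60]), fs=fs)


@pytest.fixture
def random_epochs(rng):
    """Two 10-s epochs of 6 correlated pink-ish channels at 256 Hz."""
    fs = 256.0
    n = int(10 * fs)
    labels = ["LA01", "LA02", "LA03", "RA01", "RA02", "RA03"]
    mix = np.eye(6) + 0.3
    epochs = []
    for _ in range(2):
        z = rng.standard_normal((6, n))
        epochs.append(Recording(data=mix @ z, fs=fs,
                                channels=make_channels(labels)))
    # share channel objects between epochs, as the ingest pipeline does
    for ep in epochs[1:]:
        ep.channels = epochs[0].channels
    return EpochSet(epochs=epochs, epoch_length_s=10.0)
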