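import numpy as np
import pytest

from osadetect.ecg_io import EcgRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labeled_record(rng):
    """A 3-minute 100 Hz record with weak structure and N/A/N labels."""
    fs = 100.0
    t = np.arange(int(fs * 180)) / fs
    x = 0.8 * np.sin(2 * np.pi * 1.1 * t) + 0.05 * rng.standard_normal(t.size)
    return EcgRecord("rec00", x, fs, labels=["N", "A", "N"])
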