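import numpy as np
import pytest

from ecgssm import MorphologyProfile, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_record():
    """A noise-free 10 s sinus-like record at 500 Hz, one beat per second."""
    return generate_record([MorphologyProfile("SYN00")], fs=500,
                           duration=10.0, noise_sd=0.0, seed=3,
                           record_id="clean")


def random_record(seed: int, fs: float = 500.0, duration: float = 4.0):
    """A random-valued 12-lead record (not physiological; for I/O tests)."""
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    from ecgssm.signal_io import ECGRecord, STANDARD_LEADS
    return ECGRecord(
        record_id=f"rand{seed}",
        signal=rng.normal(0, 0.5, size=(12, n)).clip(-3, 3),
        fs=fs,
        lead_names=list(STANDARD_LEADS),
        labels={"164889003", "59118001"} if seed % 2 else {"426783006"},
        source_meta={"Age": "63", "Sex": "Female"},
    )
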