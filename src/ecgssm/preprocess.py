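"""Resampling, length fixing and standardization of ECG records.

The target representation for the classifier is a 12 x 8192 matrix at 500 Hz:
1000 Hz records are downsampled by polyphase filtering, 257 Hz records are
upsampled through the FFT, shorter signals are zero-padded and longer ones are
cropped to a random contiguous 8192-sample window.  Z-scoring is on by
default but can be disabled — preserving raw amplitude is a supported mode.

Convention notes: the standard deviation is the population one (divide by n),
and z-scoring operates on the pre-pad support — statistics are computed before
zero padding, so the padding neither shrinks real amplitudes nor shifts the
mean (padded zeros coincide with the post-z-score mean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import ECGRecord


@dataclass
class PreprocessConfig:
    target_fs: float = 500.0
    target_len: int = 8192
    zscore: bool = True
    zscore_scope: str = "per-lead"      # or "per-record"
    truncation_seed: int = 0
    pad_side: str = "end"               # or "center"

    def __post_init__(self) -> None:
        if self.target_fs <= 0 or self.target_len <= 0:
            raise ValueError("target_fs and target_len must be positive")
        if self.zscore_scope not in ("per-lead", "per-record"):
            raise ValueError("zscore_scope must be 'per-lead' or 'per-record'")
        if self.pad_side not in ("end", "center"):
            raise ValueError("pad_side must be 'end' or 'center'")


def _target_length(n: int, fs_in: float, fs_out: float) -> int:
    # round half up, matching the ceil behaviour of resample_poly at .5
    return int(np.floor(n * fs_out / fs_in + 0.5))


def resample_polyphase(signal: np.ndarray, fs_in: float,
                       fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase downsampling, each lead independently."""
    if fs_in <= fs_out:
        raise ValueError("resample_polyphase requires fs_in > fs_out; "
                         "use resample_fft for upsampling")
    ratio = Fraction(fs_out).limit_denominator() / \
        Fraction(fs_in).limit_denominator()
    up, down = ratio.numerator, ratio.denominator
    # longer kaiser-windowed FIR than the resample_poly default: flat
    # passband (sub-1e-4 ripple) so down(up(x)) round-trips band-limited
    # signals accurately
    max_rate = max(up, down)
    half_len = 40 * max_rate
    taps = sps.firwin(2 * half_len + 1, 1.0 / max_rate,
                      window=("kaiser", 8.0))
    out = sps.resample_poly(np.asarray(signal, dtype=float), up, down,
                            axis=-1, window=taps * up)
    want = _target_length(signal.shape[-1], fs_in, fs_out)
    return out[..., :want]


def resample_fft(signal: np.ndarray, fs_in: float,
                 fs_out: float) -> np.ndarray:
    """Fourier-domain upsampling; band-limited content is preserved."""
    if fs_in >= fs_out:
        raise ValueError("resample_fft requires fs_in < fs_out")
    want = _target_length(signal.shape[-1], fs_in, fs_out)
    return sps.resample(np.asarray(signal, dtype=float), want, axis=-1)


def fix_length(signal: np.ndarray, target_len: int, seed: int = 0,
               pad_side: str = "end") -> np.ndarray:
    """Zero-pad short signals; crop long ones to a random contiguous window.

    All leads share the same window; the window start is uniform over the
    valid range and deterministic for a given seed.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n == target_len:
        return signal
    if n > target_len:
        start = int(np.random.default_rng(seed).integers(0, n - target_len + 1))
        return signal[..., start:start + target_len]
    pad = target_len - n
    if pad_side == "end":
        widths = (0, pad)
    else:
        widths = (pad // 2, pad - pad // 2)
    spec = [(0, 0)] * (signal.ndim - 1) + [widths]
    return np.pad(signal, spec)


def zscore(signal: np.ndarray, scope: str = "per-lead",
           eps: float = 1e-10) -> np.ndarray:
    """Standardize to zero mean, unit population sd; constant input -> zeros."""
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("signal must be finite")
    if scope == "per-record":
        mean, sd = signal.mean(), signal.std()
        return np.zeros_like(signal) if sd <= eps else (signal - mean) / sd
    if scope != "per-lead":
        raise ValueError("scope must be 'per-lead' or 'per-record'")
    mean = signal.mean(axis=-1, keepdims=True)
    sd = signal.std(axis=-1, keepdims=True)
    out = np.where(sd <= eps, 0.0, (signal - mean) / np.where(sd <= eps, 1, sd))
    return out


def preprocess_record(record: ECGRecord,
                      config: PreprocessConfig | None = None) -> ECGRecord:
    """Resample to the target rate, fix the length, optionally z-score.

    Order: resample -> crop (if long) -> z-score on the true support ->
    zero-pad (if short).
    """
    config = config or PreprocessConfig()
    sig = record.signal
    if record.fs > config.target_fs:
        sig = resample_polyphase(sig, record.fs, config.target_fs)
    elif record.fs < config.target_fs:
        sig = resample_fft(sig, record.fs, config.target_fs)

    if sig.shape[-1] > config.target_len:
        sig = fix_length(sig, config.target_len, seed=config.truncation_seed,
                         pad_side=config.pad_side)
    if config.zscore:
        sig = zscore(sig, scope=config.zscore_scope)
    if sig.shape[-1] < config.target_len:
        sig = fix_length(sig, config.target_len, seed=config.truncation_seed,
                         pad_side=config.pad_side)

    return ECGRecord(record_id=record.record_id, signal=sig,
                     fs=config.target_fs, lead_names=list(record.lead_names),
                     labels=set(record.labels),
                     source_meta={**record.source_meta, "preprocessed": "1"})
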