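"""Reading and writing 12-lead ECG records.

Two on-disk dialects are supported:

* the PhysioNet/CinC-challenge flavour of the WFDB header format — a ``.hea``
  text header (record line, one line per lead, ``#``-prefixed comments, with
  diagnosis codes on a ``# Dx:`` line) paired with a MATLAB ``.mat`` companion
  holding the integer signal matrix under the key ``val``;
* a portable fixture dialect — the same ``.hea`` header paired with a plain
  ``.dat`` file of little-endian 16-bit integers, column-major by sample.

Signals are stored as integers with a per-lead gain (ADC units per millivolt)
and converted to physical units (mV) on read.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

logger = logging.getLogger(__name__)

#: canonical 12-lead order assumed by every downstream model
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: sampling rates present in the challenge corpora
CHALLENGE_RATES = (257, 500, 1000)


class HeaderError(ValueError):
    """Malformed or inconsistent header content."""


@dataclass
class ECGRecord:
    """One multichannel ECG in physical units.

    Attributes
    ----------
    record_id : str
        Identifier, also the file stem on disk.
    signal : ndarray, shape (n_leads, n_samples)
        Voltages in millivolts.
    fs : float
        Sampling rate in Hz.
    lead_names : list of str
        One name per signal row, canonically ``STANDARD_LEADS``.
    labels : set of str
        Diagnosis codes (e.g. SNOMED CT identifiers from the ``# Dx:`` line).
    source_meta : dict
        Free-form header fields preserved across a round trip.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    lead_names: list[str]
    labels: set[str] = field(default_factory=set)
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (leads x samples) array")
        if self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.lead_names)} lead names"
            )
        if self.signal.shape[1] == 0:
            raise ValueError("record has zero samples")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN/Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class LabelVocabulary:
    """Fixed, ordered class vocabulary; index position is the class id."""

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("vocabulary codes must be unique")
        if not self.codes:
            raise ValueError("vocabulary must be non-empty")

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    @classmethod
    def synthetic(cls, n_classes: int = 26) -> "LabelVocabulary":
        """A synthetic stand-in vocabulary (codes ``SYN00``..) sized like the
        26-class task (25 abnormalities + sinus rhythm)."""
        return cls(tuple(f"SYN{i:02d}" for i in range(n_classes)))


def labels_to_vector(labels: set[str], vocab: LabelVocabulary) -> np.ndarray:
    """Multi-hot encode a diagnosis-code set over a fixed vocabulary.

    Codes absent from the vocabulary are dropped with a warning (the 2020 and
    2021 challenge vocabularies differ, so readers must tolerate strays).
    """
    vec = np.zeros(vocab.size, dtype=float)
    unknown = []
    for code in labels:
        try:
            vec[vocab.index(code)] = 1.0
        except ValueError:
            unknown.append(code)
    if unknown:
        logger.warning("dropping %d code(s) not in vocabulary: %s",
                       len(unknown), ",".join(sorted(unknown)))
    return vec


# --------------------------------------------------------------------------
# header dialect
# --------------------------------------------------------------------------

def _parse_header(header_path: Path) -> dict:
    lines = header_path.read_text().splitlines()
    if not lines:
        raise HeaderError(f"{header_path}: empty header")
    rec_fields = lines[0].split()
    if len(rec_fields) < 4:
        raise HeaderError(f"{header_path}:1: record line needs "
                          "'name n_leads fs n_samples'")
    try:
        n_leads = int(rec_fields[1])
        fs = float(rec_fields[2])
        n_samples = int(rec_fields[3])
    except ValueError as exc:
        raise HeaderError(f"{header_path}:1: {exc}") from exc

    leads, gains = [], []
    for lineno, line in enumerate(lines[1:1 + n_leads], start=2):
        parts = line.split()
        if len(parts) < 3:
            raise HeaderError(f"{header_path}:{lineno}: lead line needs "
                              "'file gain name'")
        # challenge gain field looks like "1000/mV" or "1000(0)/mV"
        gain_txt = parts[1].split("/")[0].split("(")[0]
        try:
            gains.append(float(gain_txt))
        except ValueError as exc:
            raise HeaderError(f"{header_path}:{lineno}: bad gain "
                              f"{parts[1]!r}") from exc
        leads.append(parts[-1])
    if len(leads) != n_leads:
        raise HeaderError(f"{header_path}: declared {n_leads} leads, "
                          f"found {len(leads)} lead lines")

    meta, dx = {}, set()
    for line in lines[1 + n_leads:]:
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            if key.lower() == "dx":
                dx = {c.strip() for c in val.split(",")
                      if c.strip() and c.strip() != "NA"}
            else:
                meta[key] = val
    return {
        "record_id": rec_fields[0],
        "n_leads": n_leads,
        "fs": fs,
        "n_samples": n_samples,
        "lead_names": leads,
        "gains": gains,
        "labels": dx,
        "meta": meta,
        "signal_file": lines[1].split()[0] if n_leads else None,
    }


def _load_signal(header_path: Path, info: dict) -> np.ndarray:
    stem = header_path.with_suffix("")
    mat_path, dat_path = stem.with_suffix(".mat"), stem.with_suffix(".dat")
    if mat_path.exists():
        raw = np.asarray(loadmat(mat_path)["val"], dtype=float)
    elif dat_path.exists():
        flat = np.fromfile(dat_path, dtype="<i2")
        if flat.size != info["n_leads"] * info["n_samples"]:
            raise HeaderError(
                f"{dat_path}: expected {info['n_leads'] * info['n_samples']} "
                f"samples, found {flat.size}")
        # column-major by sample: each frame holds one sample per lead
        raw = flat.reshape(info["n_samples"], info["n_leads"]).T.astype(float)
    else:
        raise FileNotFoundError(
            f"no signal companion for {header_path}: expected "
            f"{mat_path} or {dat_path}")
    return raw


def read_record(header_path: str | Path,
                reorder_leads: bool = True) -> ECGRecord:
    """Read a header + signal pair into an :class:`ECGRecord` in millivolts.

    Leads are reordered to :data:`STANDARD_LEADS` when all twelve names are
    present; records with missing or extra leads are rejected (no imputation).
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    info = _parse_header(header_path)
    raw = _load_signal(header_path, info)
    if raw.shape[0] != info["n_leads"]:
        raise HeaderError(
            f"{header_path}: header declares {info['n_leads']} leads but "
            f"signal file has {raw.shape[0]} rows")
    if raw.shape[1] != info["n_samples"]:
        raise HeaderError(
            f"{header_path}: header declares {info['n_samples']} samples but "
            f"signal file has {raw.shape[1]}")

    signal = raw / np.asarray(info["gains"], dtype=float)[:, None]
    lead_names = list(info["lead_names"])
    if reorder_leads:
        if sorted(lead_names) != sorted(STANDARD_LEADS):
            raise HeaderError(
                f"{header_path}: expected the 12 standard leads, got "
                f"{lead_names}")
        order = [lead_names.index(name) for name in STANDARD_LEADS]
        signal = signal[order]
        lead_names = list(STANDARD_LEADS)
    return ECGRecord(
        record_id=info["record_id"],
        signal=signal,
        fs=info["fs"],
        lead_names=lead_names,
        labels=info["labels"],
        source_meta=info["meta"],
    )


def write_record(record: ECGRecord, out_dir: str | Path,
                 gain: float = 1000.0, fmt: str = "mat") -> tuple[Path, Path]:
    """Write ``record`` as a header + signal pair readable by ``read_record``.

    Voltages are quantized to integers at ``gain`` ADC units per mV, so the
    round trip is lossless up to 1/(2·gain) mV.  ``fmt`` selects the signal
    companion: ``"mat"`` (challenge dialect) or ``"dat"`` (portable int16).
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"not a writable directory: {out_dir}")
    if fmt not in ("mat", "dat"):
        raise ValueError(f"unknown signal format {fmt!r}")

    quantized = np.round(record.signal * gain)
    if np.abs(quantized).max() > np.iinfo(np.int16).max:
        raise ValueError("signal amplitude overflows int16 at this gain; "
                         "lower the gain")
    quantized = quantized.astype(np.int16)

    sig_name = f"{record.record_id}.{fmt}"
    lines = [f"{record.record_id} {record.n_leads} {record.fs:g} "
             f"{record.n_samples}"]
    for name in record.lead_names:
        lines.append(f"{sig_name} {gain:g}/mV {name}")
    lines.append(f"# Dx: {','.join(sorted(record.labels)) or 'NA'}")
    for key, val in record.source_meta.items():
        lines.append(f"# {key}: {val}")

    header_path = out_dir / f"{record.record_id}.hea"
    header_path.write_text("\n".join(lines) + "\n")
    sig_path = out_dir / sig_name
    if fmt == "mat":
        savemat(sig_path, {"val": quantized})
    else:
        quantized.T.reshape(-1).tofile(sig_path)
    return header_path, sig_path


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def write_manifest(records: list[ECGRecord], paths: list[Path],
                   manifest_path: str | Path) -> pd.DataFrame:
    """Write a CSV manifest (record_id, path, fs, labels) for a dataset."""
    frame = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "path": [str(p) for p in paths],
        "fs": [r.fs for r in records],
        "labels": ["|".join(sorted(r.labels)) for r in records],
    })
    frame.to_csv(manifest_path, index=False)
    return frame


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(manifest_path, dtype={"record_id": str, "labels": str})
    frame["labels"] = frame["labels"].fillna("")
    return frame


def manifest_label_sets(frame: pd.DataFrame) -> list[set[str]]:
    return [set(s.split("|")) - {""} for s in frame["labels"]]
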