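"""Readers and writers for the on-disk formats the pipeline touches.

Signals travel either as EDF (read-only, via :mod:`mne` when installed) or as
a plain NPZ container written by this module; hypnograms and AHI tables are
CSV; feature images are PNG.  All timestamps are seconds from recording
start, epochs are 0-based and cover the half-open interval
``[30*i, 30*(i+1))``.
"""

from __future__ import annotations

import csv
import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The AASM 5-class stage alphabet, in canonical order.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}

EPOCH_DURATION_S = 30

# On-disk label synonyms -> canonical stage names.  "P" (preparation) is not a
# stage; it is filtered by read_hypnogram.
_LABEL_SYNONYMS = {
    "W": "W",
    "WAKE": "W",
    "AWAKE": "W",
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
    "R": "R",
    "REM": "R",
}


class FormatError(ValueError):
    """Raised for malformed or unreadable input files."""


@dataclasses.dataclass
class EEGRecording:
    """A single-channel EEG signal with identity and sampling metadata.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    channel : str
        Derivation name, e.g. ``"C4-M1"``.
    fs : float
        Sampling rate in Hz (> 0).
    samples : ndarray
        Ordered real-valued amplitudes in microvolts.
    """

    subject_id: str
    channel: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("corrupt signal: NaN/Inf samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_epochs(self) -> int:
        return int(self.samples.size // (EPOCH_DURATION_S * self.fs))


@dataclasses.dataclass
class Hypnogram:
    """Ordered 30 s epoch labels aligned to a recording.

    Epoch ``i`` covers ``[30*i, 30*(i+1))`` seconds from recording start.
    """

    subject_id: str
    labels: list[str]
    epoch_duration_s: int = EPOCH_DURATION_S

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if not self.labels:
            raise ValueError("hypnogram has no epochs")
        for lab in self.labels:
            if lab not in STAGE_TO_INDEX:
                raise FormatError(f"unknown stage label: {lab!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> int:
        return self.epoch_duration_s * len(self.labels)

    def as_indices(self) -> np.ndarray:
        return np.array([STAGE_TO_INDEX[s] for s in self.labels], dtype=np.int64)


@dataclasses.dataclass
class SubjectTable:
    """Per-subject AHI values and file locations.

    ``frame`` has columns ``subject_id`` (unique), ``ahi`` (events/hour,
    finite and >= 0) and optionally ``recording_path`` / ``hypnogram_path``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "subject_id" not in df.columns or "ahi" not in df.columns:
            raise FormatError("subject table needs 'subject_id' and 'ahi' columns")
        if df["subject_id"].duplicated().any():
            raise FormatError("duplicate subject_id in subject table")
        ahi = df["ahi"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ahi)) or np.any(ahi < 0):
            raise FormatError("AHI values must be finite and >= 0")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    def ahi_of(self, subject_id: str) -> float:
        row = self.frame.loc[self.frame["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return float(row["ahi"].iloc[0])


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

def write_recording(path: str | Path, rec: EEGRecording) -> Path:
    """Write a recording to the package's NPZ signal container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        samples=rec.samples,
        fs=np.float64(rec.fs),
        channel=np.str_(rec.channel),
        subject_id=np.str_(rec.subject_id),
    )
    return path


def read_recording(path: str | Path, channel: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or the NPZ signal container.

    Parameters
    ----------
    path : path
        ``.edf`` files are read through :mod:`mne` (metadata sampling rate,
        samples converted to microvolts); anything else is treated as the NPZ
        container written by :func:`write_recording`.
    channel : str, optional
        Channel to select.  For NPZ files the stored channel must match when
        given; a mismatch raises ``FormatError("channel not found")``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channel)
    try:
        with np.load(path, allow_pickle=False) as data:
            samples = np.asarray(data["samples"], dtype=np.float64)
            fs = float(data["fs"])
            stored_channel = str(data["channel"])
            subject_id = str(data["subject_id"])
    except Exception as exc:  # unreadable container
        raise FormatError(f"corrupt signal: {path} ({exc})") from exc
    if channel is not None and channel != stored_channel:
        raise FormatError(
            f"channel not found: {channel!r} (file has {stored_channel!r})"
        )
    if not np.all(np.isfinite(samples)):
        raise FormatError(f"corrupt signal: NaN/Inf samples in {path}")
    return EEGRecording(subject_id=subject_id, channel=stored_channel, fs=fs, samples=samples)


def _read_edf(path: Path, channel: str | None) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise FormatError(f"channel not found: {channel!r} (file has {raw.ch_names})")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    if not np.all(np.isfinite(data)):
        raise FormatError(f"corrupt signal: NaN/Inf samples in {path}")
    return EEGRecording(
        subject_id=path.stem,
        channel=channel,
        fs=float(raw.info["sfreq"]),
        samples=data,
    )


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(path: str | Path, hyp: Hypnogram) -> Path:
    """Write a hypnogram CSV: header ``stage``, one label per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage"])
        for lab in hyp.labels:
            writer.writerow([lab])
    return path


def read_hypnogram(path: str | Path, subject_id: str | None = None) -> tuple[Hypnogram, int]:
    """Read a hypnogram CSV and drop preparation ("P") epochs.

    The CSV holds one label per 30 s epoch, optionally under a ``stage``
    header.  Synonyms are normalized ("Wake" -> W, "REM" -> R); epochs marked
    "P" are removed without reordering the survivors.

    Returns
    -------
    (Hypnogram, int)
        The cleaned hypnogram and the number of removed "P" epochs.
    """
    path = Path(path)
    raw_labels: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            token = row[0].strip()
            if token.lower() in ("stage", "label"):  # header
                continue
            raw_labels.append(token)
    if not raw_labels:
        raise FormatError(f"unknown stage label: empty hypnogram in {path}")
    labels: list[str] = []
    removed = 0
    for token in raw_labels:
        canon = token.upper()
        if canon == "P":
            removed += 1
            continue
        if canon not in _LABEL_SYNONYMS:
            raise FormatError(f"unknown stage label: {token!r}")
        labels.append(_LABEL_SYNONYMS[canon])
    if not labels:
        raise FormatError(f"hypnogram in {path} has no scored epochs after P removal")
    return Hypnogram(subject_id=subject_id or path.stem, labels=labels), removed


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------

def write_subject_table(path: str | Path, table: SubjectTable) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def read_subject_table(path: str | Path) -> SubjectTable:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    return SubjectTable(frame=frame)


# ---------------------------------------------------------------------------
# Feature images
# ---------------------------------------------------------------------------

def save_feature_image(path: str | Path, pixels: np.ndarray) -> Path:
    """Save an H x W x 3 float image in [0, 1] as an 8-bit PNG."""
    from PIL import Image

    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {pixels.shape}")
    if pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9:
        warnings.warn("pixels outside [0, 1]; clipping before PNG export")
    quantized = np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(quantized, mode="RGB").save(path)
    return path


def feature_image_name(subject_id: str, epoch_index: int, label: str) -> str:
    """Canonical per-epoch PNG file name."""
    return f"{subject_id}_{epoch_index:05d}_{label}.png"


def labels_from_lists(labels: Sequence[str]) -> np.ndarray:
    """Map stage labels to integer indices (W=0 ... R=4)."""
    return np.array([STAGE_TO_INDEX[s] for s in labels], dtype=np.int64)
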