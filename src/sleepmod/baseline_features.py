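"""Benchmark time-frequency representations: STFT spectrogram, CWT scalogram.

Both baselines operate on a fixed 30 s epoch: the signal is resampled to
64 Hz, transformed, log-power scaled, min-max normalized and rendered at
76x60x3 (the baseline image geometry).  The STFT uses 256-point Hamming
windows with 50% overlap restricted to 0-32 Hz; the CWT uses an analytic
Morlet filterbank with 12 voices per octave (64 log-spaced scales reaching
up to 32 Hz).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .io_formats import EEGRecording
from .modulation_features import FeatureImage, _resize_bilinear
from .preprocessing import resample
from .windowing import EpochWindow

_TARGET_FS = 64.0
_MAX_HZ = 32.0
_NPERSEG = 256
_WAVELET = "cmor1.5-1.0"  # analytic (complex) Morlet
_VOICES_PER_OCTAVE = 12
_N_SCALES = 64
_LOG_EPS = 1e-10


def _extract_30s(window: EpochWindow, rec: EEGRecording) -> np.ndarray:
    if window.length_s != 30:
        raise ValueError(
            f"baseline features are fixed to 30 s windows, got {window.length_s} s"
        )
    sl = window.sample_slice(rec.fs)
    if sl.start < 0 or sl.stop > rec.samples.size:
        raise ValueError("window exceeds recording bounds")
    return rec.samples[sl]


def _render(matrix: np.ndarray, label: str) -> FeatureImage:
    lo, hi = matrix.min(), matrix.max()
    if hi <= lo:
        scaled = np.full_like(matrix, 0.5)
    else:
        scaled = (matrix - lo) / (hi - lo)
    resized = np.clip(_resize_bilinear(scaled[::-1, :], (76, 60)), 0.0, 1.0)
    span = resized.max() - resized.min()
    if span > 0:
        resized = (resized - resized.min()) / span
    pixels = np.repeat(resized[:, :, None], 3, axis=2)
    return FeatureImage(pixels, "76x60", label)


def stft_feature(window: EpochWindow, rec: EEGRecording) -> FeatureImage:
    """Log-power STFT spectrogram image of a 30 s epoch (76x60x3).

    Resamples to 64 Hz, computes a magnitude-squared STFT with 256-point
    Hamming segments at 50% overlap, keeps 0-32 Hz and log-scales power.
    """
    segment = _extract_30s(window, rec)
    seg_rec = EEGRecording(rec.subject_id, rec.channel, rec.fs, segment)
    seg64 = resample(seg_rec, _TARGET_FS)
    freqs, _, zxx = sps.stft(
        seg64.samples,
        fs=_TARGET_FS,
        window="hamming",
        nperseg=_NPERSEG,
        noverlap=_NPERSEG // 2,
    )
    power = np.abs(zxx) ** 2
    keep = freqs <= _MAX_HZ
    log_power = np.log10(power[keep] + _LOG_EPS)
    return _render(log_power, window.label)


def _cwt_frequencies() -> np.ndarray:
    """64 log-spaced analysis frequencies, 12 per octave, topping at 32 Hz."""
    k = np.arange(_N_SCALES)
    return _MAX_HZ / 2 ** (k[::-1] / _VOICES_PER_OCTAVE)


def cwt_feature(window: EpochWindow, rec: EEGRecording) -> FeatureImage:
    """Analytic-Morlet scalogram image of a 30 s epoch (76x60x3).

    Resamples to 64 Hz, normalizes the epoch (zero mean, unit SD), computes
    the complex Morlet CWT over 64 scales (12 voices/octave up to 32 Hz) and
    applies log-power scaling.
    """
    segment = _extract_30s(window, rec)
    seg_rec = EEGRecording(rec.subject_id, rec.channel, rec.fs, segment)
    seg64 = resample(seg_rec, _TARGET_FS)
    x = seg64.samples
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    freqs = _cwt_frequencies()  # ascending; one scalogram row per frequency
    scales = pywt.frequency2scale(_WAVELET, freqs / _TARGET_FS)
    coeffs, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / _TARGET_FS)
    log_power = np.log10(np.abs(coeffs) ** 2 + _LOG_EPS)
    return _render(log_power, window.label)


def cwt_row_frequencies() -> np.ndarray:
    """Analysis frequencies (Hz, ascending) of the scalogram rows."""
    return np.sort(_cwt_frequencies())
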