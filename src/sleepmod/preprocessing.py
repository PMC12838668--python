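"""Signal conditioning: band-pass filtering, per-subject z-scoring, resampling.

The band-pass is a fourth-order Butterworth (0.3-40 Hz by default) applied
zero-phase (forward-backward) so epoch boundaries are not phase-shifted.
Z-scoring standardizes each subject's whole recording with its global mean
and standard deviation (population convention), which makes every downstream
feature invariant to absolute signal amplitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .io_formats import EEGRecording


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Global amplitude statistics of a subject's recording (microvolts)."""

    mu_s: float
    sigma_s: float

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")


def bandpass_filter(
    rec: EEGRecording,
    low_hz: float = 0.3,
    high_hz: float = 40.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the whole recording.

    The prototype filter is of the given order; forward-backward application
    squares its magnitude response (and doubles the effective attenuation)
    while cancelling phase.

    Raises
    ------
    ValueError
        If ``high_hz`` is at or above the Nyquist frequency.
    """
    nyq = rec.fs / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"Nyquist violation: high_hz={high_hz} needs fs > {2 * high_hz}, got fs={rec.fs}"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if rec.samples.size <= 3 * order:
        raise ValueError("signal too short to filter")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return EEGRecording(rec.subject_id, rec.channel, rec.fs, filtered)


def zscore_normalize(rec: EEGRecording) -> tuple[EEGRecording, NormalizationStats]:
    """Standardize a recording with its global mean/SD: (x - mu) / sigma.

    Uses the population (1/N) standard deviation.  The output has mean 0 and
    SD 1 to within floating tolerance; the statistics are returned for audit.

    Raises
    ------
    ValueError
        For a constant signal (sigma = 0), which cannot be standardized.
    """
    mu = float(np.mean(rec.samples))
    sigma = float(np.std(rec.samples))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise ValueError("degenerate signal: zero variance, cannot z-score")
    normalized = (rec.samples - mu) / sigma
    return (
        EEGRecording(rec.subject_id, rec.channel, rec.fs, normalized),
        NormalizationStats(mu_s=mu, sigma_s=sigma),
    )


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase resampling to ``target_fs`` with anti-alias filtering.

    Duration is preserved to within one sample period.  Resampling to the
    current rate is the identity.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return EEGRecording(rec.subject_id, rec.channel, rec.fs, rec.samples.copy())
    from fractions import Fraction

    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    resampled = sps.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return EEGRecording(rec.subject_id, rec.channel, target_fs, resampled)
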