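"""The modulation spectrogram: subband Hilbert envelopes Fourier-analysed.

Pipeline per analysis window: (i) decompose the preprocessed signal into
carrier subbands (either the five AASM bands delta/theta/alpha/sigma/beta or
a fine contiguous filterbank, 44 equal-width bins over 0.5-30 Hz by
default); (ii) take the magnitude of the analytic (Hilbert) signal of each
band as its instantaneous-amplitude envelope; (iii) low-pass the envelopes
at 10 Hz and downsample to 20 Hz, bounding representable modulation
frequencies at 10 Hz; (iv) Fourier-transform each mean-removed envelope
(rectangular window) to obtain one carrier row of the carrier x modulation
energy matrix; (v) clip to the 6-99.6 percentile range, map affinely to
[0, 1] and render as an H x W x 3 image at one of three resolutions.

The mean is removed before the envelope FFT so the DC bin cannot dominate
the percentile normalization; bin 0 is re-filled with the envelope mean
magnitude so an unmodulated carrier still registers in its row.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sps

from .io_formats import EEGRecording
from .windowing import EpochWindow

#: The three supported (height, width) image resolutions.
RESOLUTIONS: dict[str, tuple[int, int]] = {
    "76x60": (76, 60),
    "152x120": (152, 120),
    "224x224": (224, 224),
}

AASM_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("sigma", 12.0, 15.0),
    ("beta", 15.0, 30.0),
)


@dataclasses.dataclass(frozen=True)
class SubbandDefinition:
    """A carrier subband [f_low, f_high) of the analysis filterbank."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"need 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


@dataclasses.dataclass
class ModulationSpectrogram:
    """Carrier x modulation energy matrix with axis metadata."""

    values: np.ndarray  # (n_bands, n_mod_freqs), non-negative
    carrier_centers_hz: np.ndarray
    mod_freqs_hz: np.ndarray
    window_length_s: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.carrier_centers_hz = np.asarray(self.carrier_centers_hz, dtype=np.float64)
        self.mod_freqs_hz = np.asarray(self.mod_freqs_hz, dtype=np.float64)
        if self.values.shape != (self.carrier_centers_hz.size, self.mod_freqs_hz.size):
            raise ValueError("values shape must match axis lengths")
        if np.any(self.values < 0):
            raise ValueError("modulation energies must be non-negative")


@dataclasses.dataclass
class FeatureImage:
    """Normalized H x W x 3 image in [0, 1] with its stage label."""

    pixels: np.ndarray
    resolution: str
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        expected = RESOLUTIONS[self.resolution] + (3,)
        if self.pixels.shape != expected:
            raise ValueError(f"pixels shape {self.pixels.shape} != {expected}")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("pixels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Filterbank
# ---------------------------------------------------------------------------


def design_filterbank(
    mode: str = "fine",
    n_bins: int = 44,
    f_min: float = 0.5,
    f_max: float = 30.0,
) -> list[SubbandDefinition]:
    """Carrier filterbank: the five named AASM bands or a fine partition.

    ``aasm5`` returns delta/theta/alpha/sigma/beta; ``fine`` returns
    ``n_bins`` contiguous equal-width bins spanning [f_min, f_max] (default
    44 bins over 0.5-30 Hz, the configuration used for feature images).
    """
    if mode == "aasm5":
        return [SubbandDefinition(name, lo, hi) for name, lo, hi in AASM_BANDS]
    if mode != "fine":
        raise ValueError(f"unknown filterbank mode {mode!r}")
    if n_bins < 1 or not f_min < f_max:
        raise ValueError("fine mode needs n_bins >= 1 and f_min < f_max")
    edges = np.linspace(f_min, f_max, n_bins + 1)
    return [
        SubbandDefinition(f"bin-{k}", float(edges[k]), float(edges[k + 1]))
        for k in range(n_bins)
    ]


def _band_sos(band: SubbandDefinition, fs: float, order: int = 4) -> np.ndarray:
    if fs <= 2 * band.f_high:
        raise ValueError(
            f"band {band.name} [{band.f_low}, {band.f_high}] Hz exceeds Nyquist at fs={fs}"
        )
    return sps.butter(order, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos")


def band_envelope(
    signal: np.ndarray,
    fs: float,
    band: SubbandDefinition,
    lp_cutoff: float = 10.0,
    env_fs: float = 20.0,
) -> np.ndarray:
    """Subband Hilbert envelope, low-passed and downsampled to ``env_fs``.

    The band-filtered signal's analytic magnitude is low-pass filtered at
    ``lp_cutoff`` (which doubles as the anti-alias filter), small negative
    filtering excursions are clipped at 0, and the result is decimated by
    index selection to exactly ``env_fs`` samples per second.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2 * fs:
        raise ValueError("need at least 2 s of samples for envelope extraction")
    sos = _band_sos(band, fs)
    banded = sps.sosfiltfilt(sos, signal)
    analytic = sps.hilbert(banded)
    env = np.abs(analytic)
    lp = sps.butter(4, lp_cutoff, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(lp, env)
    env = np.clip(env, 0.0, None)
    factor = fs / env_fs
    if abs(factor - round(factor)) < 1e-9:
        env = env[:: int(round(factor))]
    else:  # non-integer ratio: polyphase fallback
        from fractions import Fraction

        frac = Fraction(env_fs / fs).limit_denominator(1000)
        env = np.clip(sps.resample_poly(env, frac.numerator, frac.denominator), 0.0, None)
    return env


def modulation_spectrum(
    envelope: np.ndarray, env_fs: float = 20.0, max_mod_hz: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a mean-removed envelope.

    Rectangular window; bin spacing ``env_fs / N``.  Non-DC bins carry the
    amplitude (2/N scaling) of the corresponding envelope oscillation; bin 0
    holds the envelope mean magnitude.  Frequencies above ``max_mod_hz`` (the
    envelope Nyquist for env_fs = 20 Hz) are truncated.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    n = envelope.size
    if n < 2:
        raise ValueError("envelope must have at least 2 samples")
    mean = envelope.mean()
    spec = np.fft.rfft(envelope - mean)
    mags = (2.0 / n) * np.abs(spec)
    mags[0] = abs(mean)
    freqs = np.fft.rfftfreq(n, d=1.0 / env_fs)
    keep = freqs <= max_mod_hz + 1e-12
    return freqs[keep], mags[keep]


def compute_modulation_spectrogram(
    window: EpochWindow,
    rec: EEGRecording,
    filterbank: list[SubbandDefinition] | None = None,
    lp_cutoff: float = 10.0,
    env_fs: float = 20.0,
) -> ModulationSpectrogram:
    """Full modulation spectrogram of one analysis window.

    ``rec`` should already be band-passed and z-scored.  Row b is the
    modulation spectrum of subband b's envelope over the window's samples.
    """
    if filterbank is None:
        filterbank = design_filterbank()
    sl = window.sample_slice(rec.fs)
    if sl.start < 0 or sl.stop > rec.samples.size:
        raise ValueError("window exceeds recording bounds")
    segment = rec.samples[sl]
    rows = []
    freqs_ref: np.ndarray | None = None
    for band in filterbank:
        env = band_envelope(segment, rec.fs, band, lp_cutoff, env_fs)
        freqs, mags = modulation_spectrum(env, env_fs)
        rows.append(mags)
        freqs_ref = freqs
    return ModulationSpectrogram(
        values=np.vstack(rows),
        carrier_centers_hz=np.array([b.center_hz for b in filterbank]),
        mod_freqs_hz=freqs_ref,
        window_length_s=window.length_s,
        normalization="raw",
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _resize_bilinear(matrix: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    from PIL import Image

    img = Image.fromarray(matrix.astype(np.float32), mode="F")
    h, w = out_hw
    resized = img.resize((w, h), resample=Image.BILINEAR)
    return np.asarray(resized, dtype=np.float64)


def normalize_and_render(
    ms: ModulationSpectrogram,
    p_lo: float = 6.0,
    p_hi: float = 99.6,
    resolution: str = "152x120",
    label: str = "W",
) -> FeatureImage:
    """Percentile-clip, scale to [0, 1] and render at a target resolution.

    Values are clipped to the [p_lo, p_hi] percentiles of the matrix and
    mapped affinely onto [0, 1] (scale-invariant contrast enhancement), then
    resized bilinearly with carrier frequency on the vertical axis (low
    frequencies at the bottom of the image) and modulation frequency
    increasing rightward, and replicated onto 3 identical channels.  A
    constant matrix renders as all-0.5 with a warning.
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution {resolution!r}; use one of {list(RESOLUTIONS)}")
    values = np.asarray(ms.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("modulation spectrogram contains non-finite values")
    lo, hi = np.percentile(values, [p_lo, p_hi])
    if hi <= lo:
        warnings.warn("constant modulation spectrogram; rendering mid-gray image")
        h, w = RESOLUTIONS[resolution]
        return FeatureImage(np.full((h, w, 3), 0.5), resolution, label)
    scaled = (np.clip(values, lo, hi) - lo) / (hi - lo)
    # image row 0 = top = highest carrier frequency
    flipped = scaled[::-1, :]
    resized = np.clip(_resize_bilinear(flipped, RESOLUTIONS[resolution]), 0.0, 1.0)
    span = resized.max() - resized.min()
    if span > 0:  # re-stretch: interpolation shrinks the extremes
        resized = (resized - resized.min()) / span
    pixels = np.repeat(resized[:, :, None], 3, axis=2)
    return FeatureImage(pixels, resolution, label)


# ---------------------------------------------------------------------------
# Batch extraction
# ---------------------------------------------------------------------------


class ModulationExtractor:
    """Whole-recording subband envelopes, sliced per window.

    Filtering and Hilbert demodulation run once on the continuous
    preprocessed recording (avoiding per-window filter transients), then
    each window's envelope segment at 20 Hz is Fourier-analysed.  This is
    the fast path used for cohort-scale feature generation; results agree
    with :func:`compute_modulation_spectrogram` up to boundary transients.
    """

    def __init__(
        self,
        rec: EEGRecording,
        filterbank: list[SubbandDefinition] | None = None,
        lp_cutoff: float = 10.0,
        env_fs: float = 20.0,
    ) -> None:
        self.filterbank = filterbank if filterbank is not None else design_filterbank()
        self.env_fs = env_fs
        self.rec = rec
        self._envelopes = np.vstack(
            [
                band_envelope(rec.samples, rec.fs, band, lp_cutoff, env_fs)
                for band in self.filterbank
            ]
        )
        self.carrier_centers_hz = np.array([b.center_hz for b in self.filterbank])

    def spectrogram(self, window: EpochWindow) -> ModulationSpectrogram:
        i0 = int(round(window.start_s * self.env_fs))
        i1 = int(round(window.end_s * self.env_fs))
        if i0 < 0 or i1 > self._envelopes.shape[1]:
            raise ValueError("window exceeds recording bounds")
        rows = []
        freqs_ref = None
        for env in self._envelopes[:, i0:i1]:
            freqs, mags = modulation_spectrum(env, self.env_fs)
            rows.append(mags)
            freqs_ref = freqs
        return ModulationSpectrogram(
            values=np.vstack(rows),
            carrier_centers_hz=self.carrier_centers_hz,
            mod_freqs_hz=freqs_ref,
            window_length_s=window.length_s,
        )

    def feature_image(
        self, window: EpochWindow, resolution: str = "152x120"
    ) -> FeatureImage:
        ms = self.spectrogram(window)
        return normalize_and_render(ms, resolution=resolution, label=window.label)
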