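import numpy as np
import pytest

from sleepmod import EEGRecording, bandpass_filter, zscore_normalize
from sleepmod.modulation_features import (
    ModulationExtractor,
    ModulationSpectrogram,
    SubbandDefinition,
    band_envelope,
    compute_modulation_spectrogram,
    design_filterbank,
    modulation_spectrum,
    normalize_and_render,
)
from sleepmod.windowing import EpochWindow

from conftest import am_signal


def dft_oracle(envelope, env_fs=20.0, max_mod_hz=10.0):
    """Brute-force DFT of the mean-removed envelope (independent of rfft)."""
    env = np.asarray(envelope, dtype=np.float64)
    n = env.size
    y = env - env.mean()
    ks = np.arange(n // 2 + 1)
    mags = np.empty(ks.size)
    t = np.arange(n)
    for k in ks:
        c = np.sum(y * np.exp(-2j * np.pi * k * t / n))
        mags[k] = (2.0 / n) * abs(c)
    mags[0] = abs(env.mean())
    freqs = ks * env_fs / n
    keep = freqs <= max_mod_hz + 1e-12
    return freqs[keep], mags[keep]


def preprocessed(x, fs=100.0):
    rec = EEGRecording("s", "C4-M1", fs, x)
    out, _ = zscore_normalize(bandpass_filter(rec))
    return out


class TestFilterbank:
    def test_aasm5_bands(self):
        fb = design_filterbank("aasm5")
        assert [(b.f_low, b.f_high) for b in fb] == [
            (0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 15.0), (15.0, 30.0)
        ]
        assert [b.name for b in fb] == ["delta", "theta", "alpha", "sigma", "beta"]

    def test_fine_partition_contiguous(self):
        fb = design_filterbank("fine", 44, 0.5, 30.0)
        assert len(fb) == 44
        widths = [b.f_high - b.f_low for b in fb]
        np.testing.assert_allclose(widths, (30.0 - 0.5) / 44)
        for a, b in zip(fb, fb[1:]):
            assert a.f_high == pytest.approx(b.f_low)

    def test_single_bin_is_full_range(self):
        (b,) = design_filterbank("fine", 1, 0.5, 30.0)
        assert (b.f_low, b.f_high) == (0.5, 30.0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            design_filterbank("fine", 4, 10.0, 2.0)


class TestBandEnvelope:
    def test_am_envelope_matches_closed_form(self):
        fs = 100.0
        x = am_signal(13.5, 1.0, depth=0.8, fs=fs)
        env = band_envelope(x, fs, SubbandDefinition("sigma", 12, 15))
        t = np.arange(env.size) / 20.0
        ref = 1 + 0.8 * np.cos(2 * np.pi * 1.0 * t)
        sl = slice(20, -20)  # discard 1 s edges
        err = np.sqrt(np.mean((env[sl] - ref[sl]) ** 2)) / np.sqrt(np.mean(ref[sl] ** 2))
        assert err < 0.05

    def test_unmodulated_tone_has_flat_envelope(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        a = 2.7
        env = band_envelope(a * np.cos(2 * np.pi * 10 * t), fs, SubbandDefinition("alpha", 8, 12))
        core = env[40:-40]
        assert core.std() / core.mean() < 0.02
        assert core.mean() == pytest.approx(a, rel=0.05)

    def test_envelope_rate_and_length(self):
        fs = 100.0
        x = am_signal(10.0, 1.0, fs=fs, duration_s=60.0)
        env = band_envelope(x, fs, SubbandDefinition("alpha", 8, 12))
        assert env.size == 1200  # 60 s * 20 Hz
        assert np.all(env >= 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_envelope(np.zeros(500), 50.0, SubbandDefinition("beta", 15, 30))


class TestModulationSpectrum:
    def test_oracle_equivalence_on_random_envelopes(self, rng):
        for _ in range(20):
            n = int(rng.integers(40, 400))
            env = np.abs(rng.standard_normal(n)) + 0.1
            freqs, mags = modulation_spectrum(env)
            freqs_o, mags_o = dft_oracle(env)
            np.testing.assert_allclose(freqs, freqs_o, atol=1e-12)
            np.testing.assert_allclose(mags, mags_o, rtol=1e-9, atol=1e-12)

    def test_pure_modulation_peak(self):
        t = np.arange(0, 60, 1 / 20.0)
        env = 1 + 0.8 * np.cos(2 * np.pi * 1.0 * t)
        freqs, mags = modulation_spectrum(env)
        nz = mags.copy()
        nz[0] = 0
        assert freqs[nz.argmax()] == pytest.approx(1.0, abs=1 / 60)
        assert mags[0] == pytest.approx(1.0, rel=1e-6)  # DC = envelope mean

    def test_constant_envelope_only_dc(self):
        freqs, mags = modulation_spectrum(np.full(600, 3.0))
        assert np.all(mags[1:] < 1e-9 * mags[0])

    def test_two_component_amplitude_ratio(self):
        t = np.arange(0, 60, 1 / 20.0)
        env = 2 + 1.0 * np.cos(2 * np.pi * 0.5 * t) + 0.5 * np.cos(2 * np.pi * 2.0 * t)
        freqs, mags = modulation_spectrum(env)
        i1 = np.argmin(np.abs(freqs - 0.5))
        i2 = np.argmin(np.abs(freqs - 2.0))
        assert mags[i1] / mags[i2] == pytest.approx(2.0, rel=0.05)

    def test_nyquist_bound(self):
        freqs, _ = modulation_spectrum(np.random.default_rng(0).random(1200))
        assert freqs.max() <= 10.0 + 1e-12


class TestModulationSpectrogram:
    def test_spindle_like_signal_peaks_in_sigma_row(self, rng):
        fs = 100.0
        x = am_signal(13.0, 0.7, depth=0.8, fs=fs) + 0.05 * rng.standard_normal(6000)
        rec = preprocessed(x, fs)
        w = EpochWindow(0, 0, 60, "N2", "fixed")
        ms = compute_modulation_spectrogram(w, rec, design_filterbank("aasm5"))
        nz = ms.values.copy()
        nz[:, 0] = 0
        i, j = np.unravel_index(nz.argmax(), nz.shape)
        assert i == 3  # sigma row
        assert ms.mod_freqs_hz[j] == pytest.approx(0.7, abs=1 / 60)

    def test_unmodulated_delta_tone_concentrates_at_dc(self):
        # analysed away from the recording edges so filter transients do not
        # masquerade as envelope modulation
        fs = 100.0
        t = np.arange(0, 180, 1 / fs)
        rec = preprocessed(np.cos(2 * np.pi * 2 * t), fs)
        ex = ModulationExtractor(rec, design_filterbank("aasm5"))
        ms = ex.spectrogram(EpochWindow(2, 60, 120, "N3", "fixed"))
        dominant = ms.values[:, 0].argmax()
        assert dominant == 0  # delta row
        row = ms.values[dominant]
        assert row[1:].max() < 0.01 * row[0]  # no modulation bin stands out

    def test_shape_contract(self, noisy_recording):
        rec, _ = zscore_normalize(bandpass_filter(noisy_recording))
        w = EpochWindow(0, 0, 60, "W", "fixed")
        ms = compute_modulation_spectrogram(w, rec, design_filterbank("aasm5"))
        assert ms.values.shape == (5, int(10 / (1 / 60)) + 1)
        assert np.all(ms.values >= 0)
        assert ms.mod_freqs_hz[1] - ms.mod_freqs_hz[0] == pytest.approx(1 / 60)

    def test_out_of_bounds_window_rejected(self, tone_recording):
        rec, _ = zscore_normalize(bandpass_filter(tone_recording))
        w = EpochWindow(2, 60, 120, "W", "fixed")
        with pytest.raises(ValueError, match="bounds"):
            compute_modulation_spectrogram(w, rec)

    def test_extractor_agrees_with_per_window_path(self, rng):
        fs = 100.0
        x = am_signal(13.0, 0.7, depth=0.8, fs=fs, duration_s=90.0)
        rec = preprocessed(x, fs)
        fb = design_filterbank("aasm5")
        w = EpochWindow(1, 30, 60, "N2", "fixed")
        direct = compute_modulation_spectrogram(w, rec, fb)
        batch = ModulationExtractor(rec, fb).spectrogram(w)
        # same geometry and the same spectral localization; values agree up
        # to per-window filter edge transients
        assert batch.values.shape == direct.values.shape
        for values in (direct.values, batch.values):
            nz = values.copy()
            nz[:, 0] = 0
            i, j = np.unravel_index(nz.argmax(), nz.shape)
            assert i == 3  # sigma carrier row
            assert direct.mod_freqs_hz[j] == pytest.approx(0.7, abs=1 / 30)
        corr = np.corrcoef(direct.values[:, 1:].ravel(), batch.values[:, 1:].ravel())[0, 1]
        assert corr > 0.8


class TestRendering:
    def _ms(self, values):
        values = np.asarray(values, dtype=float)
        return ModulationSpectrogram(
            values=values,
            carrier_centers_hz=np.arange(values.shape[0], dtype=float) + 1,
            mod_freqs_hz=np.linspace(0, 10, values.shape[1]),
            window_length_s=60,
        )

    def test_hot_cell_full_range(self, rng):
        values = rng.random((44, 601)) * 0.1
        values[20, 300] = 50.0
        img = normalize_and_render(self._ms(values), resolution="152x120")
        assert img.pixels.max() == pytest.approx(1.0)
        assert img.pixels.min() == pytest.approx(0.0)

    @pytest.mark.parametrize("resolution,shape", [
        ("76x60", (76, 60, 3)), ("152x120", (152, 120, 3)), ("224x224", (224, 224, 3)),
    ])
    def test_output_geometry(self, rng, resolution, shape):
        img = normalize_and_render(self._ms(rng.random((44, 601))), resolution=resolution)
        assert img.pixels.shape == shape
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    def test_scale_invariance(self, rng):
        values = rng.random((5, 61))
        a = normalize_and_render(self._ms(values), resolution="76x60")
        b = normalize_and_render(self._ms(10 * values), resolution="76x60")
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-9)

    def test_constant_matrix_mid_gray(self):
        with pytest.warns(UserWarning, match="constant"):
            img = normalize_and_render(self._ms(np.ones((5, 61))), resolution="76x60")
        assert np.all(img.pixels == 0.5)

    def test_resolutions_share_content(self, rng):
        # same spectrogram at the three sizes: downscaled versions correlate
        from PIL import Image

        values = rng.random((44, 601))
        imgs = {
            res: normalize_and_render(self._ms(values), resolution=res).pixels[:, :, 0]
            for res in ("76x60", "152x120", "224x224")
        }
        small = imgs["76x60"]
        for res in ("152x120", "224x224"):
            big = Image.fromarray(imgs[res].astype(np.float32), mode="F")
            down = np.asarray(big.resize((60, 76), resample=Image.BILINEAR))
            corr = np.corrcoef(small.ravel(), down.ravel())[0, 1]
            assert corr > 0.95
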