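import numpy as np
import pytest
from scipy import signal as sps

from sleepmod import bandpass_filter, zscore_normalize
from sleepmod.evaluation import stratify_by_ahi
from sleepmod.io_formats import STAGES
from sleepmod.modulation_features import compute_modulation_spectrogram, design_filterbank
from sleepmod.synthetic_data import (
    CohortSpec,
    NearestCentroidStager,
    band_power_features,
    default_transition_matrix,
    fragmented_transition_matrix,
    generate_cohort,
    generate_hypnogram,
    generate_recording,
    synth_stage_signal,
    transitions_per_hour,
)
from sleepmod.windowing import EpochWindow, assign_adaptive_windows, extended_fraction


class TestHypnogramGeneration:
    def test_seed_determinism(self):
        a = generate_hypnogram(500, seed=4)
        b = generate_hypnogram(500, seed=4)
        assert a.labels == b.labels

    def test_sticky_chain_run_length(self):
        tm = np.full((5, 5), 0.0025)
        np.fill_diagonal(tm, 0.99)
        h = generate_hypnogram(10_000, tm, seed=0)
        labels = h.labels
        runs, current = [], 1
        for a, b in zip(labels, labels[1:]):
            if a == b:
                current += 1
            else:
                runs.append(current)
                current = 1
        runs.append(current)
        assert np.mean(runs) == pytest.approx(100, rel=0.2)  # 1/(1-0.99)

    def test_uniform_chain_stage_frequencies(self):
        tm = np.full((5, 5), 0.2)
        h = generate_hypnogram(10_000, tm, seed=1)
        freqs = np.array([h.labels.count(s) for s in STAGES]) / len(h)
        np.testing.assert_allclose(freqs, 0.2, atol=0.03)

    def test_invalid_matrix_rejected(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            generate_hypnogram(10, bad, seed=0)


class TestStageSignals:
    def test_n3_is_delta_dominated(self):
        fs = 100.0
        x = synth_stage_signal("N3", 60.0, fs, seed=2)
        freqs, psd = sps.welch(x, fs=fs, nperseg=1024)
        band = lambda lo, hi: np.trapezoid(psd[(freqs >= lo) & (freqs < hi)],
                                           freqs[(freqs >= lo) & (freqs < hi)])
        assert band(0.5, 4) / band(0.5, 30) >= 0.6

    def test_n2_spindle_modulation_recovered_end_to_end(self):
        from sleepmod.io_formats import EEGRecording

        fs = 100.0
        x = synth_stage_signal("N2", 60.0, fs, seed=3)
        rec, _ = zscore_normalize(bandpass_filter(EEGRecording("s", "c", fs, x)))
        ms = compute_modulation_spectrogram(
            EpochWindow(0, 0, 60, "N2", "fixed"), rec, design_filterbank("aasm5")
        )
        nz = ms.values.copy()
        nz[:, 0] = 0
        i, j = np.unravel_index(nz.argmax(), nz.shape)
        assert i == 3  # sigma carrier row
        assert ms.mod_freqs_hz[j] == pytest.approx(0.7, abs=1.5 / 60)

    def test_zero_depth_concentrates_at_dc(self):
        from sleepmod.synthetic_data import StageComponent, StageSignalSpec

        comps = {
            s: (StageComponent(10.0, 1.0, 1.0, 0.0),) for s in STAGES
        }
        spec = StageSignalSpec(components=comps, noise_level=0.0)
        x = synth_stage_signal("N2", 60.0, 100.0, spec, seed=1)
        from sleepmod.modulation_features import SubbandDefinition, band_envelope, modulation_spectrum

        env = band_envelope(x, 100.0, SubbandDefinition("alpha", 8, 12))
        _, mags = modulation_spectrum(env)
        assert mags[1:].max() < 0.05 * mags[0]

    def test_seed_determinism(self):
        a = synth_stage_signal("R", 30.0, 100.0, seed=9)
        b = synth_stage_signal("R", 30.0, 100.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestRecordingGeneration:
    def test_length_arithmetic(self):
        h = generate_hypnogram(10, seed=0)
        rec = generate_recording(h, fs=100.0, seed=1)
        assert rec.samples.size == 30_000

    def test_stage_labels_recoverable_by_band_power(self):
        h = generate_hypnogram(200, seed=5)
        rec = generate_recording(h, fs=100.0, seed=6)
        feats = band_power_features(rec)
        clf = NearestCentroidStager().fit(feats, h.labels)
        pred = clf.predict(feats)
        acc = np.mean([p == t for p, t in zip(pred, h.labels)])
        assert acc >= 0.90

    def test_seed_determinism(self):
        h = generate_hypnogram(5, seed=0)
        a = generate_recording(h, fs=100.0, seed=3)
        b = generate_recording(h, fs=100.0, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestCohorts:
    def test_cohort_structure_and_stratification(self, tmp_path):
        spec = CohortSpec(n_subjects_per_cohort=3, epochs_per_subject=20, seed=11)
        table, data = generate_cohort(spec, out_dir=tmp_path)
        assert len(table.subject_ids) == 12
        recovered = {c.subject_id: c.cohort for c in stratify_by_ahi(table)}
        intended = dict(zip(table.frame["subject_id"], table.frame["cohort"]))
        assert recovered == intended
        # files on disk
        assert (tmp_path / "subjects.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        assert len(list(tmp_path.glob("S*.npz"))) == 12

    def test_fragmentation_monotone_in_ahi(self):
        tm = default_transition_matrix()
        rates = []
        for ahi in [2.5, 10.0, 22.0, 45.0]:
            tmf = fragmented_transition_matrix(tm, ahi, 0.04)
            hyps = [generate_hypnogram(500, tmf, seed=s) for s in range(5)]
            rates.append(np.mean([transitions_per_hour(h) for h in hyps]))
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_severe_cohort_has_more_adaptive_fallbacks(self):
        spec = CohortSpec(n_subjects_per_cohort=5, epochs_per_subject=500,
                          cohorts=("Normal", "Severe"), seed=2)
        table, data = generate_cohort(spec)
        frac = {"Normal": [], "Severe": []}
        for _, row in table.frame.iterrows():
            _, hyp = data[row["subject_id"]]
            windows = assign_adaptive_windows(hyp)
            frac[row["cohort"]].append(1.0 - extended_fraction(windows))
        assert np.mean(frac["Severe"]) > np.mean(frac["Normal"])

    def test_pure_function_of_seed(self):
        spec = CohortSpec(n_subjects_per_cohort=1, epochs_per_subject=10, seed=7)
        t1, d1 = generate_cohort(spec)
        t2, d2 = generate_cohort(spec)
        assert t1.frame.equals(t2.frame)
        for sid in d1:
            np.testing.assert_array_equal(d1[sid][0].samples, d2[sid][0].samples)
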