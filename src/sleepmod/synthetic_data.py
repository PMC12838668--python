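"""Synthetic stage-labeled sleep EEG with the structure the method assumes.

Each stage is rendered as a sum of amplitude-modulated sinusoids plus
1/f-shaped background noise:

    sum_k  a_k * (1 + d_k * cos(2*pi*f_m,k*t + phi)) * cos(2*pi*f_c,k*t + psi)

with stage-specific carrier bands (delta slow waves in N3, 12-15 Hz spindles
with waxing-waning envelopes in N2, alpha in relaxed wake, mixed theta/beta
in REM).  Hypnograms are first-order Markov chains over the five stages;
apnea severity enters through the Apnea-Hypopnea Index (AHI): off-diagonal
transition probabilities are scaled by ``1 + fragmentation_gain * AHI``
(more stage transitions) and each sleep epoch receives a Poisson number of
brief high-amplitude alpha/beta arousal bursts with rate proportional to the
AHI, emulating post-event micro-arousals.  Every generator is a pure
function of (spec, seed).

The module also provides a deliberately simple relative band-power
nearest-centroid stager used as a separability oracle for the generated data
and as a stage-agnostic baseline in cohort-robustness experiments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import (
    EPOCH_DURATION_S,
    STAGES,
    EEGRecording,
    Hypnogram,
    SubjectTable,
    write_hypnogram,
    write_recording,
    write_subject_table,
)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StageComponent:
    """One amplitude-modulated oscillation of a stage signature."""

    carrier_hz: float
    amplitude: float
    mod_rate_hz: float
    mod_depth: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or not 0 <= self.mod_depth <= 1:
            raise ValueError("amplitude >= 0 and mod_depth in [0, 1] required")
        if self.mod_rate_hz > 10:
            raise ValueError("modulation rates above 10 Hz are not representable")


@dataclasses.dataclass(frozen=True)
class StageSignalSpec:
    """Per-stage oscillatory components plus broadband 1/f noise level."""

    components: dict[str, tuple[StageComponent, ...]]
    noise_level: float = 0.5

    def __post_init__(self) -> None:
        for stage in STAGES:
            if stage not in self.components:
                raise ValueError(f"missing stage {stage} in StageSignalSpec")


def default_stage_spec() -> StageSignalSpec:
    """Stage signatures following the canonical sleep-EEG band picture.

    W: alpha (10 Hz) with beta; N1: low-voltage theta with residual alpha;
    N2: 13 Hz spindles with a 0.7 Hz waxing-waning envelope over a theta/
    delta background; N3: dominant high-amplitude slow waves (<4 Hz);
    R(EM): desynchronized mixed theta/beta, no spindles, higher noise floor.
    """
    c = StageComponent
    return StageSignalSpec(
        components={
            "W": (c(10.0, 1.0, 1.0, 0.3), c(22.0, 0.55, 2.0, 0.3)),
            "N1": (c(6.0, 0.9, 0.6, 0.4), c(9.5, 0.35, 1.0, 0.3)),
            "N2": (c(13.0, 1.0, 0.7, 0.8), c(2.5, 0.55, 0.5, 0.4), c(6.0, 0.4, 0.6, 0.3)),
            "N3": (c(1.5, 2.6, 0.4, 0.5), c(13.0, 0.25, 0.7, 0.6)),
            "R": (c(4.5, 0.8, 1.2, 0.4), c(25.0, 0.6, 3.0, 0.4)),
        },
        noise_level=0.45,
    )


def default_transition_matrix() -> np.ndarray:
    """Baseline (healthy) stage-transition matrix, order W, N1, N2, N3, R.

    Self-transitions dominate (epoch-scale stage persistence); adjacency
    loosely follows normal adult dynamics (W<->N1, N1->N2, N2<->N3, R
    entered from N2).  Values are package constants chosen for balanced
    stage coverage on desk-scale simulations, not claims about any dataset.
    """
    return np.array(
        [
            # W     N1    N2    N3    R
            [0.86, 0.09, 0.03, 0.00, 0.02],  # W
            [0.06, 0.80, 0.11, 0.00, 0.03],  # N1
            [0.02, 0.03, 0.87, 0.05, 0.03],  # N2
            [0.01, 0.01, 0.09, 0.89, 0.00],  # N3
            [0.03, 0.04, 0.05, 0.00, 0.88],  # R
        ]
    )


def _default_ahi_samplers() -> dict[str, tuple[float, float]]:
    # Uniform AHI ranges per severity cohort (events/hour).
    return {
        "Normal": (0.5, 4.5),
        "Mild": (5.0, 14.5),
        "Moderate": (15.0, 29.5),
        "Severe": (30.0, 60.0),
    }


@dataclasses.dataclass
class CohortSpec:
    """Recipe for a synthetic multi-subject cohort.

    ``fragmentation_gain`` multiplies off-diagonal transition probabilities
    by ``1 + gain * AHI`` (rows renormalized); ``arousal_rate_per_event``
    converts AHI (events/hour) into the expected number of arousal bursts
    per 30 s epoch (1.0 = one burst per respiratory event).
    """

    n_subjects_per_cohort: int = 3
    epochs_per_subject: int = 200
    fs: float = 100.0
    cohorts: tuple[str, ...] = ("Normal", "Mild", "Moderate", "Severe")
    ahi_ranges: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=_default_ahi_samplers
    )
    transition_matrix: np.ndarray = dataclasses.field(
        default_factory=default_transition_matrix
    )
    stage_spec: StageSignalSpec = dataclasses.field(default_factory=default_stage_spec)
    fragmentation_gain: float = 0.04
    arousal_rate_per_event: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_transition_matrix(self.transition_matrix)
        if self.fragmentation_gain < 0:
            raise ValueError("fragmentation_gain must be >= 0")


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------


def _validate_transition_matrix(tm: np.ndarray) -> None:
    tm = np.asarray(tm, dtype=float)
    if tm.shape != (5, 5) or np.any(tm < 0):
        raise ValueError("transition matrix must be 5x5 and non-negative")
    if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")


def generate_hypnogram(
    n_epochs: int,
    transition_matrix: np.ndarray | None = None,
    seed: int = 0,
    initial_stage: str = "W",
) -> Hypnogram:
    """Markov-chain hypnogram over the five stages, seed-deterministic."""
    if transition_matrix is None:
        transition_matrix = default_transition_matrix()
    tm = np.asarray(transition_matrix, dtype=float)
    _validate_transition_matrix(tm)
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    state = STAGES.index(initial_stage)
    labels = []
    for _ in range(n_epochs):
        labels.append(STAGES[state])
        state = rng.choice(5, p=tm[state])
    return Hypnogram(subject_id=f"sim-seed{seed}", labels=labels)


def fragmented_transition_matrix(
    tm: np.ndarray, ahi: float, fragmentation_gain: float
) -> np.ndarray:
    """Scale off-diagonal transition probabilities by ``1 + gain * AHI``.

    Rows are renormalized; self-transitions absorb the complement, floored
    at 0.05 so runs never collapse to single epochs entirely.
    """
    tm = np.asarray(tm, dtype=float).copy()
    factor = 1.0 + fragmentation_gain * ahi
    out = np.zeros_like(tm)
    for i in range(5):
        off = tm[i].copy()
        off[i] = 0.0
        off = off * factor
        total_off = min(off.sum(), 0.95)
        if off.sum() > 0:
            off = off * (total_off / off.sum())
        out[i] = off
        out[i, i] = 1.0 - total_off
    return out


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power-shaped Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def synth_stage_signal(
    stage: str,
    duration_s: float,
    fs: float,
    spec: StageSignalSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One stage's signal: AM sinusoids plus 1/f noise, seed-deterministic."""
    if spec is None:
        spec = default_stage_spec()
    if stage not in spec.components:
        raise ValueError(f"unknown stage {stage!r}")
    comps = spec.components[stage]
    for comp in comps:
        if fs <= 2 * comp.carrier_hz:
            raise ValueError(
                f"fs={fs} too low for carrier {comp.carrier_hz} Hz (need fs > 2*fc)"
            )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for comp in comps:
        phi = rng.uniform(0, 2 * np.pi)
        psi = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + comp.mod_depth * np.cos(2 * np.pi * comp.mod_rate_hz * t + phi)
        x += comp.amplitude * envelope * np.cos(2 * np.pi * comp.carrier_hz * t + psi)
    x += spec.noise_level * _pink_noise(n, rng)
    return x


def _arousal_burst(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """A 2-5 s high-amplitude alpha+beta burst with a Hann envelope."""
    dur = rng.uniform(2.0, 5.0)
    m = min(int(dur * fs), n)
    t = np.arange(m) / fs
    burst = 2.5 * (
        np.cos(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        + 0.8 * np.cos(2 * np.pi * 20.0 * t + rng.uniform(0, 2 * np.pi))
    )
    burst *= np.hanning(m)
    out = np.zeros(n)
    start = rng.integers(0, max(n - m, 1))
    out[start : start + m] += burst
    return out


def generate_recording(
    h: Hypnogram,
    spec: StageSignalSpec | None = None,
    fs: float = 100.0,
    seed: int = 0,
    arousals_per_epoch: float = 0.0,
) -> EEGRecording:
    """Concatenate per-epoch stage signals with 0.5 s cross-fades.

    ``arousals_per_epoch`` is the Poisson rate of superimposed arousal
    bursts per sleep (non-W) epoch; labels are left unchanged, as a scorer
    keeps the epoch's majority stage through a brief micro-arousal.
    Output length is exactly ``30 s * n_epochs * fs`` samples.
    """
    if spec is None:
        spec = default_stage_spec()
    rng = np.random.default_rng(seed)
    d = h.epoch_duration_s
    n_ep = int(round(d * fs))
    fade = int(round(0.5 * fs))
    total = n_ep * len(h)
    x = np.zeros(total)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))  # 0 -> 1
    for i, stage in enumerate(h.labels):
        seg_seed = int(rng.integers(0, 2**31 - 1))
        seg = synth_stage_signal(stage, d + 0.5, fs, spec, seed=seg_seed)
        if stage != "W" and arousals_per_epoch > 0:
            for _ in range(rng.poisson(arousals_per_epoch)):
                seg[:n_ep] += _arousal_burst(n_ep, fs, rng)
        start = i * n_ep
        if i == 0:
            x[start : start + n_ep] = seg[:n_ep]
        else:
            # cross-fade the first 0.5 s of this epoch over the previous tail
            head = seg[:fade] * ramp
            x[start : start + fade] = x[start : start + fade] * (1 - ramp) + head
            x[start + fade : start + n_ep] = seg[fade:n_ep]
        if i + 1 < len(h):
            # pre-write this epoch's 0.5 s tail into the next slot for blending
            x[start + n_ep : start + n_ep + fade] = seg[n_ep : n_ep + fade]
    return EEGRecording(subject_id=h.subject_id, channel="C4-M1", fs=fs, samples=x)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_subject(
    subject_id: str,
    ahi: float,
    spec: CohortSpec,
    seed: int,
) -> tuple[EEGRecording, Hypnogram]:
    """One subject: AHI-fragmented hypnogram plus matching recording."""
    tm = fragmented_transition_matrix(
        spec.transition_matrix, ahi, spec.fragmentation_gain
    )
    hyp = generate_hypnogram(spec.epochs_per_subject, tm, seed=seed)
    hyp = Hypnogram(subject_id=subject_id, labels=hyp.labels)
    arousal_rate = spec.arousal_rate_per_event * ahi * (EPOCH_DURATION_S / 3600.0)
    rec = generate_recording(
        hyp,
        spec.stage_spec,
        fs=spec.fs,
        seed=seed + 1,
        arousals_per_epoch=arousal_rate,
    )
    return rec, hyp


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[SubjectTable, dict[str, tuple[EEGRecording, Hypnogram]]]:
    """Generate a multi-cohort subject table with recordings and hypnograms.

    When ``out_dir`` is given, recordings (NPZ), hypnograms (CSV), the AHI
    table (CSV) and a manifest JSON recording every seed are written there.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    data: dict[str, tuple[EEGRecording, Hypnogram]] = {}
    manifest: dict[str, dict] = {}
    idx = 0
    for cohort in spec.cohorts:
        lo, hi = spec.ahi_ranges[cohort]
        for _ in range(spec.n_subjects_per_cohort):
            subject_id = f"S{idx:03d}"
            ahi = float(rng.uniform(lo, hi))
            subj_seed = int(rng.integers(0, 2**31 - 2))
            rec, hyp = generate_subject(subject_id, ahi, spec, subj_seed)
            data[subject_id] = (rec, hyp)
            row = {"subject_id": subject_id, "ahi": ahi, "cohort": cohort}
            manifest[subject_id] = {"seed": subj_seed, "ahi": ahi, "cohort": cohort}
            rows.append(row)
            idx += 1
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subject_id, (rec, hyp) in data.items():
            rec_path = out_dir / f"{subject_id}.npz"
            hyp_path = out_dir / f"{subject_id}_hypnogram.csv"
            write_recording(rec_path, rec)
            write_hypnogram(hyp_path, hyp)
            frame.loc[frame["subject_id"] == subject_id, "recording_path"] = str(rec_path)
            frame.loc[frame["subject_id"] == subject_id, "hypnogram_path"] = str(hyp_path)
        table = SubjectTable(frame=frame)
        write_subject_table(out_dir / "subjects.csv", table)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "seed": spec.seed,
                    "epochs_per_subject": spec.epochs_per_subject,
                    "fs": spec.fs,
                    "fragmentation_gain": spec.fragmentation_gain,
                    "subjects": manifest,
                },
                fh,
                indent=2,
            )
    else:
        table = SubjectTable(frame=frame)
    return table, data


def transitions_per_hour(hyp: Hypnogram) -> float:
    labels = hyp.labels
    n_trans = sum(a != b for a, b in zip(labels, labels[1:]))
    hours = hyp.duration_s / 3600.0
    return n_trans / hours


# ---------------------------------------------------------------------------
# Band-power oracle stager
# ---------------------------------------------------------------------------

_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0),
    "beta": (15.0, 30.0),
}


def band_power_features(rec: EEGRecording, n_epochs: int | None = None) -> np.ndarray:
    """Per-epoch log relative band powers (delta..beta) via Welch."""
    n_ep = int(round(EPOCH_DURATION_S * rec.fs))
    total = rec.samples.size // n_ep if n_epochs is None else n_epochs
    feats = np.zeros((total, len(_BANDS)))
    for i in range(total):
        seg = rec.samples[i * n_ep : (i + 1) * n_ep]
        freqs, psd = sps.welch(seg, fs=rec.fs, nperseg=min(512, seg.size))
        powers = []
        for lo, hi in _BANDS.values():
            mask = (freqs >= lo) & (freqs < hi)
            powers.append(np.trapezoid(psd[mask], freqs[mask]))
        powers = np.asarray(powers)
        rel = powers / powers.sum()
        feats[i] = np.log(rel + 1e-12)
    return feats


class NearestCentroidStager:
    """Stage-agnostic nearest-centroid classifier on relative band powers.

    Deliberately simple: per-epoch, no temporal context.  Serves as the
    separability oracle for the generator and as the band-power baseline in
    cohort-robustness comparisons.
    """

    def __init__(self) -> None:
        self.centroids_: np.ndarray | None = None

    def fit(self, feats: np.ndarray, labels: Sequence[str]) -> "NearestCentroidStager":
        labels = np.asarray(labels)
        cents = np.zeros((len(STAGES), feats.shape[1]))
        for i, stage in enumerate(STAGES):
            mask = labels == stage
            if mask.any():
                cents[i] = feats[mask].mean(axis=0)
            else:
                cents[i] = np.inf  # never selected
        self.centroids_ = cents
        return self

    def predict(self, feats: np.ndarray) -> list[str]:
        if self.centroids_ is None:
            raise RuntimeError("fit before predict")
        d = np.linalg.norm(feats[:, None, :] - self.centroids_[None], axis=2)
        return [STAGES[i] for i in d.argmin(axis=1)]
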