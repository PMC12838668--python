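"""End-to-end glue: preprocess -> window -> features -> sequences -> model.

These helpers tie the feature extractors to the classifier for whole
subjects and cohorts; the CLI and the experiment scripts are thin wrappers
around them.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .baseline_features import cwt_feature, stft_feature
from .io_formats import EEGRecording, Hypnogram
from .modulation_features import ModulationExtractor, design_filterbank
from .preprocessing import bandpass_filter, zscore_normalize
from .sequence_classifier import (
    ClassifierConfig,
    ImageSequenceBatch,
    StagerNet,
    TrainingHistory,
    make_image_batches,
    predict,
    train,
)
from .windowing import (
    EpochWindow,
    assign_adaptive_windows,
    build_sequences,
    merge_fixed_windows,
)

FEATURE_METHODS = ("modulation", "stft", "cwt")


def make_windows(hyp: Hypnogram, window_mode: str = "adaptive") -> list[EpochWindow]:
    """Windows per the named mode: 'adaptive' or fixed '30'/'60'/'90' (s)."""
    if window_mode == "adaptive":
        return assign_adaptive_windows(hyp)
    if window_mode in ("30", "60", "90"):
        return merge_fixed_windows(hyp, {"30": 1, "60": 2, "90": 3}[window_mode])
    raise ValueError(f"unknown window mode {window_mode!r}")


def subject_feature_images(
    rec: EEGRecording,
    hyp: Hypnogram,
    method: str = "modulation",
    window_mode: str = "adaptive",
    resolution: str = "152x120",
    filterbank=None,
) -> tuple[list[EpochWindow], list[np.ndarray]]:
    """Preprocess one subject and compute one feature image per epoch.

    The recording is band-passed (0.3-40 Hz) and z-scored; the modulation
    branch then uses the requested windowing, while the STFT/CWT baselines
    are fixed to 30 s epochs by design.
    """
    if method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {method!r}; use one of {FEATURE_METHODS}")
    pre, _ = zscore_normalize(bandpass_filter(rec))
    if method == "modulation":
        windows = make_windows(hyp, window_mode)
        extractor = ModulationExtractor(
            pre, filterbank=filterbank or design_filterbank()
        )
        images = [
            extractor.feature_image(w, resolution=resolution).pixels for w in windows
        ]
        return windows, images
    windows = make_windows(hyp, "30")
    fn = stft_feature if method == "stft" else cwt_feature
    images = [fn(w, pre).pixels for w in windows]
    return windows, images


def sequence_batches_for_subjects(
    data: Mapping[str, tuple[EEGRecording, Hypnogram]],
    subject_ids: Iterable[str],
    method: str = "modulation",
    window_mode: str = "adaptive",
    resolution: str = "152x120",
    T: int = 10,
    stride: int = 5,
    image_cache: dict | None = None,
) -> list[ImageSequenceBatch]:
    """Model-ready sequence batches for the given subjects.

    ``image_cache`` (keyed by subject) lets train/eval splits share feature
    computation across calls with different strides.
    """
    batches: list[ImageSequenceBatch] = []
    for sid in subject_ids:
        rec, hyp = data[sid]
        if image_cache is not None and sid in image_cache:
            windows, images = image_cache[sid]
        else:
            windows, images = subject_feature_images(
                rec, hyp, method=method, window_mode=window_mode, resolution=resolution
            )
            if image_cache is not None:
                image_cache[sid] = (windows, images)
        lookup = {id(w): img for w, img in zip(windows, images)}
        seqs = build_sequences(windows, subject_id=sid, T=T, stride=stride)
        batches.extend(make_image_batches(seqs, lambda w: lookup[id(w)]))
    return batches


@dataclasses.dataclass
class ExperimentResult:
    model: StagerNet
    history: TrainingHistory
    predictions: dict[str, list[str]]  # test subjects, epoch-ordered
    truths: dict[str, list[str]]


def run_experiment(
    data: Mapping[str, tuple[EEGRecording, Hypnogram]],
    train_ids: list[str],
    val_ids: list[str],
    test_ids: list[str],
    cfg: ClassifierConfig,
    method: str = "modulation",
    window_mode: str = "adaptive",
    train_stride: int = 5,
    verbose: bool = False,
) -> ExperimentResult:
    """Train on train_ids, early-stop on val_ids, predict on test_ids."""
    cache: dict = {}
    common = dict(
        data=data,
        method=method,
        window_mode=window_mode,
        resolution=cfg.resolution,
        T=cfg.seq_len,
        image_cache=cache,
    )
    train_b = sequence_batches_for_subjects(
        subject_ids=train_ids, stride=train_stride, **common
    )
    val_b = sequence_batches_for_subjects(
        subject_ids=val_ids, stride=cfg.seq_len, **common
    )
    test_b = sequence_batches_for_subjects(
        subject_ids=test_ids, stride=cfg.seq_len, **common
    )
    model = StagerNet(cfg)
    model, history = train(model, train_b, val_b, cfg, verbose=verbose)
    predictions = predict(model, test_b)
    truths = {sid: list(data[sid][1].labels) for sid in test_ids}
    return ExperimentResult(
        model=model, history=history, predictions=predictions, truths=truths
    )
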