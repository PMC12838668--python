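"""Constraint-aware epoch windowing and sequence construction.

The adaptive rule gives every scored 30 s epoch exactly one analysis window
(complete data retention): a 60 s extended window ``[t_i, t_{i+2}]`` when the
next epoch carries the same stage, and a 30 s fallback when a transition
follows (or no next epoch exists).  The window's label is strictly ``y_i`` —
no majority voting, and an extended window never spans a label change.

Fixed merge modes (k = 1, 2, 3 epochs) reproduce the window-length ablation;
``build_sequences`` packs windows into length-T batches for the sequence
classifier, left-padding the final partial batch and masking padded slots.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import EPOCH_DURATION_S, Hypnogram


@dataclasses.dataclass(frozen=True)
class EpochWindow:
    """One epoch's analysis segment, 30/60/90 s, carrying its clinical label."""

    epoch_index: int
    start_s: float
    end_s: float
    label: str
    mode: str  # adaptive-extended | adaptive-fallback | fixed

    def __post_init__(self) -> None:
        if self.epoch_index < 0:
            raise ValueError("epoch_index must be >= 0")
        if self.length_s not in (30, 60, 90):
            raise ValueError(f"window length must be 30/60/90 s, got {self.length_s}")

    @property
    def length_s(self) -> int:
        return int(round(self.end_s - self.start_s))

    def sample_slice(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)), int(round(self.end_s * fs)))


@dataclasses.dataclass
class SequenceBatch:
    """T consecutive windows from one subject plus a padding mask.

    ``mask[t]`` is True for real epochs and False for padded slots (the final
    partial batch is left-padded by repeating its first window).
    """

    subject_id: str
    windows: list[EpochWindow]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.windows) != self.mask.size:
            raise ValueError("mask length must equal number of windows")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def epoch_indices(self) -> list[int]:
        return [w.epoch_index for w in self.windows]

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]


def assign_adaptive_windows(h: Hypnogram) -> list[EpochWindow]:
    """Adaptive 60 s / 30 s windows, one per epoch, labels strictly ``y_i``.

    Epoch ``i`` gets a 60 s window ``[t_i, t_{i+2}]`` iff epoch ``i+1`` exists
    and shares its label; otherwise the standard 30 s window ``[t_i, t_{i+1}]``.
    The last epoch always falls back to 30 s.
    """
    d = h.epoch_duration_s
    windows: list[EpochWindow] = []
    n = len(h)
    for i, label in enumerate(h.labels):
        stable = i + 1 < n and h.labels[i + 1] == label
        if stable:
            windows.append(EpochWindow(i, i * d, (i + 2) * d, label, "adaptive-extended"))
        else:
            windows.append(EpochWindow(i, i * d, (i + 1) * d, label, "adaptive-fallback"))
    return windows


def merge_fixed_windows(h: Hypnogram, k: int) -> list[EpochWindow]:
    """Fixed merge windows for the window-length ablation (one per epoch).

    k=1: plain 30 s windows.  k=2: 60 s ``[t_i, t_{i+2}]`` when epochs i, i+1
    agree, else 30 s.  k=3: 90 s ``[t_{i-1}, t_{i+2}]`` when epochs i-1, i,
    i+1 all agree, falling back to the k=2 rule, then to 30 s.  Transition
    epochs are never discarded.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    d = h.epoch_duration_s
    n = len(h)
    labels = h.labels
    windows: list[EpochWindow] = []
    for i, label in enumerate(labels):
        if (
            k == 3
            and 0 < i < n - 1
            and labels[i - 1] == label
            and labels[i + 1] == label
        ):
            windows.append(EpochWindow(i, (i - 1) * d, (i + 2) * d, label, "fixed"))
        elif k >= 2 and i + 1 < n and labels[i + 1] == label:
            windows.append(EpochWindow(i, i * d, (i + 2) * d, label, "fixed"))
        else:
            windows.append(EpochWindow(i, i * d, (i + 1) * d, label, "fixed"))
    return windows


def build_sequences(
    windows: list[EpochWindow],
    subject_id: str,
    T: int = 10,
    stride: int = 5,
) -> list[SequenceBatch]:
    """Pack windows into length-T sequences with the given epoch stride.

    Batches start at epochs 0, stride, 2*stride, ...; consecutive full
    batches overlap in ``T - stride`` epochs.  A final partial batch is
    left-padded by repeating its first window, with ``mask`` False on padded
    slots so they are excluded from loss and metrics.
    """
    if T < 1 or stride < 1:
        raise ValueError("T and stride must be >= 1")
    n = len(windows)
    if n == 0:
        return []
    batches: list[SequenceBatch] = []
    start = 0
    while start < n:
        chunk = windows[start : start + T]
        n_real = len(chunk)
        if n_real < T:
            pad = [chunk[0]] * (T - n_real)
            chunk = pad + chunk
            mask = np.array([False] * (T - n_real) + [True] * n_real)
        else:
            mask = np.ones(T, dtype=bool)
        batches.append(SequenceBatch(subject_id=subject_id, windows=chunk, mask=mask))
        if start + T >= n:
            break
        start += stride
    return batches


def retention_fraction(h: Hypnogram, windows: list[EpochWindow]) -> float:
    """Fraction of scored epochs that received a window (1.0 = complete)."""
    covered = {w.epoch_index for w in windows}
    return len(covered) / len(h)


def extended_fraction(windows: list[EpochWindow]) -> float:
    """Fraction of adaptive windows that used the extended 60 s form."""
    if not windows:
        return 0.0
    return sum(w.mode == "adaptive-extended" for w in windows) / len(windows)
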