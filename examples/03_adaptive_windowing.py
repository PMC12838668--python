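"""Adaptive 60 s / 30 s windowing and T=10 sequence construction.

The adaptive rule extends an epoch's analysis window to 60 s only when the
next epoch carries the same stage, falling back to the scored 30 s at
transitions — every epoch keeps exactly one window and its own label
(complete data retention).  Sequences of T=10 windows with stride 5 overlap
by 50%, the augmentation used to train the sequence classifier.
"""

from sleepmod import Hypnogram, assign_adaptive_windows, build_sequences
from sleepmod.synthetic_data import generate_hypnogram
from sleepmod.windowing import extended_fraction

hyp = Hypnogram("demo", ["N2", "N2", "N2", "N1", "W", "W", "N1", "N2", "N2", "N3"])
windows = assign_adaptive_windows(hyp)
print("stage sequence:", " ".join(hyp.labels))
print("window lengths:", " ".join(f"{w.length_s:2d}" for w in windows), "(seconds)")
print(f"retention: {len(windows)}/{len(hyp)} epochs -> 100%")

big = generate_hypnogram(10_000, seed=3)
big_windows = assign_adaptive_windows(big)
print(f"\n10,000-epoch Markov hypnogram: {len(big_windows)} windows "
      f"({100 * extended_fraction(big_windows):.1f}% extended, rest fallback)")

sequences = build_sequences(big_windows[:25], subject_id="demo", T=10, stride=5)
starts = [s.epoch_indices[0] for s in sequences]
overlap = len(set(sequences[0].epoch_indices) & set(sequences[1].epoch_indices))
print(f"sequence starts for 25 windows: {starts}")
print(f"overlap between consecutive sequences: {overlap} epochs = "
      f"{100 * overlap / 10:.0f}% of T=10")
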