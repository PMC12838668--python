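# Methods

This note documents the models, numerical choices and limitations behind
`sleepmod`: a pipeline that classifies 30 s sleep-EEG epochs into the five
AASM stages (W, N1, N2, N3, R) from modulation-spectrogram images.

## Signal model and preprocessing

The input is a single EEG derivation (canonically C4–M1) sampled at 100 Hz.
Preprocessing is deliberately minimal:

- **Band-pass 0.3–40 Hz**, fourth-order Butterworth. We apply it zero-phase
  (forward–backward, `sosfiltfilt`) so that epoch boundaries are not
  phase-shifted; the prototype is fourth order and the effective magnitude
  response is its square. Filters are realized as second-order sections —
  narrow low-frequency bands at fs = 100 Hz are numerically fragile in
  transfer-function form.
- **Per-subject z-scoring** with the *global* mean and standard deviation of
  the whole recording (population 1/N convention), `x_norm = (x - mu)/sigma`.
  Whole-recording statistics (rather than per-epoch) keep relative amplitude
  differences between stages intact while removing inter-subject gain
  differences from electrode impedance and skull conductivity. Together with
  the percentile normalization of the images this makes every feature
  **exactly invariant to positive rescaling** of the input signal; a constant
  (zero-variance) recording is rejected as degenerate.

## Modulation spectrogram

The core representation decomposes the signal into **carrier frequency**
(what oscillates) and **modulation frequency** (how fast its amplitude
waxes and wanes):

1. **Carrier filterbank.** Either the five AASM bands (delta 0.5–4, theta
   4–8, alpha 8–12, sigma 12–15, beta 15–30 Hz) for interpretability, or —
   the default for feature images — 44 contiguous equal-width bins spanning
   0.5–30 Hz. Both use fourth-order zero-phase Butterworth band-passes (the
   filter family of the carrier filterbank is our choice; nothing downstream
   depends on it strongly).
2. **Envelope extraction.** Each subband's instantaneous amplitude is the
   magnitude of its analytic (Hilbert) signal.
3. **Envelope low-pass + downsampling.** Envelopes are low-passed at 10 Hz
   (fourth-order Butterworth, zero-phase) and decimated to 20 Hz by index
   selection — the low-pass doubles as the anti-alias filter. This bounds
   representable modulation frequencies at 10 Hz, which covers the slow
   envelopes of sleep phenomena (spindle waxing-waning at ~0.5–2 Hz,
   slow-wave fluctuations) while rejecting fast EMG-like fluctuation.
4. **Envelope Fourier transform.** Each mean-removed envelope is transformed
   with a rectangular window; non-DC bins carry amplitude (2/N) scaling.
   The mean is removed so the DC bin cannot dominate the percentile
   normalization; bin 0 is then re-filled with the envelope mean magnitude
   so an unmodulated carrier still registers in its row. Bin spacing is
   1/L Hz for an L-second window — the reason extended windows matter:
   resolving sub-hertz spindle modulation needs L >= 60 s.
5. **Rendering.** The carrier × modulation matrix is clipped to its 6th and
   99.6th percentiles, mapped affinely to [0, 1], bilinearly resized
   (carrier on the vertical axis, low frequencies at the bottom), re-stretched
   to [0, 1] (interpolation shrinks the extremes), and replicated onto three
   identical channels. Supported resolutions: 76×60×3, 152×120×3 (default),
   224×224×3. We read "normalized to the 6–99.6% range" as a percentile clip
   + affine map; channels are grayscale-replicated rather than colormapped
   because a colormap adds no information for a CNN and breaks
   scale-invariance. A constant matrix renders as all-0.5 with a warning.

Two computation paths exist: `compute_modulation_spectrogram` filters each
window independently (the reference semantics), while `ModulationExtractor`
filters the *continuous* recording once and slices envelopes per window —
much faster for cohorts and free of per-window filter transients. They agree
in spectral localization; values differ slightly near recording edges, where
zero-phase filter transients can masquerade as low-frequency envelope
modulation. Property tests that probe weak modulation therefore analyse
interior windows.

## Adaptive windowing

Each scored 30 s epoch i receives exactly one analysis window labeled with
its own stage y_i (never majority-voted):

- **extended (60 s)** covering [t_i, t_{i+2}] iff epoch i+1 exists and has
  the same label — the window never spans a stage change;
- **fallback (30 s)** [t_i, t_{i+1}] at transitions, preserving the temporal
  boundary.

The last epoch has no successor and takes the fallback; this keeps retention
at exactly 100%. Fixed merge modes (30/60/90 s; k = 1, 2, 3 epochs) exist for
the window-length ablation and likewise fall back rather than discarding
transition epochs, so retention is complete in every mode. For k = 3 an epoch
without an identical-label (i−1, i, i+1) triple falls back to the k = 2 rule,
then to 30 s.

**Sequences.** Windows are packed into sequences of T = 10 consecutive epochs
with stride S = 5 for training (50% overlap between consecutive sequences,
an implicit augmentation). Sequence starts advance by the stride until the
end of the data has been covered; a final partial sequence is left-padded by
repeating its first window, with a mask excluding padded slots from loss and
metrics, so every epoch is used. An exact fit produces no padded sequence.
At evaluation the default stride is T (no overlap); when overlapping
sequences are supplied, per-epoch logits are averaged before the arg-max so
exactly one label per epoch emerges.

## Baseline representations

Both baselines operate on fixed 30 s epochs resampled to 64 Hz, rendered at
76×60×3:

- **STFT:** 256-point Hamming segments at 50% overlap (4 s at 64 Hz; the
  overlap amount is our choice — only "overlapping segments" is prescribed),
  magnitude-squared, log-power scaled, restricted to 0–32 Hz.
- **CWT:** analytic (complex) Morlet, 12 voices per octave, 64 log-spaced
  scales topping out at 32 Hz (so the lowest analysis frequency is
  32·2^(−63/12) ≈ 0.84 Hz), per-epoch normalized input, log-power scaled.

Raw matrices are rendered directly (no figure decorations to crop), which
makes both baselines bit-reproducible.

## Sequence classifier

A residual CNN + BiLSTM, implemented in a self-contained numpy
neural-network engine (`sleepmod.nn`: im2col convolution, batch norm, GELU,
Dropout2D, BPTT LSTM, Adam; float32, with float64 available for gradient
checking — the backward pass is verified against numerical gradients in the
test suite).

- **Trunk:** four residual blocks (3×3 conv → batch norm → GELU → Dropout2D
  → 3×3 conv → batch norm, plus a 1×1-conv shortcut when shape changes),
  strided convolutions in the deeper blocks, global average pooling to one
  embedding per epoch. Default widths (32, 64, 128, 256) with strides
  (1, 1, 2, 2) and Dropout2D 0.25 — all config-exposed, as none of these are
  externally prescribed.
- **Temporal model:** two-layer bidirectional LSTM, 128 hidden units per
  direction (256-dimensional output per epoch), many-to-many: a shared
  linear layer scores all five stages at every sequence position.
- **Auxiliary classifier:** a per-epoch linear head on the pooled CNN
  embedding, trained with weight 0.3, keeps the convolutional features
  discriminative before temporal aggregation. We implement this
  "attention-like" intermediate supervision as a plain weighted auxiliary
  loss; no attention equation is involved.
- **CNN-only ablation** (`use_bilstm=False`): same trunk, per-epoch linear
  head, no BiLSTM, no auxiliary head.

**Training.** Class-weighted cross-entropy (weights N/(k·n_c) over present
classes, absent classes excluded — the inverse-frequency convention, mean 1);
padded slots contribute exactly zero loss and gradient. Adam with lr 1e-3,
betas (0.9, 0.999) and (coupled) weight decay 1e-4 on all parameters.
Validation every 3 epochs on a subject-disjoint internal set (overlap raises
a leakage error); early stopping after 10 consecutive non-improving
evaluations of validation macro-F1; the best checkpoint is restored. With a
constant validation score the stop fires at evaluation 11 (1 improving +
10 patient). Batch size 32 and max 300 epochs by default. All randomness
(init, shuffling, dropout) flows from the config seed, so runs are
bit-reproducible on one CPU thread.

## Evaluation protocol

Accuracy, per-class precision/recall/F1, macro-F1 and Cohen's kappa
(p_o − p_e)/(1 − p_e) are computed from the 5×5 confusion matrix. Classes
absent from both truth and prediction are excluded from the macro mean so
desk-scale runs that miss a stage remain defined; with all five stages
present the macro runs over all five. Degenerate marginals (p_e = 1) report
kappa 0 with a warning.

Cross-validation partitions **subjects**: five test folds cover every
subject exactly once; within each fold 15% of the remaining subjects form
the internal validation set (round-robin across AHI cohorts when cohort
labels are supplied — "stratified" is read as cohort-stratified), the rest
train. The plan is seeded, deterministic, and ships a leakage audit.

AHI severity bands are half-open on the right: Normal < 5, Mild [5, 15),
Moderate [15, 30), Severe >= 30 events/hour.

## Synthetic data generator

The generator emulates exactly the statistical structure the method feeds
on, not the full physiology of sleep EEG:

- **Stage signatures** are sums of amplitude-modulated sinusoids over
  1/f-shaped noise: W = alpha (10 Hz) + beta; N1 = theta (6 Hz) with
  residual alpha; N2 = 13 Hz spindles with a 0.7 Hz waxing-waning envelope
  (depth 0.8) over theta/delta; N3 = dominant high-amplitude 1.5 Hz slow
  waves; R = mixed 4.5 Hz theta + 25 Hz beta with a higher noise floor.
  Amplitudes were chosen so that a simple relative-band-power rule separates
  the stages (N3 keeps >= 60% of its 0.5–30 Hz power below 4 Hz), which the
  generator's own tests verify.
- **Hypnograms** are first-order Markov chains with strong self-transitions
  (mean dwell of several epochs) and physiologic adjacency (W↔N1, N1→N2,
  N2↔N3, R entered from N2); the stationary distribution is N2-heavy with
  every stage above ~15%, so 200-epoch recordings cover all five stages.
- **Apnea severity** enters twice, both scaled by the subject's AHI:
  off-diagonal transition probabilities are multiplied by
  1 + 0.04·AHI (rows renormalized, self-transition floored at 0.05) —
  more stage transitions per hour — and each sleep epoch receives a Poisson
  number of 2–5 s high-amplitude alpha+beta arousal bursts at a rate of one
  per respiratory event (AHI/120 per 30 s epoch), with the epoch's label
  unchanged, as a scorer keeps the majority stage through a micro-arousal.
  Epochs are concatenated with 0.5 s raised-cosine cross-fades.
- Per-cohort AHI is drawn uniformly from the band's range (Severe: 30–60).
  Every generator is a pure function of (spec, seed).

What this does **not** model: K-complex morphology, real spindle density
statistics, artifacts, electrode pops, respiratory or SpO2 channels, and
real inter-subject spectral variability. Passing tests therefore demonstrate
that the pipeline's machinery (windowing, demodulation, learning, protocol)
works and that its robustness ordering holds under controlled fragmentation
— not clinical-grade performance on real recordings.

## Desk-scale experiment sizes

The parameter-recovery experiment (`sleepmod.experiments`) trains the full
modulation pipeline on a synthetic Normal cohort of 8 training / 2
validation / 2 test subjects × 200 epochs (100 min of signal each) and then
scores the frozen model on a 2-subject Severe cohort, comparing its
macro-F1 drop with that of the band-power nearest-centroid baseline fitted
on the same training subjects. The classifier uses a compact configuration
(input average-pooling 4, channel widths 8–64, stride 2 per block, Dropout2D
0.1, batch 8, max 45 epochs) whose capacity is ample for the clean synthetic
signatures; on one CPU the whole experiment runs in minutes. These sizes are
the package's own desk-scale choice; the architecture defaults above remain
the reference configuration.

## Known limitations

- EDF support is read-only (via `mne`); the native NPZ container is used for
  round-trip tests and synthetic cohorts.
- The per-window and whole-recording envelope paths differ near recording
  edges (filter transients); batch extraction is the recommended path.
- Cohen's kappa of single-class degenerate runs is reported as 0 by
  convention, not as a meaningful agreement value.
- The numpy network engine is single-threaded and CPU-bound; it is built for
  correctness and determinism at desk scale, not for large-scale training.
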