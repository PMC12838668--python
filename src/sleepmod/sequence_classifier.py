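"""Residual-CNN + BiLSTM sequence stager with an auxiliary per-epoch head.

The model ingests sequences of T feature images from one subject: four
residual convolutional blocks (conv + batch norm + GELU + Dropout2D, strided
in deeper blocks, with shortcut connections) followed by global average
pooling give one embedding per epoch; a two-layer bidirectional LSTM (128
hidden units per direction, 256-dimensional output) models the stage
progression across the sequence, and a shared linear layer emits per-epoch
5-class scores.  An auxiliary linear classifier on the pooled CNN embedding
provides intermediate supervision so the convolutional features stay
discriminative before temporal aggregation; its loss is added with weight
``aux_loss_weight``.  Training uses class-weighted cross-entropy (padded
sequence slots masked out), Adam, periodic validation, early stopping on
validation macro-F1 and restoration of the best checkpoint.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .io_formats import STAGES
from .modulation_features import RESOLUTIONS
from .windowing import SequenceBatch


@dataclasses.dataclass
class ClassifierConfig:
    """Architecture and optimization settings.

    Defaults follow the reference configuration: 4 residual blocks, BiLSTM
    2 x 128, T=10 sequences, Adam(1e-3, 0.9, 0.999) with weight decay 1e-4,
    validation every 3 epochs with patience 10 on macro-F1.  ``input_pool``
    average-pools the input image by that factor before the first block — a
    capacity/runtime dial for small-scale runs.  ``use_bilstm=False`` gives
    the CNN-only ablation (per-epoch linear head on the pooled embedding,
    no auxiliary classifier).
    """

    n_classes: int = 5
    resolution: str = "152x120"
    block_channels: tuple[int, ...] = (32, 64, 128, 256)
    block_strides: tuple[int, ...] = (1, 1, 2, 2)
    input_pool: int = 1
    lstm_layers: int = 2
    lstm_hidden: int = 128
    seq_len: int = 10
    dropout2d_rate: float = 0.25
    aux_loss_weight: float = 0.3
    use_bilstm: bool = True
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 300
    eval_every: int = 3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValueError(
                f"image resolution {self.resolution!r} not supported; "
                f"use one of {list(RESOLUTIONS)}"
            )
        if not 0 <= self.dropout2d_rate < 1:
            raise ValueError("dropout2d_rate must be in [0, 1)")
        if self.aux_loss_weight < 0:
            raise ValueError("aux_loss_weight must be >= 0")
        if len(self.block_channels) != len(self.block_strides):
            raise ValueError("block_channels and block_strides must align")


@dataclasses.dataclass
class EvaluationRecord:
    epoch: int
    train_loss: float
    val_accuracy: float
    val_macro_f1: float
    val_kappa: float
    is_best: bool


@dataclasses.dataclass
class TrainingHistory:
    """Per-evaluation validation metrics and the selected checkpoint."""

    records: list[EvaluationRecord] = dataclasses.field(default_factory=list)
    best_eval_index: int = -1
    stopped_epoch: int = 0

    @property
    def n_evaluations(self) -> int:
        return len(self.records)


class EarlyStopper:
    """Patience-based stopping on a maximized validation score.

    The first evaluation always improves on the initial -inf; training
    stops once ``patience`` consecutive evaluations fail to improve, i.e.
    with a constant score the stop fires at evaluation ``1 + patience``.
    """

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = -np.inf
        self.evals_since_best = 0
        self.n_evaluations = 0

    def update(self, score: float) -> bool:
        """Record one evaluation; returns True if it improved the best."""
        self.n_evaluations += 1
        if score > self.best:
            self.best = score
            self.evals_since_best = 0
            return True
        self.evals_since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.evals_since_best >= self.patience


@dataclasses.dataclass
class ImageSequenceBatch:
    """A model-ready sequence: T images with labels, epoch ids and mask."""

    subject_id: str
    epoch_indices: np.ndarray
    images: np.ndarray  # (T, H, W, 3)
    labels: np.ndarray  # (T,) int in [0, 5)
    mask: np.ndarray  # (T,) bool; False = padded slot

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.epoch_indices = np.asarray(self.epoch_indices, dtype=np.int64)


def make_image_batches(
    seq_batches: Sequence[SequenceBatch],
    image_of: Callable,
) -> list[ImageSequenceBatch]:
    """Materialize sequence batches into image arrays via ``image_of(window)``."""
    out = []
    for sb in seq_batches:
        images = np.stack([np.asarray(image_of(w), dtype=np.float32) for w in sb.windows])
        labels = np.array([STAGES.index(w.label) for w in sb.windows], dtype=np.int64)
        out.append(
            ImageSequenceBatch(
                subject_id=sb.subject_id,
                epoch_indices=np.array(sb.epoch_indices),
                images=images,
                labels=labels,
                mask=sb.mask.copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class _ResidualBlock:
    def __init__(self, cin, cout, stride, p_drop, rng, dtype):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(cout, dtype=dtype)
        self.act1 = nn.GELU()
        self.drop = nn.Dropout2d(p_drop, rng)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(cout, dtype=dtype)
        if stride != 1 or cin != cout:
            self.short_conv = nn.Conv2d(cin, cout, 1, stride, pad=0, rng=rng, dtype=dtype)
            self.short_bn = nn.BatchNorm2d(cout, dtype=dtype)
        else:
            self.short_conv = None
        self.act_out = nn.GELU()

    def params(self):
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.short_conv is not None:
            ps += self.short_conv.params() + self.short_bn.params()
        return ps

    def forward(self, x, train):
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.act1.forward(y, train)
        y = self.drop.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.act_out.forward(y + s, train)

    def backward(self, dout):
        dpre = self.act_out.backward(dout)
        dy = self.bn2.backward(dpre)
        dy = self.conv2.backward(dy)
        dy = self.drop.backward(dy)
        dy = self.act1.backward(dy)
        dy = self.bn1.backward(dy)
        dx = self.conv1.backward(dy)
        if self.short_conv is not None:
            dx = dx + self.short_conv.backward(self.short_bn.backward(dpre))
        else:
            dx = dx + dpre
        return dx


class StagerNet:
    """The CNN(+BiLSTM) sequence model; see module docstring."""

    def __init__(self, cfg: ClassifierConfig, dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self.pool = nn.AvgPool2d(cfg.input_pool) if cfg.input_pool > 1 else None
        self.blocks = []
        cin = 3
        for cout, stride in zip(cfg.block_channels, cfg.block_strides):
            self.blocks.append(
                _ResidualBlock(cin, cout, stride, cfg.dropout2d_rate, rng, dtype)
            )
            cin = cout
        self.gap = nn.GlobalAvgPool()
        self.embed_dim = cfg.block_channels[-1]
        if cfg.use_bilstm:
            self.lstms = []
            din = self.embed_dim
            for _ in range(cfg.lstm_layers):
                self.lstms.append(nn.BiLSTM(din, cfg.lstm_hidden, rng, dtype))
                din = 2 * cfg.lstm_hidden
            self.head = nn.Linear(din, cfg.n_classes, rng, dtype)
            self.aux_head = nn.Linear(self.embed_dim, cfg.n_classes, rng, dtype)
        else:
            self.lstms = []
            self.head = nn.Linear(self.embed_dim, cfg.n_classes, rng, dtype)
            self.aux_head = None

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for blk in self.blocks:
            ps += blk.params()
        for lstm in self.lstms:
            ps += lstm.params()
        ps += self.head.params()
        if self.aux_head is not None:
            ps += self.aux_head.params()
        return ps

    def _bn_layers(self):
        for blk in self.blocks:
            yield blk.bn1
            yield blk.bn2
            if blk.short_conv is not None:
                yield blk.short_bn
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for bn in self._bn_layers():
            arrays += [bn.running_mean, bn.running_var]
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), state, strict=True):
            dst[...] = src

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward(
        self, images: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """(B, T, H, W, 3) images -> (main logits, aux logits), each (B, T, K)."""
        B, T, H, W, C = images.shape
        expected = RESOLUTIONS[self.cfg.resolution]
        if (H, W) != expected or C != 3:
            raise ValueError(
                f"image shape {(H, W, C)} does not match configured resolution "
                f"{expected + (3,)}"
            )
        x = images.reshape(B * T, H, W, C).transpose(0, 3, 1, 2).astype(self.dtype)
        if self.pool is not None:
            x = self.pool.forward(x, train)
        for blk in self.blocks:
            x = blk.forward(x, train)
        emb = self.gap.forward(x, train)  # (B*T, E)
        self._emb_shape = (B, T, self.embed_dim)
        seq = emb.reshape(B, T, self.embed_dim)
        if self.cfg.use_bilstm:
            h = seq
            for lstm in self.lstms:
                h = lstm.forward(h, train)
            main = self.head.forward(h, train)
            aux = self.aux_head.forward(seq, train)
            return main, aux
        main = self.head.forward(seq, train)
        return main, None

    def backward(self, dmain: np.ndarray, daux: np.ndarray | None) -> None:
        B, T, E = self._emb_shape
        if self.cfg.use_bilstm:
            dh = self.head.backward(dmain.astype(self.dtype))
            for lstm in reversed(self.lstms):
                dh = lstm.backward(dh)
            dseq = dh
            if daux is not None and self.aux_head is not None:
                dseq = dseq + self.aux_head.backward(daux.astype(self.dtype))
        else:
            dseq = self.head.backward(dmain.astype(self.dtype))
        demb = dseq.reshape(B * T, E)
        dx = self.gap.backward(demb)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        if self.pool is not None:
            self.pool.backward(dx)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        cfg_json = json.dumps(dataclasses.asdict(self.cfg))
        np.savez(path, __config__=np.str_(cfg_json), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "StagerNet":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            for key in ("block_channels", "block_strides", "betas"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg = ClassifierConfig(**cfg_dict)
            model = cls(cfg)
            state = [data[f"arr_{i}"] for i in range(len(model.state_arrays()))]
        model.set_state(state)
        return model


def build_model(cfg: ClassifierConfig) -> StagerNet:
    """Construct a seed-deterministic model for the configured resolution."""
    return StagerNet(cfg)


# ---------------------------------------------------------------------------
# Class weights
# ---------------------------------------------------------------------------


def compute_class_weights(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights, normalized over present classes.

    ``w_c = N / (k_present * n_c)`` for classes that occur (mean weight 1
    over present classes); absent classes get weight 0 and are excluded
    from the loss.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    if isinstance(labels[0], str):
        idx = np.array([STAGES.index(s) for s in labels])
    else:
        idx = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(idx, minlength=len(STAGES)).astype(float)
    present = counts > 0
    k = int(present.sum())
    weights = np.zeros(len(STAGES))
    weights[present] = len(labels) / (k * counts[present])
    return weights


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _stack(batches: list[ImageSequenceBatch]):
    images = np.stack([b.images for b in batches])
    labels = np.stack([b.labels for b in batches])
    mask = np.stack([b.mask for b in batches])
    return images, labels, mask


def _evaluate(model: StagerNet, batches: list[ImageSequenceBatch], chunk: int = 16):
    """Masked per-epoch predictions and truths over a batch list (eval mode)."""
    preds, truths = [], []
    for i in range(0, len(batches), chunk):
        images, labels, mask = _stack(batches[i : i + chunk])
        main, _ = model.forward(images, train=False)
        p = main.argmax(axis=2)
        preds.append(p[mask])
        truths.append(labels[mask])
    return np.concatenate(preds), np.concatenate(truths)


def train(
    model: StagerNet,
    train_batches: list[ImageSequenceBatch],
    val_batches: list[ImageSequenceBatch],
    cfg: ClassifierConfig,
    class_weights: np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[StagerNet, TrainingHistory]:
    """Optimize the model with early stopping on validation macro-F1.

    Train and validation batches must come from disjoint subject sets
    (checked; overlap raises a leakage error).  The main-head loss plus
    ``aux_loss_weight`` times the auxiliary-head loss is minimized with
    Adam; validation runs every ``eval_every`` epochs and training halts
    after ``patience`` consecutive non-improving evaluations, restoring the
    best-macro-F1 model state.
    """
    from .evaluation import confusion_matrix_indices, compute_metrics

    train_subjects = {b.subject_id for b in train_batches}
    val_subjects = {b.subject_id for b in val_batches}
    overlap = train_subjects & val_subjects
    if overlap:
        raise ValueError(f"leakage: subjects in both train and validation: {sorted(overlap)}")
    if not train_batches or not val_batches:
        raise ValueError("train and validation batch lists must be non-empty")

    if class_weights is None:
        all_labels = np.concatenate([b.labels[b.mask] for b in train_batches])
        class_weights = compute_class_weights(all_labels)

    optimizer = nn.Adam(
        model.params(), lr=cfg.lr, betas=cfg.betas, weight_decay=cfg.weight_decay
    )
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    stopper = EarlyStopper(cfg.patience)
    best_state = model.get_state()
    stop = False

    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_batches))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            group = [train_batches[j] for j in order[i : i + cfg.batch_size]]
            images, labels, mask = _stack(group)
            main, aux = model.forward(images, train=True)
            loss, dmain = nn.weighted_masked_cross_entropy(
                main, labels, mask, class_weights
            )
            daux = None
            if aux is not None and cfg.aux_loss_weight > 0:
                aux_loss, daux = nn.weighted_masked_cross_entropy(
                    aux, labels, mask, class_weights
                )
                loss += cfg.aux_loss_weight * aux_loss
                daux = cfg.aux_loss_weight * daux
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss}; aborting training"
                )
            model.zero_grad()
            model.backward(dmain, daux)
            optimizer.step()
            losses.append(loss)

        if epoch % cfg.eval_every == 0:
            preds, truths = _evaluate(model, val_batches)
            cm = confusion_matrix_indices(truths, preds, n_classes=cfg.n_classes)
            report = compute_metrics(cm)
            improved = stopper.update(report.macro_f1)
            if improved:
                best_state = model.get_state()
                history.best_eval_index = len(history.records)
            history.records.append(
                EvaluationRecord(
                    epoch=epoch,
                    train_loss=float(np.mean(losses)),
                    val_accuracy=report.accuracy,
                    val_macro_f1=report.macro_f1,
                    val_kappa=report.kappa,
                    is_best=improved,
                )
            )
            if verbose:
                print(
                    f"epoch {epoch}: loss={np.mean(losses):.4f} "
                    f"val_mf1={report.macro_f1:.3f} best={stopper.best:.3f}"
                )
            if stopper.should_stop:
                stop = True
        if stop:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = cfg.max_epochs

    model.set_state(best_state)
    return model, history


def predict(
    model: StagerNet, batches: list[ImageSequenceBatch], chunk: int = 16
) -> dict[str, list[str]]:
    """Per-epoch stage labels per subject, epoch-ordered.

    Padded slots are dropped; when overlapping sequences cover an epoch more
    than once its logits are averaged before the arg-max, so exactly one
    label is produced per original epoch.
    """
    logits_by_key: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], int] = {}
    for i in range(0, len(batches), chunk):
        group = batches[i : i + chunk]
        images, _, mask = _stack(group)
        main, _ = model.forward(images, train=False)
        for b, batch in enumerate(group):
            for t in range(len(batch.mask)):
                if not batch.mask[t]:
                    continue
                key = (batch.subject_id, int(batch.epoch_indices[t]))
                if key in logits_by_key:
                    logits_by_key[key] += main[b, t]
                    counts[key] += 1
                else:
                    logits_by_key[key] = main[b, t].copy()
                    counts[key] = 1
    out: dict[str, list[str]] = {}
    subjects = sorted({k[0] for k in logits_by_key})
    for subject in subjects:
        epochs = sorted(k[1] for k in logits_by_key if k[0] == subject)
        out[subject] = [
            STAGES[int(np.argmax(logits_by_key[(subject, e)] / counts[(subject, e)]))]
            for e in epochs
        ]
    return out
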