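"""Sequence-to-activity convolutional models and their ensemble.

The network takes a one-hot DNA matrix (4 rows: A, C, G, T) embedded in its
vector context, applies a stack of convolution / batch-norm / ReLU /
max-pool blocks followed by two dense layers, and outputs one activity
prediction (constitutive libraries) or two (uninduced and induced, for
inducible libraries).  An ensemble of k submodels shares one held-out test
set; the remaining data are split into k folds and submodel j validates on
fold j.  Predictions are merged by the mean across submodels or, to
penalize extrapolation, the mean minus the standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .scaffold import LibraryScaffold, _BASE_INDEX

TARGET_CONSTITUTIVE = "constitutive_activity"
TARGET_INDUCED = "induced_activity"
TARGET_RATIO = "activation_ratio"


def huber_loss(y: float, y_hat: float, delta: float = 0.15) -> float:
    """Huber loss for a single prediction (quadratic within delta)."""
    e = abs(y - y_hat)
    return 0.5 * e * e if e <= delta else delta * (e - delta / 2.0)


def activation_ratio(pred_induced, pred_uninduced):
    """Log activation ratio and its fold-change equivalent."""
    log_ratio = np.asarray(pred_induced) - np.asarray(pred_uninduced)
    return log_ratio, 10.0**log_ratio


@dataclass(frozen=True)
class EncoderConfig:
    """Padding / augmentation rules shared by all training examples.

    Every sequence is embedded in at least ``min_pad`` bases of its vector
    context on each side; libraries shorter than the longest one get longer
    pads so all encoded inputs share one length.  During training the
    encoded frame is displaced by a shift of 0..shift_max positions.
    """

    min_pad: int = 25
    shift_max: int = 7


class SequenceEncoder:
    """Encodes library members (with vector context) into fixed-size
    one-hot frames, handling pad equalization across libraries."""

    def __init__(self, scaffolds: dict[str, LibraryScaffold], cfg: EncoderConfig = EncoderConfig()):
        self.cfg = cfg
        self.scaffolds = dict(scaffolds)
        longest = max(s.total_length for s in self.scaffolds.values())
        self.padded_length = longest + 2 * cfg.min_pad
        self.frame_length = self.padded_length + cfg.shift_max
        self.pads: dict[str, tuple[int, int]] = {}
        for name, sc in self.scaffolds.items():
            total_pad = self.padded_length - sc.total_length
            pad5 = total_pad // 2
            pad3 = total_pad - pad5
            if len(sc.flank_5) < pad5 or len(sc.flank_3) < pad3:
                raise ValueError(f"scaffold {name!r} flanks shorter than required pad")
            self.pads[name] = (pad5, pad3)

    def seq_region(self, library: str) -> tuple[int, int]:
        """Columns of the frame occupied by the promoter itself at shift 0."""
        pad5, _ = self.pads[library]
        sc = self.scaffolds[library]
        return pad5, pad5 + sc.total_length

    def to_indices(self, seq: str, library: str) -> np.ndarray:
        """Padded base-index vector (length ``padded_length``)."""
        sc = self.scaffolds[library]
        if len(seq) != sc.total_length:
            raise ValueError("sequence length does not match its scaffold")
        pad5, pad3 = self.pads[library]
        full = sc.flank_5[len(sc.flank_5) - pad5 :] + seq + sc.flank_3[:pad3]
        return np.fromiter((_BASE_INDEX[c] for c in full), dtype=np.int8, count=len(full))

    def encode_indices(self, idx: np.ndarray, shifts) -> np.ndarray:
        """One-hot frames (B, frame_length, 4), channels-last, from padded
        index rows, displaced by per-example shifts."""
        idx = np.atleast_2d(idx)
        B, P = idx.shape
        shifts = np.broadcast_to(np.asarray(shifts, dtype=int), (B,))
        if (shifts < 0).any() or (shifts > self.cfg.shift_max).any():
            raise ValueError("shift out of range")
        x = np.zeros((B, self.frame_length, 4), dtype=np.float32)
        cols = shifts[:, None] + np.arange(P)[None, :]
        x[np.arange(B)[:, None], cols, idx] = 1.0
        return x

    def encode_batch(self, seqs: list[str], library: str, shifts=0) -> np.ndarray:
        idx = np.stack([self.to_indices(s, library) for s in seqs])
        return self.encode_indices(idx, shifts)

    def embed_relaxed(self, x_seq: np.ndarray, library: str) -> np.ndarray:
        """Embed a relaxed (continuous) 4 x L promoter matrix into a shift-0
        channels-last frame with one-hot flanks; used by gradient-ascent
        design."""
        sc = self.scaffolds[library]
        pad5, pad3 = self.pads[library]
        frame = np.zeros((1, self.frame_length, 4), dtype=np.float32)
        f5 = sc.flank_5[len(sc.flank_5) - pad5 :]
        for j, c in enumerate(f5):
            frame[0, j, _BASE_INDEX[c]] = 1.0
        frame[0, pad5 : pad5 + sc.total_length, :] = np.asarray(x_seq).T
        f3 = sc.flank_3[:pad3]
        for j, c in enumerate(f3):
            frame[0, pad5 + sc.total_length + j, _BASE_INDEX[c]] = 1.0
        return frame


@dataclass(frozen=True)
class ArchitectureConfig:
    conv_blocks: int = 6
    kernel_width: int = 8
    channels: int = 128
    pool_stride: int = 2
    fc_units: tuple[int, ...] = (128, 128)
    n_outputs: int = 1
    l2_weight: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_outputs not in (1, 2):
            raise ValueError("n_outputs must be 1 or 2")
        if min(self.conv_blocks, self.kernel_width, self.channels, self.pool_stride) < 1:
            raise ValueError("all sizes must be positive")


def full_architecture(n_outputs: int = 1) -> ArchitectureConfig:
    """The full-scale architecture: six conv blocks of width 8 with 128
    channels, two 128-unit dense layers."""
    return ArchitectureConfig(n_outputs=n_outputs)


def small_architecture(n_outputs: int = 1) -> ArchitectureConfig:
    """Desk-scale preset: two conv blocks of 16 channels (dense layers as
    in the full architecture)."""
    return ArchitectureConfig(conv_blocks=2, channels=16, n_outputs=n_outputs)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    huber_delta: float = 0.15
    early_stop_patience: int = 5
    test_fraction: float = 0.1
    batch_size: int = 256
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


def small_train_config(**overrides) -> TrainConfig:
    """Training preset matched to the desk-scale architecture: a larger
    learning rate and smaller batches so small models converge in tens of
    epochs rather than the hundreds the full-scale rate would need."""
    defaults = dict(learning_rate=3e-3, batch_size=64, max_epochs=60)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def build_network(
    arch: ArchitectureConfig, input_length: int, rng: np.random.Generator
) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in, length = 4, input_length
    for _ in range(arch.conv_blocks):
        # same-padded convolutions: six pooling rounds on a ~360-bp frame
        # would otherwise shrink below the kernel width
        layers.append(nn.Conv1d(c_in, arch.channels, arch.kernel_width, rng, padding="same"))
        layers.append(nn.BatchNorm(arch.channels))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1d(arch.pool_stride))
        length = (length - arch.pool_stride) // arch.pool_stride + 1
        c_in = arch.channels
        if length < 1:
            raise ValueError("input too short for this many conv blocks")
    layers.append(nn.Flatten())
    features = c_in * length
    for units in arch.fc_units:
        layers.append(nn.Dense(features, units, rng))
        layers.append(nn.BatchNorm(units))
        layers.append(nn.ReLU())
        features = units
    # final output layer: no L2 regularization; near-zero init so initial
    # predictions start at the target mean rather than at He-init scale
    layers.append(nn.Dense(features, arch.n_outputs, rng, l2=False, init_scale=0.01))
    return nn.Sequential(layers)


def make_partitions(
    n_examples: int, k: int = 9, test_fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shared held-out test set plus k near-equal disjoint validation folds
    covering the remaining examples.  Deterministic given the seed."""
    if n_examples < k + 1:
        raise ValueError("not enough examples to partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_examples)
    n_test = int(round(n_examples * test_fraction))
    test = np.sort(perm[:n_test])
    rest = perm[n_test:]
    folds = [np.sort(f) for f in np.array_split(rest, k)]
    return test, folds


@dataclass
class TrainedModel:
    net: nn.Sequential
    history: list[dict]
    best_epoch: int


class EnsembleModel:
    """k trained submodels sharing a test set, with merge rules.

    Also implements the scorer protocol used by the design and mutagenesis
    stages: ``score_seqs(seqs, objective)`` and
    ``objective_grad(x, objective)``.
    """

    def __init__(
        self,
        submodels: list[TrainedModel],
        encoder: SequenceEncoder,
        library: str,
        n_outputs: int,
        test_indices: np.ndarray | None = None,
        validation_folds: list[np.ndarray] | None = None,
    ):
        if not submodels:
            raise ValueError("ensemble needs at least one submodel")
        self.submodels = submodels
        self.encoder = encoder
        self.library = library
        self.n_outputs = n_outputs
        self.test_indices = test_indices
        self.validation_folds = validation_folds

    @property
    def k(self) -> int:
        return len(self.submodels)

    def predict_frames(self, x: np.ndarray) -> np.ndarray:
        """(k, B, n_outputs) raw submodel predictions on encoded frames."""
        return np.stack([m.net.forward(x, train=False) for m in self.submodels])

    def predict_raw(self, seqs: list[str], batch_size: int = 512) -> np.ndarray:
        """(k, n, n_outputs) submodel predictions at shift 0."""
        out = []
        for i in range(0, len(seqs), batch_size):
            x = self.encoder.encode_batch(seqs[i : i + batch_size], self.library, 0)
            out.append(self.predict_frames(x))
        return np.concatenate(out, axis=1) if out else np.zeros((self.k, 0, self.n_outputs))

    def _channel(self, target: str) -> int:
        if self.n_outputs == 1:
            return 0
        return 1 if target == TARGET_INDUCED else 0

    def score_seqs(self, seqs: list[str], objective) -> np.ndarray:
        """Merged objective scores for a list of sequences."""
        preds = self.predict_raw(seqs)  # (k, n, n_out)
        if objective.target == TARGET_RATIO:
            if self.n_outputs != 2:
                raise ValueError("activation-ratio objective needs a 2-output model")
            ind = merge_predictions(preds[:, :, 1], objective.merge_mode)
            unind = merge_predictions(preds[:, :, 0], objective.merge_mode)
            return ind - unind
        c = self._channel(objective.target)
        return merge_predictions(preds[:, :, c], objective.merge_mode)

    def _merge_weights(self, y: np.ndarray, merge_mode: str) -> np.ndarray:
        """d(merged)/d(y_k) for one channel's submodel predictions y (k,)."""
        k = self.k
        w = np.full(k, 1.0 / k)
        if merge_mode == "mean_minus_sd":
            sd = y.std()  # population form, divisor k
            if sd > 1e-12:
                w = w - (y - y.mean()) / (k * sd)
        return w

    def objective_grad(self, x_seq: np.ndarray, objective) -> tuple[float, np.ndarray]:
        """Merged objective value and its gradient with respect to the
        relaxed 4 x L promoter input (shift 0, inference statistics)."""
        frame = self.encoder.embed_relaxed(x_seq, self.library)
        start, end = self.encoder.seq_region(self.library)
        preds = self.predict_frames(frame)[:, 0, :]  # (k, n_out)
        if objective.target == TARGET_RATIO:
            chans = [(0, -1.0), (1, +1.0)]
        else:
            chans = [(self._channel(objective.target), +1.0)]
        value = 0.0
        grad = np.zeros_like(frame)
        for c, sign in chans:
            y = preds[:, c]
            value += sign * float(merge_predictions(y[:, None], objective.merge_mode)[0])
            w = self._merge_weights(y, objective.merge_mode)
            for j, m in enumerate(self.submodels):
                out_w = np.zeros(self.n_outputs)
                out_w[c] = sign * w[j]
                grad += m.net.input_gradient(frame, out_w)
        return value, grad[0, start:end, :].T.astype(float)


def merge_predictions(preds: np.ndarray, merge_mode: str = "mean") -> np.ndarray:
    """Merge submodel predictions (k, n) -> (n,).

    ``mean`` averages; ``mean_minus_sd`` subtracts the population standard
    deviation (divisor k) to penalize sequences the submodels disagree on.
    """
    preds = np.asarray(preds)
    if merge_mode == "mean":
        return preds.mean(axis=0)
    if merge_mode == "mean_minus_sd":
        return preds.mean(axis=0) - preds.std(axis=0)
    raise ValueError(f"unknown merge mode {merge_mode!r}")


def predict_merge(ensemble: EnsembleModel, seqs: list[str], merge_mode: str = "mean") -> np.ndarray:
    """(n, n_outputs) merged predictions at shift 0."""
    preds = ensemble.predict_raw(seqs)
    return np.stack(
        [merge_predictions(preds[:, :, c], merge_mode) for c in range(ensemble.n_outputs)],
        axis=1,
    )


def train_submodel(
    idx_matrix: np.ndarray,
    targets: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    encoder: SequenceEncoder,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
    seed: int,
) -> TrainedModel:
    """Train one submodel with shift augmentation and early stopping.

    ``idx_matrix`` holds padded base indices (n, padded_length); targets are
    (n, n_outputs).  Training stops after ``early_stop_patience`` epochs
    without validation improvement and the best-epoch weights are restored.
    """
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation sets must be nonempty")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    rng = np.random.default_rng(seed)
    net = build_network(arch, encoder.frame_length, rng)
    opt = nn.Adam(net.params(), lr=cfg.learning_rate, l2_weight=arch.l2_weight)

    x_val = encoder.encode_indices(idx_matrix[val_idx], 0)
    y_val = targets[val_idx]

    def val_loss() -> float:
        pred = net.forward(x_val, train=False)
        loss, _ = nn.huber(y_val, pred, cfg.huber_delta)
        return loss

    history: list[dict] = []
    best = (np.inf, None, -1)
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        shifts = rng.integers(0, encoder.cfg.shift_max + 1, len(order))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            x = encoder.encode_indices(idx_matrix[sel], shifts[i : i + len(sel)])
            y = targets[sel]
            pred = net.forward(x, train=True)
            loss, dpred = nn.huber(y, pred, cfg.huber_delta)
            net.zero_grad()
            net.backward(dpred)
            opt.step()
            ep_loss += loss
            n_batches += 1
        vl = val_loss()
        history.append({"epoch": epoch, "train_loss": ep_loss / max(n_batches, 1), "val_loss": vl})
        if vl < best[0]:
            best = (vl, net.get_weights(), epoch)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    if best[1] is not None:
        net.set_weights(best[1])
    return TrainedModel(net, history, best[2])


def train_ensemble(
    seqs: list[str],
    targets: np.ndarray,
    library: str,
    encoder: SequenceEncoder,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
    k: int = 9,
) -> EnsembleModel:
    """Train a k-submodel ensemble: one shared test set, k validation folds;
    submodel j trains on every non-test fold except fold j."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[0] != len(seqs):
        targets = targets.T
    idx_matrix = np.stack([encoder.to_indices(s, library) for s in seqs])
    test, folds = make_partitions(len(seqs), k, cfg.test_fraction, cfg.seed)
    submodels = []
    for j in range(k):
        train_idx = np.concatenate([folds[i] for i in range(k) if i != j]) if k > 1 else np.concatenate(folds)
        if k == 1:
            # degenerate single-model case: hold fold 0 out of itself is
            # impossible, so fall back to an 80/10/10-style split
            rng = np.random.default_rng(cfg.seed + 1)
            perm = rng.permutation(folds[0])
            n_val = max(1, int(round(len(perm) * cfg.test_fraction / (1 - cfg.test_fraction))))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx = folds[j]
        submodels.append(
            train_submodel(
                idx_matrix, targets, train_idx, val_idx, encoder, arch, cfg, cfg.seed + 1000 + j
            )
        )
    return EnsembleModel(
        submodels, encoder, library, arch.n_outputs, test_indices=test, validation_folds=folds
    )
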