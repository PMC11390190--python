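"""Optimization recipe for the two networks.

Both networks train with SGD: weights initialized from a zero-mean
normal with standard deviation 0.01, biases zero, weight decay 0.0005,
batch size 64, and momentum ramped linearly from 0 to 0.9 over the
first 10 epochs.  The segmentation network uses a constant learning
rate of 2e-4 and per-cell binary cross-entropy against the ground-truth
mask downsampled to the 44x44 map grid; the patch classifier uses
2-class softmax cross-entropy and a learning-rate multiplier that is
1.0 up to epoch 10 and halves every 8 epochs thereafter
(``2^(-(epoch-6)/8)``, the decaying reading of the printed schedule).
The PReLU negative slope starts at 0.9 and decreases by 0.01 per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from thyronet import nn
from thyronet.architectures import Network


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 2e-4
    momentum: float = 0.9
    momentum_ramp_epochs: int = 10
    weight_decay: float = 0.0005
    init_std: float = 0.01
    batch_size: int = 64
    max_epochs: int = 20
    prelu_slope_init: float = 0.9
    prelu_slope_decay: float = 0.01
    lr_schedule: str = "constant"        # "constant" (CNN15) | "cnn4"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0 or self.init_std <= 0 or self.batch_size < 1:
            raise ValueError("base_lr, init_std positive; batch_size >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return select_best_epoch(self)

    def __len__(self) -> int:
        return len(self.train_loss)


def init_weights(network: Network, std: float = 0.01, seed: int = 0) -> Network:
    """Zero-mean normal weights with the given std; biases exactly zero."""
    if std <= 0:
        raise ValueError("std must be positive")
    rng = np.random.default_rng(seed)
    for p in network.params():
        if p.is_bias:
            p.data[...] = 0.0
        else:
            p.data[...] = rng.normal(0.0, std, size=p.data.shape)
    return network


def lr_multiplier_cnn4(epoch: int) -> float:
    """Classifier learning-rate multiplier: 1.0 through epoch 10, then
    ``2^(-(epoch - 6) / 8)`` — a smooth halving every 8 epochs."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    if epoch <= 10:
        return 1.0
    return float(2.0 ** (-(epoch - 6) / 8.0))


def _momentum_at(epoch: int, cfg: TrainConfig) -> float:
    """Linear 0 -> momentum ramp over the first ramp epochs."""
    if cfg.momentum_ramp_epochs <= 0:
        return cfg.momentum
    return cfg.momentum * min(epoch / cfg.momentum_ramp_epochs, 1.0)


def _prelu_slope_at(epoch: int, cfg: TrainConfig) -> float:
    return max(cfg.prelu_slope_init - cfg.prelu_slope_decay * (epoch - 1), 0.0)


def downsample_mask_to_map(mask: np.ndarray, cell: int = 8,
                           out_side: int = 44) -> np.ndarray:
    """Area-downsample a binary mask to the map grid and threshold at 0.5."""
    m = (np.asarray(mask) > 0).astype(np.float64)
    h, w = m.shape
    need = out_side * cell
    if h < need or w < need:
        m = np.pad(m, ((0, max(need - h, 0)), (0, max(need - w, 0))))
    m = m[:need, :need]
    blocks = m.reshape(out_side, cell, out_side, cell).mean(axis=(1, 3))
    return (blocks >= 0.5).astype(np.float32)


def _epoch_loop(network: Network, x: np.ndarray, y: np.ndarray,
                loss_fn, optimizer: nn.SGD, batch: int,
                rng: np.random.Generator) -> float:
    order = rng.permutation(len(x))
    losses = []
    for start in range(0, len(x), batch):
        idx = order[start:start + batch]
        logits = network.forward(x[idx])
        loss, dlogits = loss_fn(logits, y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        optimizer.zero_grad()
        network.backward(dlogits)
        optimizer.step()
        losses.append(loss)
    return float(np.mean(losses))


def _train(network: Network, x: np.ndarray, y: np.ndarray,
           x_val: np.ndarray, y_val: np.ndarray,
           cfg: TrainConfig, loss_fn, accuracy_fn) -> tuple[Network, TrainHistory]:
    if len(x) == 0:
        raise ValueError("empty training set")
    init_weights(network, std=cfg.init_std, seed=cfg.seed)
    opt = nn.SGD(network.params(), lr=cfg.base_lr, momentum=0.0,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    batch = min(cfg.batch_size, len(x))
    for epoch in range(1, cfg.max_epochs + 1):
        opt.momentum = _momentum_at(epoch, cfg)
        mult = lr_multiplier_cnn4(epoch) if cfg.lr_schedule == "cnn4" else 1.0
        opt.lr = cfg.base_lr * mult
        slope = _prelu_slope_at(epoch, cfg)
        for layer in network.prelu_layers():
            layer.slope = slope
        train_loss = _epoch_loop(network, x, y, loss_fn, opt, batch, rng)
        val_logits = network.forward(x_val)
        val_loss, _ = loss_fn(val_logits, y_val)
        history.train_loss.append(train_loss)
        history.val_loss.append(float(val_loss))
        history.val_accuracy.append(accuracy_fn(val_logits, y_val))
    return network, history


def train_cnn15(patches: np.ndarray, target_maps: np.ndarray,
                config: TrainConfig = TrainConfig(),
                network: Network | None = None,
                val_patches: np.ndarray | None = None,
                val_maps: np.ndarray | None = None) -> tuple[Network, TrainHistory]:
    """Train the segmentation network.

    ``patches`` is (N, 2, H, W) float input; ``target_maps`` is the
    matching (N, h, w) binary map stack (the ground-truth mask
    downsampled to the map grid).  Per-cell binary cross-entropy on the
    logits.  When no network is given the canonical CNN15 is built.
    """
    from thyronet.architectures import build_cnn15
    net = network if network is not None else build_cnn15()
    x = np.asarray(patches, dtype=np.float32)
    y = np.asarray(target_maps, dtype=np.float32)
    if y.ndim == 3:
        y = y[:, None]                   # (N, 1, h, w) to match the logits
    xv = x if val_patches is None else np.asarray(val_patches, dtype=np.float32)
    yv = y if val_maps is None else np.asarray(val_maps, dtype=np.float32)
    if yv.ndim == 3:
        yv = yv[:, None]

    def accuracy(logits, targets):
        pred = (logits >= 0).astype(np.float32)
        return float((pred == targets).mean())

    return _train(net, x, y, xv, yv, config, nn.bce_with_logits, accuracy)


def train_cnn4(patches: np.ndarray, labels: np.ndarray,
               config: TrainConfig | None = None,
               network: Network | None = None,
               val_patches: np.ndarray | None = None,
               val_labels: np.ndarray | None = None) -> tuple[Network, TrainHistory]:
    """Train the patch classifier with 2-class softmax cross-entropy.

    ``patches`` is (N, 2, 64, 64); ``labels`` integer 0/1.  The default
    base learning rate is the recipe's printed 1.0 — sensible here
    because the 0.01-std initialization keeps gradients minuscule.  A
    single-class training set is allowed (with a warning) but cannot
    produce a useful classifier.
    """
    import warnings

    from thyronet.architectures import build_cnn4
    if config is None:
        config = TrainConfig(base_lr=1.0, lr_schedule="cnn4")
    net = network if network is not None else build_cnn4()
    x = np.asarray(patches, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training set; classifier cannot discriminate")
    xv = x if val_patches is None else np.asarray(val_patches, dtype=np.float32)
    yv = y if val_labels is None else np.asarray(val_labels, dtype=np.int64)

    def accuracy(logits, targets):
        return float((logits.argmax(axis=1) == targets).mean())

    return _train(net, x, y, xv, yv, config, nn.softmax_cross_entropy, accuracy)


def split_dataset(n_items: int, mode: str = "ratio_433",
                  seed: int = 0,
                  custom: tuple[float, float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint (train, validation, test) index split.

    ``ratio_433`` divides 40/30/30%.  ``ratio_75_25`` holds out 25% for
    test and carves 10% of the training portion as validation so
    best-epoch selection stays possible.  ``custom`` takes explicit
    fractions summing to 1.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    if mode == "ratio_433":
        n_train = int(round(0.4 * n_items))
        n_val = int(round(0.3 * n_items))
    elif mode == "ratio_75_25":
        n_test = int(round(0.25 * n_items))
        n_val = int(round(0.1 * (n_items - n_test)))
        n_train = n_items - n_test - n_val
    elif mode == "custom":
        if custom is None or abs(sum(custom) - 1.0) > 1e-9:
            raise ValueError("custom mode needs fractions summing to 1")
        n_train = int(round(custom[0] * n_items))
        n_val = int(round(custom[1] * n_items))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    train = order[:n_train]
    val = order[n_train:n_train + n_val]
    test = order[n_train + n_val:]
    if min(len(train), len(val), len(test)) == 0:
        raise ValueError("fewer items than partitions")
    return train, val, test


def select_best_epoch(history: TrainHistory) -> int:
    """1-based epoch of minimum validation loss; earliest epoch on ties."""
    if len(history) == 0:
        raise ValueError("empty history")
    losses = np.asarray(history.val_loss)
    return int(np.argmin(losses)) + 1
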