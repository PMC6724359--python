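"""ActivityResNet: residual 1-D CNN over 6-channel IMU windows.

Classifies fixed-length accelerometer+gyroscope windows (4 s at 50 Hz by
default) into idle / walk / stairs / run / fall.  The architecture is a
convolutional stem followed by residual blocks (identity shortcut, 1x1
projection when the channel count changes) with max-pool downsampling,
global average pooling and a dense softmax head.  The training protocol is
the same as the segmentation network's: Adam at lr0 = 0.001, categorical
cross-entropy, reduce-on-plateau (factor 10, patience 2).

Streams are classified over sliding windows with 50% overlap; fall events
are additionally gated by a transient-magnitude pre-check so a fall is only
reported when the window actually contains a high-g impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .signal_io import ImuRecord
from .synth import ACTIVITIES, G
from .training import TrainHistory, fit, inverse_frequency_weights

__all__ = [
    "ActivityConfig",
    "ActivityResNet",
    "build_activity_model",
    "train_activity",
    "classify_stream",
    "evaluate_activity_cv",
    "FALL_GATE_G",
]

#: minimum acceleration-magnitude transient (in g) for the fall gate
FALL_GATE_G = 2.0


@dataclass
class ActivityConfig:
    window_s: float = 4.0
    fs: float = 50.0
    n_channels: int = 6
    classes: tuple[str, ...] = ACTIVITIES
    stem_filters: int = 16
    stem_kernel: int = 7
    block_filters: tuple[int, ...] = (16, 24, 32)
    block_kernel: int = 5
    activation: str = "relu"
    # training protocol (same form as the segmentation network)
    lr0: float = 1e-3
    lr_drop_factor: float = 10.0
    patience: int = 2
    split: float = 0.75
    val_split: float = 0.2
    k_folds: int = 4
    epochs: int = 20
    batch_size: int = 32
    class_weighting: bool = True
    seed: int = 0

    @property
    def window_len(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def n_classes(self) -> int:
        return len(self.classes)


class _ResBlock:
    """conv-BN-act-conv-BN + shortcut (1x1 projection on width change)."""

    def __init__(self, c_in, c_out, kernel, activation, rng):
        self.conv1 = nn.Conv1D(c_in, c_out, kernel, rng=rng)
        self.bn1 = nn.BatchNorm(c_out)
        self.act1 = nn.Activation(activation)
        self.conv2 = nn.Conv1D(c_out, c_out, kernel, rng=rng)
        self.bn2 = nn.BatchNorm(c_out)
        self.act2 = nn.Activation(activation)
        self.proj = nn.Conv1D(c_in, c_out, 1, rng=rng) if c_in != c_out else None

    def layers(self):
        out = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, train):
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train),
                                               train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        return self.act2.forward(h + s, train)

    def backward(self, dy):
        d = self.act2.backward(dy)
        ds = self.proj.backward(d) if self.proj is not None else d
        dh = self.conv1.backward(self.act1.backward(self.bn1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        return dh + ds


class ActivityResNet:
    """Residual IMU window classifier; input (N, L, 6) -> (N, 5) logits."""

    def __init__(self, cfg: ActivityConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = [nn.Conv1D(cfg.n_channels, cfg.stem_filters,
                               cfg.stem_kernel, rng=rng),
                     nn.BatchNorm(cfg.stem_filters),
                     nn.Activation(cfg.activation)]
        self.blocks, self.pools = [], []
        c = cfg.stem_filters
        for f in cfg.block_filters:
            self.blocks.append(_ResBlock(c, f, cfg.block_kernel,
                                         cfg.activation, rng))
            self.pools.append(nn.MaxPool(2))
            c = f
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(c, cfg.n_classes, rng=rng)
        # per-channel standardization constants, set from the training set
        self.norm_mean = np.zeros(cfg.n_channels, dtype=nn.DTYPE)
        self.norm_std = np.ones(cfg.n_channels, dtype=nn.DTYPE)

    def _all_layers(self):
        yield from self.stem
        for blk, pool in zip(self.blocks, self.pools):
            yield from blk.layers()
            yield pool
        yield self.gap
        yield self.head

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def set_normalization(self, X: np.ndarray) -> None:
        """Fix the per-channel z-score constants from a training set."""
        self.norm_mean[...] = X.reshape(-1, X.shape[-1]).mean(axis=0)
        self.norm_std[...] = X.reshape(-1, X.shape[-1]).std(axis=0) + 1e-9

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.shape[1] != self.cfg.window_len or x.shape[2] != self.cfg.n_channels:
            raise ValueError(f"expected windows ({self.cfg.window_len}, "
                             f"{self.cfg.n_channels}), got {x.shape[1:]}")
        h = (x - self.norm_mean) / self.norm_std
        for layer in self.stem:
            h = layer.forward(h, train)
        for blk, pool in zip(self.blocks, self.pools):
            h = blk.forward(h, train)
            h = pool.forward(h, train)
        return self.head.forward(self.gap.forward(h, train), train)

    def backward(self, dlogits):
        d = self.gap.backward(self.head.backward(dlogits))
        for blk, pool in zip(reversed(self.blocks), reversed(self.pools)):
            d = blk.backward(pool.backward(d))
        for layer in reversed(self.stem):
            d = layer.backward(d)
        return d / self.norm_std

    def predict_proba(self, X, batch_size=64):
        out = []
        for i in range(0, len(X), batch_size):
            out.append(nn.softmax(self.forward(np.asarray(X[i:i + batch_size]),
                                               train=False)))
        return np.concatenate(out, axis=0)

    def state_arrays(self):
        arrs = []
        for layer in self._all_layers():
            for p, _ in layer.params():
                arrs.append(p)
            if isinstance(layer, nn.BatchNorm):
                arrs.extend([layer.run_mean, layer.run_var])
        arrs.extend([self.norm_mean, self.norm_std])
        return arrs


def build_activity_model(cfg: ActivityConfig | None = None) -> ActivityResNet:
    return ActivityResNet(cfg or ActivityConfig())


def train_activity(model: ActivityResNet, X: np.ndarray, y: np.ndarray,
                   cfg: ActivityConfig | None = None, verbose=False) -> TrainHistory:
    """Train on IMU windows X (n, L, 6) with integer labels y (n,)."""
    cfg = cfg or model.cfg
    missing = set(range(cfg.n_classes)) - set(np.unique(y).tolist())
    if missing:
        warnings.warn(f"classes absent from training labels: {sorted(missing)}")
    model.set_normalization(np.asarray(X, float))
    w = inverse_frequency_weights(y, cfg.n_classes) if cfg.class_weighting else None
    return fit(model, np.asarray(X, float), np.asarray(y, np.int64),
               epochs=cfg.epochs, batch_size=cfg.batch_size, lr0=cfg.lr0,
               lr_drop_factor=cfg.lr_drop_factor, patience=cfg.patience,
               val_frac=cfg.val_split, seed=cfg.seed, class_weights=w,
               verbose=verbose)


def classify_stream(model: ActivityResNet, imu: ImuRecord, overlap: float = 0.5):
    """Classify an IMU stream over sliding windows (50% overlap by default).

    Returns a list of (t_center_s, class_name, confidence).  A window is only
    reported as ``fall`` when its acceleration magnitude actually contains a
    transient above the gate (reduces false alarms); the gate never
    suppresses a window whose transient exceeds 3 g.
    """
    cfg = model.cfg
    if imu.fs != cfg.fs:
        raise ValueError(f"stream at {imu.fs} Hz; model expects {cfg.fs} Hz")
    X = imu.channels
    L = cfg.window_len
    if len(X) < L:
        raise ValueError("stream shorter than one window")
    step = max(int(L * (1 - overlap)), 1)
    starts = range(0, len(X) - L + 1, step)
    W = np.stack([X[s:s + L] for s in starts])
    probs = model.predict_proba(W)
    acc_mag = np.linalg.norm(imu.acc, axis=1)
    fall_idx = cfg.classes.index("fall") if "fall" in cfg.classes else None
    out = []
    for s, p in zip(starts, probs):
        c = int(np.argmax(p))
        if fall_idx is not None and c == fall_idx:
            transient = float(acc_mag[s:s + L].max()) / G
            if transient < FALL_GATE_G:
                p = p.copy()
                p[fall_idx] = 0.0
                p /= p.sum()
                c = int(np.argmax(p))
        out.append(((s + L / 2) / cfg.fs, cfg.classes[c], float(p[c])))
    return out


def evaluate_activity_cv(X: np.ndarray, y: np.ndarray, cfg: ActivityConfig,
                         verbose=False):
    """Fourfold (by default) cross-validation of the activity classifier.

    Same contract as the segmentation network's ``evaluate_cv`` with
    per-window accuracy; folds are stratified by activity class.
    """
    from .annotation_net import evaluate_cv

    return evaluate_cv(X, y, cfg, groups=y,
                       model_factory=build_activity_model,
                       train_fn=train_activity, verbose=verbose)
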