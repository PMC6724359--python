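"""ECGSeq2Seq: encoder-decoder 1-D CNN for per-sample ECG annotation.

The network maps an 8 s, 2000-sample ECG window to a 2000x9 field of class
probabilities (semantic segmentation).  The encoder is a convolutional stem
(strided convolutions + max pooling) followed by inception-type blocks, each
halving the sequence length; the decoder restores the length with x2
nearest-neighbor upsampling stages, concatenating each upsampled feature map
with the encoder feature map of the same length (skip connections) before a
convolution.  Convolutions are followed by batch normalization and a linear
activation; the only nonlinearities between them are the max-pool stages and
the final per-sample softmax.

Training uses categorical cross-entropy with inverse-frequency class
weights, Adam at lr0 = 0.001, and a reduce-on-plateau schedule (factor 10,
patience 2 epochs on validation accuracy).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .signal_io import CLASS_NAMES, EcgRecord, make_windows
from .training import TrainHistory, fit, inverse_frequency_weights
from .vitals import BeatEvent

__all__ = [
    "Seq2SeqConfig",
    "EcgSeq2Seq",
    "AnnotationResult",
    "CvResult",
    "build_model",
    "train",
    "evaluate_cv",
    "annotate",
    "save_model",
    "load_model",
]

#: beat classes whose presence raises a record-level abnormality flag
ABNORMAL_BEAT_CLASSES = frozenset({"FB", "SVEB", "VEB"})


@dataclass
class Seq2SeqConfig:
    """Architecture and training protocol of the segmentation network.

    ``stem`` is a list of (filters, kernel, stride) convolutions applied
    before a max-pool of 2; each of the ``n_inception_blocks`` blocks has
    branches of kernel 1/3/5 plus a pooled branch, ``branch_filters`` filters
    each, and is followed by a max-pool of 2.  The decoder mirrors every
    halving with an upsample-by-2 stage and a ``decoder_kernel`` convolution
    of ``decoder_filters`` filters.
    """

    seq_len: int = 2000
    n_classes: int = 9
    stem: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(32, 7, 2), (32, 7, 2)])
    stem_pool: int = 2
    n_inception_blocks: int = 4
    branch_filters: int = 32
    branch_kernels: tuple[int, ...] = (1, 3, 5)
    decoder_filters: int = 32
    decoder_kernel: int = 3
    upsample_factor: int = 2
    activation: str = "linear"
    # training protocol
    lr0: float = 1e-3
    lr_drop_factor: float = 10.0
    patience: int = 2
    split: float = 0.75       # train fraction of a train/test split
    val_split: float = 0.2    # validation fraction within the training set
    k_folds: int = 4
    epochs: int = 20
    batch_size: int = 16
    class_weighting: bool = True
    seed: int = 0

    @classmethod
    def scaled(cls, **kw) -> "Seq2SeqConfig":
        """Desk-scale variant: same topology, narrower and shallower.

        At this capacity ReLU activations and an unweighted loss train far
        more efficiently than the full-scale protocol's linear activations
        and inverse-frequency weights, so the scaled variant uses them.
        """
        base = dict(stem=[(12, 7, 2)], n_inception_blocks=2, branch_filters=8,
                    decoder_filters=16, activation="relu",
                    class_weighting=False, epochs=10, batch_size=32)
        base.update(kw)
        return cls(**base)


class _InceptionBlock:
    """Parallel conv branches (k=1/3/5) + max-pool branch, concatenated."""

    def __init__(self, c_in, branch_filters, kernels, activation, rng):
        self.branches = []
        for k in kernels:
            self.branches.append([nn.Conv1D(c_in, branch_filters, k, rng=rng),
                                  nn.BatchNorm(branch_filters),
                                  nn.Activation(activation)])
        self.pool_branch = [nn.MaxPoolSame(3),
                            nn.Conv1D(c_in, branch_filters, 1, rng=rng),
                            nn.BatchNorm(branch_filters),
                            nn.Activation(activation)]
        self.c_out = branch_filters * (len(kernels) + 1)

    def layers(self):
        for br in self.branches:
            yield from br
        yield from self.pool_branch

    def forward(self, x, train):
        outs = []
        for br in self.branches:
            h = x
            for layer in br:
                h = layer.forward(h, train)
            outs.append(h)
        h = x
        for layer in self.pool_branch:
            h = layer.forward(h, train)
        outs.append(h)
        self._widths = [o.shape[2] for o in outs]
        return np.concatenate(outs, axis=2)

    def backward(self, dy):
        dxs = []
        ofs = 0
        paths = list(self.branches) + [self.pool_branch]
        for br, w in zip(paths, self._widths):
            d = dy[:, :, ofs:ofs + w]
            for layer in reversed(br):
                d = layer.backward(d)
            dxs.append(d)
            ofs += w
        return sum(dxs)


class EcgSeq2Seq:
    """The encoder-decoder segmentation model; tensors are (N, L, C)."""

    def __init__(self, cfg: Seq2SeqConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        act = cfg.activation
        # --- encoder ---
        self.stem_stages = []
        c = 1
        L = cfg.seq_len
        self._skip_lengths: list[int] = []
        for filters, kernel, stride in cfg.stem:
            self.stem_stages.append([nn.Conv1D(c, filters, kernel, stride, rng=rng),
                                     nn.BatchNorm(filters), nn.Activation(act)])
            c = filters
            L = -(-L // stride)
            self._skip_lengths.append(L)
        self.stem_pool = nn.MaxPool(cfg.stem_pool)
        L = -(-L // cfg.stem_pool)
        self.blocks = []
        self.block_pools = []
        for _ in range(cfg.n_inception_blocks):
            blk = _InceptionBlock(c, cfg.branch_filters, cfg.branch_kernels,
                                  act, rng)
            self.blocks.append(blk)
            self.block_pools.append(nn.MaxPool(2))
            c = blk.c_out
            self._skip_lengths.append(L)
            L = -(-L // 2)
        self.bottleneck_len = L
        # --- decoder: one upsample stage per halving, deepest first ---
        skip_channels = ([s[0].c_out for s in self.stem_stages]
                         + [b.c_out for b in self.blocks])
        # pair each decoder stage with the encoder feature of equal length
        self._dec_targets = list(reversed(self._skip_lengths)) + [cfg.seq_len]
        self._dec_skip_ch = list(reversed(skip_channels)) + [0]
        for i in range(1, len(self._dec_targets)):
            if self._dec_targets[i] < self._dec_targets[i - 1]:
                raise ValueError(
                    f"incompatible skip lengths: decoder stage {i} targets "
                    f"{self._dec_targets[i]} < previous {self._dec_targets[i - 1]}")
        Lu = self.bottleneck_len
        for i, tgt in enumerate(self._dec_targets):
            Lu *= cfg.upsample_factor
            if Lu < tgt:
                raise ValueError(
                    f"incompatible skip lengths: decoder stage {i} upsamples "
                    f"to {Lu} but its skip pair has length {tgt}")
            Lu = tgt
        self.dec_stages = []
        for tgt, sc in zip(self._dec_targets, self._dec_skip_ch):
            conv = nn.Conv1D(c + sc, cfg.decoder_filters, cfg.decoder_kernel,
                             rng=rng)
            self.dec_stages.append({
                "up": nn.Upsample(cfg.upsample_factor),
                "conv": conv, "bn": nn.BatchNorm(cfg.decoder_filters),
                "act": nn.Activation(act), "target": tgt, "skip_ch": sc})
            c = cfg.decoder_filters
        self.head = nn.Conv1D(c, cfg.n_classes, 1, rng=rng)

    # -- bookkeeping ------------------------------------------------------
    def _all_layers(self):
        for st in self.stem_stages:
            yield from st
        yield self.stem_pool
        for blk, pool in zip(self.blocks, self.block_pools):
            yield from blk.layers()
            yield pool
        for d in self.dec_stages:
            yield d["up"]
            yield d["conv"]
            yield d["bn"]
            yield d["act"]
        yield self.head

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    # -- forward / backward ----------------------------------------------
    def forward(self, x, train=True):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.cfg.seq_len:
            raise ValueError(f"model expects length {self.cfg.seq_len}, "
                             f"got {x.shape[1]}")
        skips = []
        h = x
        for stage in self.stem_stages:
            for layer in stage:
                h = layer.forward(h, train)
            skips.append(h)
        h = self.stem_pool.forward(h, train)
        for blk, pool in zip(self.blocks, self.block_pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        self._trims = []
        self._concat_widths = []
        skips_rev = list(reversed(skips)) + [None]
        for d, skip in zip(self.dec_stages, skips_rev):
            h = d["up"].forward(h, train)
            trim = h.shape[1] - d["target"]
            if trim < 0:
                raise ValueError("incompatible skip lengths: upsampled map "
                                 f"shorter than target {d['target']}")
            if trim:
                h = h[:, :d["target"], :]
            self._trims.append(trim)
            if skip is not None:
                self._concat_widths.append((h.shape[2], skip.shape[2]))
                h = np.concatenate([h, skip], axis=2)
            else:
                self._concat_widths.append((h.shape[2], 0))
            h = d["act"].forward(d["bn"].forward(d["conv"].forward(h, train),
                                                 train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        dskips = []  # gradients flowing into encoder skip maps, deepest first
        for stage, trim, (wc, ws) in zip(reversed(self.dec_stages),
                                         reversed(self._trims),
                                         reversed(self._concat_widths)):
            d = stage["conv"].backward(stage["bn"].backward(
                stage["act"].backward(d)))
            if ws:
                dskips.append(d[:, :, wc:])
                d = d[:, :, :wc]
            else:
                dskips.append(None)
            if trim:
                d = np.pad(d, ((0, 0), (0, trim), (0, 0)))
            d = stage["up"].backward(d)
        # backward visits decoder stages deepest-last, so dskips[0] is the
        # input-level stage (no skip) and the rest align with `skips`
        # shallow-first already
        dskips = dskips[1:]
        for blk, pool, dsk in zip(reversed(self.blocks),
                                  reversed(self.block_pools),
                                  reversed(dskips[len(self.stem_stages):])):
            d = pool.backward(d)
            d = d + dsk
            d = blk.backward(d)
        d = self.stem_pool.backward(d)
        for stage, dsk in zip(reversed(self.stem_stages),
                              reversed(dskips[:len(self.stem_stages)])):
            d = d + dsk
            for layer in reversed(stage):
                d = layer.backward(d)
        return d

    def predict_proba(self, X, batch_size=16):
        """(n, L) -> (n, L, n_classes) softmax probabilities."""
        out = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(np.asarray(X[i:i + batch_size]), train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)

    # -- checkpointing ----------------------------------------------------
    def state_arrays(self):
        arrs = []
        for layer in self._all_layers():
            for p, _ in layer.params():
                arrs.append(p)
            if isinstance(layer, nn.BatchNorm):
                arrs.extend([layer.run_mean, layer.run_var])
        return arrs


def build_model(cfg: Seq2SeqConfig | None = None) -> EcgSeq2Seq:
    """Construct an (untrained) ECGSeq2Seq from a config."""
    return EcgSeq2Seq(cfg or Seq2SeqConfig())


def train(model: EcgSeq2Seq, X: np.ndarray, Y: np.ndarray,
          cfg: Seq2SeqConfig | None = None, verbose=False) -> TrainHistory:
    """Train the segmentation model on windows X (n, L) with labels Y (n, L)."""
    cfg = cfg or model.cfg
    present = np.unique(Y)
    missing = set(range(cfg.n_classes)) - set(present.tolist())
    if missing:
        warnings.warn(f"classes absent from training labels: {sorted(missing)} "
                      "(macro metrics will be affected)")
    w = inverse_frequency_weights(Y, cfg.n_classes) if cfg.class_weighting else None
    return fit(model, np.asarray(X, float), np.asarray(Y, np.int64),
               epochs=cfg.epochs, batch_size=cfg.batch_size, lr0=cfg.lr0,
               lr_drop_factor=cfg.lr_drop_factor, patience=cfg.patience,
               val_frac=cfg.val_split, seed=cfg.seed, class_weights=w,
               verbose=verbose)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    accuracies: list[float]
    mean: float
    sd: float
    confusions: list[np.ndarray]
    histories: list[TrainHistory]
    notes: list[str]


def _fold_indices(n, k, rng, groups=None):
    """Disjoint folds; when ``groups`` is given the split is stratified so
    each fold carries a near-equal share of every group."""
    if groups is None:
        perm = rng.permutation(n)
        return [perm[i::k] for i in range(k)]
    folds = [[] for _ in range(k)]
    groups = np.asarray(groups)
    for g in np.unique(groups):
        idx = rng.permutation(np.flatnonzero(groups == g))
        for i in range(k):
            folds[i].extend(idx[i::k].tolist())
    return [np.asarray(sorted(f)) for f in folds]


def evaluate_cv(X: np.ndarray, Y: np.ndarray, cfg: Seq2SeqConfig,
                groups=None, model_factory=None, train_fn=None,
                verbose=False) -> CvResult:
    """k-fold cross-validation with disjoint folds.

    Returns per-fold confusion matrices (rows = true class) and the
    mean +- sd per-sample accuracy over test folds.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, np.int64)
    k = cfg.k_folds
    if len(X) < k * cfg.n_classes:
        raise ValueError("dataset too small for the requested folds")
    rng = np.random.default_rng(cfg.seed)
    folds = _fold_indices(len(X), k, rng, groups)
    model_factory = model_factory or (lambda c: build_model(c))
    train_fn = train_fn or train
    accs, confs, hists, notes = [], [], [], []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        model = model_factory(cfg)
        hists.append(train_fn(model, X[train_idx], Y[train_idx], cfg,
                              verbose=verbose))
        probs = model.predict_proba(X[test_idx], batch_size=cfg.batch_size)
        pred = probs.argmax(axis=-1).reshape(-1)
        true = Y[test_idx].reshape(-1)
        K = cfg.n_classes
        conf = np.zeros((K, K), dtype=np.int64)
        np.add.at(conf, (true, pred), 1)
        empty = [c for c in range(K) if conf[c].sum() == 0]
        if empty:
            notes.append(f"fold {fi}: no test samples for classes {empty}")
        accs.append(float((pred == true).mean()))
        confs.append(conf)
        if verbose:
            print(f"fold {fi}: accuracy {accs[-1]:.4f}")
    return CvResult(accuracies=accs, mean=float(np.mean(accs)),
                    sd=float(np.std(accs, ddof=1)) if k > 1 else 0.0,
                    confusions=confs, histories=hists, notes=notes)


# ---------------------------------------------------------------------------
# Beat-level annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    per_sample_probs: np.ndarray      # (n, n_classes)
    per_sample_class: np.ndarray      # (n,)
    beat_annotations: list[tuple[BeatEvent, str, float]]
    flags: set[str]


def annotate(model: EcgSeq2Seq, rec: EcgRecord, beats: list[BeatEvent],
             class_names=CLASS_NAMES, neighborhood_s: float = 0.3,
             rhythm_flag_frac: float = 0.5) -> AnnotationResult:
    """Convert per-sample scores into a human-readable beat annotation.

    Each detected beat is assigned the majority per-sample class within
    +-300 ms of its R-peak (ties broken toward the class with the higher
    mean probability there); confidence is the majority fraction.  Flags:
    ``abnormal_beat`` when any beat class is FB/SVEB/VEB; ``rhythm`` when a
    sustained rhythm class covers more than half of some window.
    """
    if rec.fs != 250.0:
        raise ValueError("annotate expects a 250 Hz record")
    L = model.cfg.seq_len
    n = len(rec.samples)
    K = model.cfg.n_classes
    probs = np.zeros((n, K))
    probs[:, 0] = 1.0
    starts = list(range(0, n - L + 1, L))
    if starts:
        Xw = np.stack([rec.samples[s:s + L] for s in starts])
        P = model.predict_proba(Xw)
        for s, p in zip(starts, P):
            probs[s:s + L] = p
    per_class = probs.argmax(axis=1)

    r = int(round(neighborhood_s * rec.fs))
    out = []
    flags: set[str] = set()
    for b in beats:
        lo, hi = max(0, b.index - r), min(n, b.index + r + 1)
        votes = np.bincount(per_class[lo:hi], minlength=K)
        top = np.flatnonzero(votes == votes.max())
        if len(top) > 1:  # tie-break by mean probability over the neighborhood
            top = [top[int(np.argmax([probs[lo:hi, c].mean() for c in top]))]]
        cls = int(top[0])
        conf = float(votes[cls] / votes.sum())
        name = class_names[cls]
        out.append((b, name, conf))
        if name in ABNORMAL_BEAT_CLASSES:
            flags.add("abnormal_beat")
    for s in starts:
        counts = np.bincount(per_class[s:s + L], minlength=K)
        for c in range(1, K):
            if class_names[c] in ("MI", "HF", "AR") and \
                    counts[c] > rhythm_flag_frac * L:
                flags.add("rhythm")
    return AnnotationResult(per_sample_probs=probs, per_sample_class=per_class,
                            beat_annotations=out, flags=flags)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model, directory) -> None:
    """Save weights (npz) with the config as JSON alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.cfg)
    cfg["__model__"] = type(model).__name__
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory, config_cls=None, model_cls=None):
    """Rebuild a model from :func:`save_model` output."""
    directory = Path(directory)
    cfg_dict = json.loads((directory / "config.json").read_text())
    kind = cfg_dict.pop("__model__", "EcgSeq2Seq")
    if model_cls is None:
        if kind == "EcgSeq2Seq":
            config_cls, model_cls = Seq2SeqConfig, EcgSeq2Seq
        else:
            from .activity_net import ActivityConfig, ActivityResNet
            config_cls, model_cls = ActivityConfig, ActivityResNet
    for k, v in list(cfg_dict.items()):
        if isinstance(v, list) and v and isinstance(v[0], list):
            cfg_dict[k] = [tuple(t) for t in v]
        elif isinstance(v, list) and k.endswith("kernels"):
            cfg_dict[k] = tuple(v)
    model = model_cls(config_cls(**cfg_dict))
    with np.load(directory / "weights.npz") as z:
        for i, a in enumerate(model.state_arrays()):
            a[...] = z[f"a{i}"]
    return model
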