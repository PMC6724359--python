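"""Shared training loop for the segmentation and activity networks.

Both networks are trained the same way: Adam starting at learning rate
0.001, categorical cross-entropy loss, and a reduce-on-plateau schedule that
divides the learning rate by 10 when validation accuracy has not improved
for ``patience`` consecutive epochs.  An 80/20 train/validation split is
carved out of the supplied training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, softmax_xent

__all__ = ["TrainHistory", "fit", "inverse_frequency_weights"]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Class weights proportional to 1/frequency, normalized to mean 1.

    Classes absent from ``y`` get weight 1 (a warning is the caller's job)."""
    counts = np.bincount(y.ravel(), minlength=n_classes).astype(float)
    w = np.ones(n_classes)
    present = counts > 0
    w[present] = 1.0 / counts[present]
    w[present] /= w[present].mean()
    return w


def _eval(model, X, y, class_weights, batch_size):
    losses, correct, total = [], 0, 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i:i + batch_size], train=False)
        lf = logits.reshape(-1, logits.shape[-1])
        yf = y[i:i + batch_size].reshape(-1)
        loss, _, p = softmax_xent(lf, yf, class_weights)
        losses.append(loss * len(yf))
        correct += int((p.argmax(axis=1) == yf).sum())
        total += len(yf)
    return float(np.sum(losses) / total), correct / total


def fit(model, X, y, *, epochs=20, batch_size=16, lr0=1e-3,
        lr_drop_factor=10.0, patience=2, val_frac=0.2, seed=0,
        class_weights=None, min_lr=1e-6, shuffle=True,
        verbose=False) -> TrainHistory:
    """Train ``model`` in place; returns the per-epoch history.

    ``model`` must expose ``forward(x, train)`` -> logits, ``backward(dlogits)``
    and ``parameters()``.  For sequence models logits are (N, L, K) and ``y``
    is (N, L); for window classifiers (N, K) and (N,).  Deterministic for a
    fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float32)
    n = len(X)
    idx = rng.permutation(n) if shuffle else np.arange(n)
    n_val = max(int(round(val_frac * n)), 1) if val_frac > 0 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=lr0)
    hist = TrainHistory()
    best_val = -np.inf
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, ep_correct, ep_total = 0.0, 0, 0
        for i in range(0, len(Xtr), batch_size):
            b = order[i:i + batch_size]
            logits = model.forward(Xtr[b], train=True)
            lf = logits.reshape(-1, logits.shape[-1])
            yf = ytr[b].reshape(-1)
            loss, grad, p = softmax_xent(lf, yf, class_weights)
            model.backward(grad.reshape(logits.shape))
            opt.step()
            ep_loss += loss * len(yf)
            ep_correct += int((p.argmax(axis=1) == yf).sum())
            ep_total += len(yf)
        hist.train_loss.append(ep_loss / ep_total)
        hist.train_acc.append(ep_correct / ep_total)
        if n_val:
            vl, va = _eval(model, Xval, yval, class_weights, batch_size)
        else:
            vl, va = hist.train_loss[-1], hist.train_acc[-1]
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        hist.lr.append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}: loss {hist.train_loss[-1]:.4f} "
                  f"acc {hist.train_acc[-1]:.4f} val_acc {va:.4f} lr {opt.lr:g}")
        # reduce-on-plateau: no improvement for `patience` consecutive epochs
        if va > best_val + 1e-12:
            best_val = va
            stale = 0
        else:
            stale += 1
            if stale >= patience and opt.lr > min_lr:
                opt.lr = max(opt.lr / lr_drop_factor, min_lr)
                stale = 0
    return hist
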