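"""Training loop and patient-level prediction.

The model is trained from scratch with stochastic gradient descent
(momentum 0.9, weight decay 0.0004, batch size 32) and per-cell
cross-entropy: the binary patient label is broadcast to every cell of the
86 x m head output, and the loss is the mean cross-entropy between the
per-cell softmax and that broadcast label.  The published hyperparameter
grids are learning rate {0.1, 0.01, 0.001} and epochs {200, 400, 600};
desk-scale experiments in this package use far fewer epochs (see
docs/methods.md).

A patient-level score is the mean class-1 probability over all head
cells — the natural scalar reduction consistent with the uniform
broadcast labels — thresholded at 0.5 for the confusion-based metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .resnet import CamModel, softmax

LR_GRID = (0.1, 0.01, 0.001)
EPOCH_GRID = (200, 400, 600)


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    epochs: int = 200
    momentum: float = 0.9
    weight_decay: float = 0.0004
    batch_size: int = 32
    seed: int = 0

    def replace(self, **kw) -> "TrainConfig":
        from dataclasses import replace

        return replace(self, **kw)


def broadcast_label(label: int, m: int, n_features: int = 86) -> np.ndarray:
    """The per-cell label array (n_features, m, 1), all cells = label."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    return np.full((n_features, m, 1), label, dtype=np.int64)


class SGD:
    """SGD with momentum and decoupled-from-nothing L2 weight decay."""

    def __init__(self, params, lr, momentum, weight_decay):
        self.params = params
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.value) for _, p in params]

    def step(self) -> None:
        for (name, p), v in zip(self.params, self.velocity):
            g = p.grad
            if self.wd and not name.endswith((".beta", ".gamma", ".bias")):
                g = g + self.wd * p.value
            v *= self.mu
            v += g
            p.value -= self.lr * v


def cell_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-cell cross-entropy and its gradient w.r.t. the logits.

    logits: (N, 86, m, 2); labels: (N,) binary.
    """
    p = softmax(logits)
    n, a, b, _ = logits.shape
    onehot = np.zeros_like(p)
    onehot[..., 1] = labels[:, None, None]
    onehot[..., 0] = 1 - labels[:, None, None]
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / (n * a * b))
    dlogits = ((p - onehot) / (n * a * b)).astype(np.float32)
    return loss, dlogits


def calibrate_batchnorm(
    model: CamModel, images: np.ndarray, batch_size: int = 16
) -> None:
    """Replace batch-norm running statistics with full-set statistics.

    At the short epoch counts used for desk-scale experiments the
    exponentially averaged running statistics lag far behind the trained
    weights, which corrupts evaluation-mode predictions; one extra pass
    over the training images with per-batch statistics pooled exactly
    fixes them.
    """
    bns = list(model.batchnorm_layers())
    saved = [(bn.momentum) for bn in bns]
    acc = [None] * len(bns)
    total = 0
    for k in range(0, len(images), batch_size):
        batch = images[k : k + batch_size]
        n = len(batch)
        for bn in bns:
            bn.momentum = 1.0  # running stats := this batch's stats
        model.forward(batch, train=True)
        for i, bn in enumerate(bns):
            m = bn.running_mean.copy()
            v = bn.running_var.copy()
            if acc[i] is None:
                acc[i] = [m * n, (v + m * m) * n]
            else:
                acc[i][0] += m * n
                acc[i][1] += (v + m * m) * n
        total += n
    for bn, mom, a in zip(bns, saved, acc):
        bn.momentum = mom
        mean = a[0] / total
        var = np.maximum(a[1] / total - mean * mean, 0)
        bn.set_stats(mean, var)
    model.clear_caches()


def train(
    model: CamModel,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
) -> list[float]:
    """Train in place; returns the per-epoch mean loss history.

    Deterministic given ``config.seed`` (which drives batch shuffling).
    Raises ``RuntimeError`` if the loss diverges to NaN, suggesting a
    smaller learning rate.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim == 3:
        images = images[..., None]
    n = len(images)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.params(), config.learning_rate, config.momentum,
              config.weight_decay)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for k in range(0, n, config.batch_size):
            idx = order[k : k + config.batch_size]
            model.zero_grad()
            logits = model.forward(images[idx], train=True)
            loss, dlogits = cell_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged (NaN/inf) at epoch {epoch}; "
                    "try a smaller learning rate"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    calibrate_batchnorm(model, images)
    return history


def predict_patient(model: CamModel, images: np.ndarray) -> np.ndarray:
    """Patient-level class-1 score(s): mean cell probability, in [0, 1].

    Accepts a single 224x224 image or a stack; evaluation mode (running
    batch-norm statistics), so the result does not depend on how patients
    are batched together.
    """
    single = np.asarray(images).ndim == 2
    probs = model.cell_probabilities(images)
    scores = probs[..., 1].mean(axis=(1, 2))
    return float(scores[0]) if single else scores
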