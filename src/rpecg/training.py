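"""Data splitting, augmentation, pixel-mean centering, and the SGD loop.

Training protocol: SGD with momentum 0.9 and weight decay 1e-4, initial
learning rate 0.1 divided by 10 whenever the validation error plateaus
(no improvement for ``plateau_patience`` epochs); batch size 128 by default
(256 selectable); no dropout.  Images are centered by subtracting the
per-pixel mean computed over the training set only.  Augmentation:
horizontal reflection with probability 1/2, integer translations up to
``translation_max_px`` with edge replication, and additive per-channel RGB
intensity jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "TrainConfig",
    "DataSplit",
    "split_data",
    "kfold_split",
    "compute_pixel_mean",
    "augment_image",
    "train_model",
    "evaluate_model",
    "recalibrate_batchnorm",
]


@dataclass
class TrainConfig:
    lr_initial: float = 0.1
    lr_divisor: float = 10.0
    plateau_patience: int = 5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 30
    seed: int = 0
    horizontal_flip: bool = True
    translation_max_px: int = 16
    rgb_jitter_sd: float = 0.05
    # alternative schedule: divide lr every lr_step_iters iterations instead
    # of on validation plateau
    lr_step_iters: int | None = None
    # keep the weights of the best-validation epoch (guards against
    # late-training divergence at high learning rates)
    restore_best: bool = True

    def __post_init__(self):
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class DataSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0


def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(r) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # largest remainder first
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_data(ids, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> DataSplit:
    """Random 70/15/15 (by default) partition with largest-remainder rounding."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    sizes = _largest_remainder_sizes(len(ids), fractions)
    a, b = sizes[0], sizes[0] + sizes[1]
    shuffled = [ids[i] for i in perm]
    return DataSplit(shuffled[:a], shuffled[a:b], shuffled[b:],
                     fractions=tuple(fractions), seed=seed)


def kfold_split(ids, k: int = 5, seed: int = 0) -> list[tuple[list, list]]:
    """k shuffled folds of near-equal size; each id tests exactly once."""
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = [ids[j] for j in folds[i]]
        train = [ids[j] for f in folds[:i] + folds[i + 1:] for j in f]
        out.append((train, test))
    return out


def compute_pixel_mean(images: np.ndarray) -> np.ndarray:
    """Per-pixel (H, W, C) mean over a stack of training images.

    Computed on the training set only and subtracted identically from
    train/val/test images.  ``axis="channel"`` behaviour is obtained by
    averaging the result over (0, 1) at the call site if wanted.
    """
    images = np.asarray(images)
    if images.size == 0:
        raise ValueError("empty image set")
    return images.mean(axis=0)


def augment_image(image: np.ndarray, config: TrainConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Random flip/translate/jitter of one (H, W, 3) image in [0, 1]."""
    out = image
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    t = config.translation_max_px
    if t > 0:
        dy, dx = int(rng.integers(-t, t + 1)), int(rng.integers(-t, t + 1))
        if dy or dx:
            out = _translate_edge_replicate(out, dy, dx)
    if config.rgb_jitter_sd > 0:
        out = out + rng.normal(0.0, config.rgb_jitter_sd, size=3).astype(out.dtype)
    return np.clip(out, 0.0, 1.0)


def _translate_edge_replicate(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    h, w = img.shape[:2]
    ys = np.clip(np.arange(h) - dy, 0, h - 1)
    xs = np.clip(np.arange(w) - dx, 0, w - 1)
    return img[np.ix_(ys, xs)]


def _to_nchw(images: np.ndarray, pixel_mean: np.ndarray | None,
             dtype=np.float32) -> np.ndarray:
    x = np.asarray(images, dtype=dtype)
    if pixel_mean is not None:
        x = x - pixel_mean.astype(dtype)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def recalibrate_batchnorm(network, images, pixel_mean=None, batch_size: int = 128,
                          max_images: int = 256):
    """Reset batch-norm running statistics to the exact average over the
    given (training) images.

    After short training runs the exponentially weighted running mean and
    variance lag far behind the batch statistics the network was actually
    trained with, which wrecks inference-mode predictions; a single
    streaming pass (momentum 1/k on the k-th batch) fixes them.
    """
    bns = [m for m in network.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    images = images[:max_images] if max_images else images
    for k, i in enumerate(range(0, len(images), batch_size), start=1):
        for bn in bns:
            bn.momentum = 1.0 / k
        x = _to_nchw(images[i:i + batch_size], pixel_mean)
        network.forward(x, train=True)
    for bn in bns:
        bn.momentum = 0.1


def evaluate_model(network, images: np.ndarray, pixel_mean: np.ndarray | None = None,
                   batch_size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Softmax scores and argmax labels (ties -> lowest class index)."""
    scores = []
    for i in range(0, len(images), batch_size):
        x = _to_nchw(images[i:i + batch_size], pixel_mean)
        scores.append(nn.softmax(network.forward(x, train=False)))
    scores = np.concatenate(scores) if scores else np.zeros((0, 1))
    return scores, scores.argmax(axis=1)


def train_model(network, train_images, train_labels, val_images, val_labels,
                config: TrainConfig, pixel_mean: np.ndarray | None = None,
                augment: bool = True, verbose: bool = False):
    """Train ``network`` by SGD with the plateau learning-rate schedule.

    ``train_labels``/``val_labels`` are integer class indices.  Returns the
    per-epoch history (train loss/error, validation error, learning rate);
    the network is modified in place.

    The learning rate is divided by ``lr_divisor`` whenever the validation
    error has not improved for ``plateau_patience`` consecutive epochs
    (or every ``lr_step_iters`` iterations if that mode is selected).
    """
    y_tr = np.asarray(train_labels, dtype=int)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    y_val = np.asarray(val_labels, dtype=int)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(network.params(), lr=config.lr_initial,
                 momentum=config.momentum, weight_decay=config.weight_decay)

    history = {"train_loss": [], "train_error": [], "val_error": [], "lr": []}
    best_val = np.inf
    best_state = None
    bns = [m for m in network.modules() if isinstance(m, nn.BatchNorm2d)]
    stale = 0
    iteration = 0
    n = len(train_images)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, errs = [], []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            batch = train_images[idx]
            if augment:
                batch = np.stack([augment_image(im, config, rng) for im in batch])
            x = _to_nchw(batch, pixel_mean)
            y = y_tr[idx]
            logits = network.forward(x, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            opt.zero_grad()
            network.backward(dlogits.astype(x.dtype))
            opt.step()
            losses.append(loss)
            errs.append(float((logits.argmax(axis=1) != y).mean()))
            iteration += 1
            if config.lr_step_iters and iteration % config.lr_step_iters == 0:
                opt.lr /= config.lr_divisor

        recalibrate_batchnorm(network, train_images, pixel_mean, config.batch_size)
        if len(val_images):
            _, pred = evaluate_model(network, val_images, pixel_mean,
                                     config.batch_size)
            val_error = float((pred != y_val).mean())
        else:
            val_error = float(np.mean(errs))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_error"].append(float(np.mean(errs)))
        history["val_error"].append(val_error)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}: loss={history['train_loss'][-1]:.4f} "
                  f"train_err={history['train_error'][-1]:.4f} "
                  f"val_err={val_error:.4f} lr={opt.lr:g}")

        improved = val_error < best_val - 1e-12
        if improved:
            best_val = val_error
            if config.restore_best:
                best_state = ([p.data.copy() for p in network.params()],
                              [(bn.running_mean.copy(), bn.running_var.copy())
                               for bn in bns])
        if config.lr_step_iters is None:
            if improved:
                stale = 0
            else:
                stale += 1
                if stale >= config.plateau_patience:
                    opt.lr /= config.lr_divisor
                    stale = 0

    if config.restore_best and best_state is not None:
        params, bn_stats = best_state
        for p, saved in zip(network.params(), params):
            p.data[...] = saved
        for bn, (mean, var) in zip(bns, bn_stats):
            bn.running_mean, bn.running_var = mean, var
    return history
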