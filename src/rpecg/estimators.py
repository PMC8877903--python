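"""scikit-learn-style classifier wrapping the numpy residual networks.

``ResNetClassifier`` takes recurrence-plot images as (n, H, W, 3) float
arrays in [0, 1] and arbitrary (string or integer) class labels; it centers
images by the training-set per-pixel mean, trains by SGD with the plateau
learning-rate schedule, and predicts by softmax argmax.  It composes with
sklearn pipelines and model selection (get_params/set_params, classes_,
predict_proba).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .resnet_model import build_network, count_parameters
from .training import TrainConfig, compute_pixel_mean, evaluate_model, train_model

__all__ = ["ResNetClassifier"]


class ResNetClassifier(ClassifierMixin, BaseEstimator):
    """Residual CNN classifier over RGB images.

    Parameters
    ----------
    depth : 18, 34, 50, 101 or 152.
    base_width : width of the first residual stage (64 is the canonical
        network; smaller values give proportionally cheaper models).
    input_size : expected image side; fit validates against the data.
    epochs, batch_size, lr, momentum, weight_decay, plateau_patience :
        SGD protocol (defaults follow the training recipe: lr 0.1 divided
        by 10 on validation-error plateau, momentum 0.9, weight decay 1e-4).
    augment : enable flip/translate/jitter augmentation during fit.
    translation_max_px, rgb_jitter_sd : augmentation strengths.
    val_fraction : slice of the training data held out to drive the
        plateau schedule when no explicit validation set is passed to fit.
    seed : controls initialization, shuffling and augmentation.

    Attributes (after fit)
    ----------------------
    classes_ : sorted unique labels.
    network_ : the trained network.
    pixel_mean_ : per-pixel training mean subtracted from every input.
    history_ : per-epoch loss/error/lr record.
    n_parameters_ : trainable parameter count.
    """

    def __init__(self, depth: int = 18, base_width: int = 64, input_size: int = 224,
                 epochs: int = 10, batch_size: int = 128, lr: float = 0.1,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 plateau_patience: int = 5, augment: bool = True,
                 translation_max_px: int = 16, rgb_jitter_sd: float = 0.05,
                 val_fraction: float = 0.15, seed: int = 0):
        self.depth = depth
        self.base_width = base_width
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.plateau_patience = plateau_patience
        self.augment = augment
        self.translation_max_px = translation_max_px
        self.rgb_jitter_sd = rgb_jitter_sd
        self.val_fraction = val_fraction
        self.seed = seed

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"expected (n, H, W, 3) images, got shape {X.shape}")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"images are {X.shape[1]}x{X.shape[2]} but input_size={self.input_size}"
            )
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")

        cfg = TrainConfig(
            lr_initial=self.lr, plateau_patience=self.plateau_patience,
            momentum=self.momentum, weight_decay=self.weight_decay,
            batch_size=self.batch_size, max_epochs=self.epochs, seed=self.seed,
            horizontal_flip=self.augment,
            translation_max_px=self.translation_max_px if self.augment else 0,
            rgb_jitter_sd=self.rgb_jitter_sd if self.augment else 0.0,
        )
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            n_val = int(round(self.val_fraction * len(X)))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr = X[tr_idx], y_idx[tr_idx]
            Xv, yv = X[val_idx], y_idx[val_idx]
        else:
            X_tr, y_tr = X, y_idx
            Xv = self._validate_images(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))

        self.pixel_mean_ = compute_pixel_mean(X_tr)
        self.network_ = build_network(
            depth=self.depth, num_classes=len(self.classes_),
            input_size=self.input_size, base_width=self.base_width,
            seed=self.seed,
        )
        self.n_parameters_ = count_parameters(self.network_)
        self.history_ = train_model(
            self.network_, X_tr, y_tr, Xv, yv, cfg,
            pixel_mean=self.pixel_mean_, augment=self.augment,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_images(X)
        scores, _ = evaluate_model(self.network_, X, self.pixel_mean_,
                                   self.batch_size)
        return scores

    def predict(self, X):
        scores = self.predict_proba(X)
        return self.classes_[scores.argmax(axis=1)]

    # ---- persistence: npz of weights + BN stats, JSON-able sidecar dict
    def save(self, path: str) -> None:
        """Serialize the fitted model to ``<path>`` (.npz) plus
        ``<path>.json`` holding the architecture and classes."""
        import json

        from . import nn

        arrays = {f"param_{i}": p.data for i, p in enumerate(self.network_.params())}
        bns = [m for m in self.network_.modules() if isinstance(m, nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        arrays["pixel_mean"] = self.pixel_mean_
        np.savez_compressed(path, **arrays)
        sidecar = {"params": self.get_params(),
                   "classes": [str(c) for c in self.classes_],
                   "spec": self.network_.spec.to_dict()}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ResNetClassifier":
        import json

        from . import nn

        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        est = cls(**sidecar["params"])
        est.classes_ = np.array(sidecar["classes"])
        est.network_ = build_network(
            depth=est.depth, num_classes=len(est.classes_),
            input_size=est.input_size, base_width=est.base_width, seed=est.seed,
        )
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(est.network_.params()):
            p.data[...] = data[f"param_{i}"]
        bns = [m for m in est.network_.modules() if isinstance(m, nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"bn_mean_{i}"]
            bn.running_var = data[f"bn_var_{i}"]
        est.pixel_mean_ = data["pixel_mean"]
        est.n_parameters_ = count_parameters(est.network_)
        return est
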