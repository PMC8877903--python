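"""Recurrence plots and their rendering as fixed-size RGB images.

A recurrence plot of a time series x with embedding dimension m and delay
tau compares every pair of delay-embedded states.  The unthresholded
variant keeps the raw pairwise distances D[i, j] = ||x_i - x_j||; the
thresholded variant binarizes them through a Heaviside step at a cutoff
epsilon (with Theta(0) = 1, so the identity diagonal is always recurrent).

Rendering: distances are min-max normalized to [0, 1] per matrix, mapped
through a piecewise-linear rainbow colormap (the classic "jet" breakpoints:
dark blue -> blue -> cyan -> green -> yellow -> red -> dark red), resized to
``size x size`` with bilinear interpolation, and flipped so row 0 sits at
the bottom (the identity diagonal runs lower-left to upper-right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RpMatrix",
    "rp_unthresholded",
    "rp_thresholded",
    "rp_to_image",
    "jet_colormap",
    "RecurrencePlotImager",
]


@dataclass
class RpMatrix:
    """N x N pairwise-distance (or binary recurrence) matrix."""

    D: np.ndarray
    m: int = 1
    tau: int = 1
    epsilon: float | None = None   # set only for the thresholded variant

    @property
    def N(self) -> int:
        return self.D.shape[0]


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay embedding: row i is (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    x = np.asarray(x, dtype=float).ravel()
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_states = len(x) - (m - 1) * tau
    if n_states < 2:
        raise ValueError(
            f"sequence of length {len(x)} too short for m={m}, tau={tau} embedding"
        )
    idx = np.arange(n_states)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def rp_unthresholded(x, m: int = 1, tau: int = 1) -> RpMatrix:
    """Unthresholded recurrence plot: D[i, j] = ||state_i - state_j||.

    For m = 1 this is simply |x_i - x_j|.
    """
    states = _embed(x, m, tau)
    if m == 1:
        v = states[:, 0]
        D = np.abs(v[:, None] - v[None, :])
    else:
        D = squareform(pdist(states, metric="euclidean"))
    return RpMatrix(D=D, m=m, tau=tau)


def rp_thresholded(x, epsilon: float, m: int = 1, tau: int = 1) -> RpMatrix:
    """Thresholded recurrence plot: Theta(epsilon - D), with Theta(0) = 1."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rp = rp_unthresholded(x, m=m, tau=tau)
    R = (epsilon - rp.D >= 0).astype(float)
    return RpMatrix(D=R, m=m, tau=tau, epsilon=float(epsilon))


# Piecewise-linear "jet" anchors: position in [0,1] -> (r, g, b).
_JET_ANCHORS = np.array([
    [0.000, 0.0, 0.0, 0.5],
    [0.125, 0.0, 0.0, 1.0],
    [0.375, 0.0, 1.0, 1.0],
    [0.625, 1.0, 1.0, 0.0],
    [0.875, 1.0, 0.0, 0.0],
    [1.000, 0.5, 0.0, 0.0],
])


def jet_colormap(values: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] to RGB via the documented jet breakpoints."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    pos = _JET_ANCHORS[:, 0]
    out = np.empty(v.shape + (3,))
    for c in range(3):
        out[..., c] = np.interp(v, pos, _JET_ANCHORS[:, c + 1])
    return out


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Deterministic bilinear resize of an H x W x 3 float array."""
    chans = [
        np.asarray(
            Image.fromarray(img[:, :, c].astype(np.float32), mode="F")
            .resize((size, size), resample=Image.BILINEAR)
        )
        for c in range(3)
    ]
    return np.stack(chans, axis=-1).astype(float)


def rp_to_image(rp: RpMatrix, size: int = 224, global_range: tuple | None = None) -> np.ndarray:
    """Render an RpMatrix as a ``size x size x 3`` RGB array in [0, 1].

    Distances are min-max normalized per matrix (a constant matrix maps to
    all zeros) unless ``global_range=(lo, hi)`` pins the normalization,
    then colored with :func:`jet_colormap`, bilinearly resized, and flipped
    vertically so the identity diagonal runs lower-left to upper-right.
    """
    if rp.N < 2:
        raise ValueError("RP matrix must be at least 2 x 2 to render")
    D = np.asarray(rp.D, dtype=float)
    if global_range is not None:
        lo, hi = global_range
    else:
        lo, hi = float(D.min()), float(D.max())
    norm = np.zeros_like(D) if hi <= lo else np.clip((D - lo) / (hi - lo), 0.0, 1.0)
    rgb = jet_colormap(norm)
    if rgb.shape[0] != size:
        rgb = _bilinear_resize(rgb, size)
    rgb = np.flipud(rgb)
    return np.clip(rgb, 0.0, 1.0)


def save_png(image: np.ndarray, path: str) -> None:
    """Write an RGB float image in [0,1] as 8-bit PNG."""
    arr = np.clip(np.rint(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


class RecurrencePlotImager(BaseEstimator, TransformerMixin):
    """Transformer: 1-D segments -> recurrence-plot RGB images.

    Parameters
    ----------
    size : output image side in pixels (default 224).
    m, tau : delay-embedding dimension and lag (default 1, 1: raw samples
        as states).
    thresholded : if True, binarize at ``epsilon`` before rendering.
    epsilon : cutoff distance for the thresholded variant.

    Stateless (``fit`` is a no-op); ``transform`` accepts a list/array of
    equal- or unequal-length 1-D sequences and returns an (n, size, size, 3)
    float array.
    """

    def __init__(self, size: int = 224, m: int = 1, tau: int = 1,
                 thresholded: bool = False, epsilon: float = 0.1):
        self.size = size
        self.m = m
        self.tau = tau
        self.thresholded = thresholded
        self.epsilon = epsilon

    def fit(self, X, y=None):
        self.n_features_in_ = None if not hasattr(X[0], "__len__") else len(X[0])
        return self

    def transform(self, X) -> np.ndarray:
        out = np.empty((len(X), self.size, self.size, 3), dtype=np.float32)
        for i, x in enumerate(X):
            if self.thresholded:
                rp = rp_thresholded(x, self.epsilon, m=self.m, tau=self.tau)
            else:
                rp = rp_unthresholded(x, m=self.m, tau=self.tau)
            out[i] = rp_to_image(rp, size=self.size)
        return out
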