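"""Training loop, preprocessing and inference for the dense V-Net.

Training follows the recipe used for cervical-muscle Dixon segmentation:
uniform spatial-window sampling (a fixed number of windows per volume per
pass), Adam with L2 weight decay, ReLU activations and the Dice-hinge
loss, stopping when the validation Sørensen-Dice plateaus.  Every source
of randomness (window sampling, dropout) flows from the single config
seed, so two single-threaded runs with the same seed produce identical
loss traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .losses import (
    dice_hinge_loss,
    dlogits_from_dprobs,
    hard_dice,
    one_hot,
    softmax,
)
from .model import DenseVNet

__all__ = [
    "TrainingConfig",
    "ProbabilisticSegmentation",
    "preprocess",
    "train",
    "segment",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters; defaults match the full-scale recipe
    except for the spatial window, which is sized for desk-scale grids."""

    learning_rate: float = 0.001
    optimizer: str = "adam"
    activation: str = "relu"
    l2_decay: float = 1e-5
    batch_size: int = 3
    samples_per_volume: int = 3
    window_shape: tuple[int, int, int] = (48, 48, 8)
    max_iterations: int = 1000
    val_interval: int = 50
    plateau_patience: int = 6
    plateau_tol: float = 2e-3
    hinge_margin: float = 0.1
    loss: str = "dice_hinge"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_iterations < 1:
            raise ValueError("rates and sizes must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")
        if self.loss not in ("dice_hinge", "dice"):
            raise ValueError("loss must be 'dice_hinge' or 'dice'")


@dataclass
class ProbabilisticSegmentation:
    """Per-class probabilities (C, X, Y, Z); hard labels by per-voxel argmax."""

    probabilities: np.ndarray
    index_to_label: dict | None = None

    def __post_init__(self) -> None:
        s = self.probabilities.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("per-voxel class probabilities must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[0]

    def hard_labels(self) -> np.ndarray:
        idx = self.probabilities.argmax(axis=0).astype(np.int16)
        if self.index_to_label is None:
            return idx
        lut = np.zeros(max(self.index_to_label) + 1, dtype=np.int16)
        for i, lbl in self.index_to_label.items():
            lut[i] = lbl
        return lut[idx]


# --------------------------------------------------------------- preprocess
def preprocess(images, mask, spacing, target_spacing=(0.7, 0.7, 3.0), pad_to=None):
    """Resample to a target voxel spacing and zero-pad symmetrically.

    Linear interpolation for intensity grids, nearest neighbour for the
    label map (the label set can only shrink, never gain values).  If
    ``pad_to`` is smaller than the resampled data an error is raised — no
    silent cropping.  Returns ``(images, mask, new_spacing)``.
    """
    zoom = [s / t for s, t in zip(spacing, target_spacing)]
    if np.allclose(zoom, 1.0):
        out_images = [np.asarray(g, dtype=float).copy() for g in images]
        out_mask = None if mask is None else np.asarray(mask).copy()
    else:
        out_images = [
            ndimage.zoom(np.asarray(g, dtype=float), zoom, order=1) for g in images
        ]
        out_mask = (
            None
            if mask is None
            else ndimage.zoom(np.asarray(mask), zoom, order=0)
        )
    shape = out_images[0].shape
    if pad_to is not None:
        pad = []
        for s, t in zip(shape, pad_to):
            if t < s:
                raise ValueError(
                    f"pad_to {tuple(pad_to)} is smaller than data shape {shape}; "
                    "refusing to crop"
                )
            before = (t - s) // 2
            pad.append((before, t - s - before))
        out_images = [np.pad(g, pad) for g in out_images]
        if out_mask is not None:
            out_mask = np.pad(out_mask, pad)
    return out_images, out_mask, tuple(target_spacing)


# ------------------------------------------------------------------- train
def _sample_window(rng, image, labels, window):
    lo = [rng.integers(0, s - w + 1) for s, w in zip(labels.shape, window)]
    sl = tuple(slice(l, l + w) for l, w in zip(lo, window))
    return image[(slice(None),) + sl], labels[sl]


def _window_queue(rng, n_volumes, samples_per_volume):
    """Yield volume indices: shuffled passes, each volume repeated
    samples_per_volume times per pass."""
    while True:
        order = rng.permutation(n_volumes)
        for v in order:
            for _ in range(samples_per_volume):
                yield int(v)


def mean_foreground_dice(model: DenseVNet, volumes, n_classes: int) -> float:
    """Mean hard Dice over foreground classes and volumes (nan-skipping)."""
    scores = []
    for image, labels in volumes:
        seg = segment(model, image)
        scores.append(hard_dice(seg.hard_labels(), labels, n_classes))
    return float(np.nanmean(np.stack(scores)))


def train(model: DenseVNet, dataset, config: TrainingConfig, validation=None):
    """Train in place; returns a history dict.

    ``dataset``/``validation`` are sequences of ``(image, labels)`` with
    ``image`` a (C, X, Y, Z) float grid and ``labels`` an (X, Y, Z) integer
    grid of class indices in ``[0, n_classes)``.  Validation defaults to
    the (non-augmented) training volumes.  Stops at ``max_iterations`` or
    when the best validation Dice has not improved by ``plateau_tol`` for
    ``plateau_patience`` consecutive validations.  A non-finite loss
    aborts with diagnostics.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    n_classes = model.config.n_classes
    window = config.window_shape
    model.check_window(window)
    for image, labels in dataset:
        if any(s < w for s, w in zip(labels.shape, window)):
            raise ValueError(
                f"volume shape {labels.shape} smaller than window {window}"
            )
    if validation is None:
        validation = dataset

    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(lr=config.learning_rate, l2_decay=config.l2_decay)
    margin = config.hinge_margin if config.loss == "dice_hinge" else 0.0
    queue = _window_queue(rng, len(dataset), config.samples_per_volume)

    history = {"iterations": [], "loss": [], "val_iterations": [], "val_dice": []}
    best = -math.inf
    stale = 0
    for it in range(1, config.max_iterations + 1):
        xs, ys = [], []
        for _ in range(config.batch_size):
            v = next(queue)
            image, labels = dataset[v]
            xw, yw = _sample_window(rng, np.asarray(image), np.asarray(labels), window)
            xs.append(xw)
            ys.append(yw)
        x = np.stack(xs).astype(np.float32)
        y = one_hot(np.stack(ys).astype(np.int64), n_classes)
        logits = model.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        loss, dprobs = dice_hinge_loss(probs, y, hinge_margin=margin)
        if not math.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: loss={loss}, "
                f"|logits| max={np.abs(logits).max():.3g}"
            )
        model.backward(dlogits_from_dprobs(probs, dprobs))
        opt.step()
        history["iterations"].append(it)
        history["loss"].append(loss)

        if it % config.val_interval == 0 or it == config.max_iterations:
            vd = mean_foreground_dice(model, validation, n_classes)
            history["val_iterations"].append(it)
            history["val_dice"].append(vd)
            if vd > best + config.plateau_tol:
                best = vd
                stale = 0
            else:
                stale += 1
            if stale >= config.plateau_patience:
                break
    return history


# ------------------------------------------------------------------ segment
def segment(model: DenseVNet, image, window_shape=None,
            index_to_label: dict | None = None) -> ProbabilisticSegmentation:
    """Probabilistic segmentation of one (C, X, Y, Z) volume.

    Volumes larger than ``window_shape`` are processed in half-overlapping
    tiles whose softmax probabilities are averaged; the hard label map is
    the per-voxel argmax mapped back through ``index_to_label`` when given.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"expected a (C, X, Y, Z) volume, got shape {x.shape}")
    if x.shape[0] != model.config.input_channels:
        raise ValueError(
            f"expected {model.config.input_channels} channels, got {x.shape[0]}"
        )
    spatial = x.shape[1:]
    if window_shape is None:
        window_shape = spatial
    window_shape = tuple(min(w, s) for w, s in zip(window_shape, spatial))
    model.check_window(window_shape)

    if window_shape == tuple(spatial):
        logits = model.forward(x[None], training=False)[0]
        probs = softmax(logits, axis=0)
        return ProbabilisticSegmentation(probs, index_to_label)

    acc = np.zeros((model.config.n_classes,) + spatial, dtype=np.float64)
    weight = np.zeros(spatial, dtype=np.float64)
    starts = []
    for s, w in zip(spatial, window_shape):
        step = max(1, w // 2)
        st = list(range(0, s - w + 1, step))
        if st[-1] != s - w:
            st.append(s - w)
        starts.append(st)
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + window_shape[0]),
                      slice(sy, sy + window_shape[1]),
                      slice(sz, sz + window_shape[2]))
                logits = model.forward(x[(slice(None),) + sl][None], training=False)[0]
                acc[(slice(None),) + sl] += softmax(logits, axis=0)
                weight[sl] += 1.0
    probs = (acc / weight[None]).astype(np.float32)
    probs /= probs.sum(axis=0, keepdims=True)
    return ProbabilisticSegmentation(probs, index_to_label)
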