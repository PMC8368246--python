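"""Training-set augmentation for volumetric Dixon images with label maps.

The augmentation chain applied to each sample is, in order: label-aware
left-right mirroring, coarse elastic deformation, anisotropic scaling and
three-axis rotation.  Defaults follow the values used for cervical muscle
segmentation training: elastic deformation with 3 control points and
sigma = 10, scaling of ±2.5% per axis, rotations of ±2.5° about the
left-right and anterior-posterior axes and ±5.0° about the
superior-inferior axis, with 2,000 augmented samples drawn from the
training pool.

Mirroring flips the left-right (first) axis of images and mask AND swaps
every left label with its paired right label, so a flipped sample remains
anatomically consistent — without the swap, mirrored samples would teach a
model impossible label-side associations.

Intensity grids are interpolated linearly, label maps with nearest
neighbour; voxels mapped from outside the field of view become background.
Intensity preprocessing (piecewise-linear histogram standardisation) and
label normalisation to contiguous training indices also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dixon import SegmentationMask
from .labels import MuscleLabelScheme

__all__ = [
    "AugmentationConfig",
    "mirror_lr",
    "elastic_deform",
    "random_affine",
    "augment_dataset",
    "fit_landmarks",
    "histogram_standardize",
    "normalize_labels",
    "denormalize_labels",
]

#: Percentile positions of the histogram landmarks (Nyul-style deciles
#: plus near-extremes).
LANDMARK_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the random augmentation chain."""

    mirror_prob: float = 0.5
    elastic_control_points: int = 3
    elastic_sigma: float = 10.0
    scale_percent: float = 2.5
    rot_lr_deg: float = 2.5
    rot_ap_deg: float = 2.5
    rot_si_deg: float = 5.0
    n_augmented: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mirror_prob <= 1.0:
            raise ValueError("mirror_prob must lie in [0, 1]")
        for name in ("elastic_sigma", "scale_percent", "rot_lr_deg", "rot_ap_deg", "rot_si_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.elastic_control_points < 1:
            raise ValueError("elastic_control_points must be >= 1")
        if self.n_augmented < 0:
            raise ValueError("n_augmented must be >= 0")


def _as_grids(images) -> list[np.ndarray]:
    grids = [np.asarray(im, dtype=float) for im in images]
    if not grids:
        raise ValueError("need at least one intensity grid")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("all intensity grids must share one shape")
    return grids


def _mask_grid(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)


def _wrap_mask(labels: np.ndarray, template) -> SegmentationMask | np.ndarray:
    if isinstance(template, SegmentationMask):
        return SegmentationMask(
            labels=labels, spacing=template.spacing, affine=template.affine
        )
    return labels


# ------------------------------------------------------------------ mirroring
def mirror_lr(images, mask, scheme: MuscleLabelScheme):
    """Left-right flip of images and mask with paired label exchange.

    Applying it twice is the identity.  Raises if the mask contains a
    non-background label with no contralateral partner in the scheme.
    """
    grids = [np.flip(g, axis=0).copy() for g in _as_grids(images)]
    m = _mask_grid(mask)
    present = set(np.unique(m).tolist()) - {scheme.background_label}
    unknown = present - set(scheme.label_set)
    if unknown:
        raise ValueError(f"unpaired labels in mask: {sorted(unknown)}")
    lut = np.arange(max(scheme.labels) + 1, dtype=m.dtype)
    for label in scheme.labels:
        lut[label] = scheme.mirror_label(label)
    flipped = lut[np.flip(m, axis=0)]
    return grids, _wrap_mask(flipped, mask)


# ------------------------------------------------------------------ elastic
def elastic_deform(images, mask, control_points: int = 3, sigma: float = 10.0,
                   seed: int | np.random.Generator = 0):
    """Coarse-grid elastic deformation.

    A ``control_points``³ grid of random displacement vectors (each
    component N(0, sigma) voxels) is interpolated to voxel resolution with
    a cubic B-spline and applied as a dense warp: linear interpolation for
    intensities, nearest neighbour for the label map.  ``sigma = 0`` is the
    identity.
    """
    if control_points < 1:
        raise ValueError("control_points must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    grids = _as_grids(images)
    m = _mask_grid(mask)
    shape = grids[0].shape
    if m.shape != shape:
        raise ValueError("mask shape differs from image shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coarse = rng.normal(0.0, sigma, size=(3, control_points, control_points, control_points))
    if sigma == 0:
        return [g.copy() for g in grids], _wrap_mask(m.copy(), mask)
    disp = np.empty((3,) + shape)
    for ax in range(3):
        zoom = [s / control_points for s in shape]
        disp[ax] = ndimage.zoom(coarse[ax], zoom, order=3, mode="nearest")
    coords = np.indices(shape, dtype=float) + disp
    out_grids = [
        ndimage.map_coordinates(g, coords, order=1, mode="constant", cval=0.0)
        for g in grids
    ]
    out_mask = ndimage.map_coordinates(m, coords, order=0, mode="constant", cval=0)
    return out_grids, _wrap_mask(out_mask.astype(m.dtype), mask)


# ------------------------------------------------------------------ affine
def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
    )
    ry = np.array(
        [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
    )
    rz = np.array(
        [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
    )
    return rz @ ry @ rx


def apply_affine(images, mask, scales=(1.0, 1.0, 1.0), angles_deg=(0.0, 0.0, 0.0)):
    """Apply a fixed centre-anchored scale+rotation to images and mask."""
    grids = _as_grids(images)
    m = _mask_grid(mask)
    shape = grids[0].shape
    t = _rotation_matrix(angles_deg) @ np.diag(scales)
    if np.allclose(t, np.eye(3)):
        return [g.copy() for g in grids], _wrap_mask(m.copy(), mask)
    inv = np.linalg.inv(t)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = center - inv @ center
    out_grids = [
        ndimage.affine_transform(g, inv, offset=offset, order=1, mode="constant", cval=0.0)
        for g in grids
    ]
    out_mask = ndimage.affine_transform(
        m, inv, offset=offset, order=0, mode="constant", cval=0
    )
    return out_grids, _wrap_mask(out_mask.astype(m.dtype), mask)


def random_affine(images, mask, scale_percent: float = 2.5,
                  rot_ranges_deg: tuple[float, float, float] = (2.5, 2.5, 5.0),
                  seed: int | np.random.Generator = 0):
    """Random anisotropic scaling and three-axis rotation.

    Per-axis scale factors are uniform in ``1 ± scale_percent/100``;
    rotation angles uniform in ``±rot_ranges_deg`` about the left-right,
    anterior-posterior and superior-inferior axes.  Returns
    ``(images, mask, params)`` with the drawn parameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = scale_percent / 100.0
    scales = tuple(float(v) for v in rng.uniform(1.0 - s, 1.0 + s, size=3))
    angles = tuple(
        float(rng.uniform(-r, r)) if r > 0 else 0.0 for r in rot_ranges_deg
    )
    out_grids, out_mask = apply_affine(images, mask, scales=scales, angles_deg=angles)
    return out_grids, out_mask, {"scales": scales, "angles_deg": angles}


# ------------------------------------------------------------------ dataset
def augment_dataset(dataset, config: AugmentationConfig, scheme: MuscleLabelScheme):
    """Draw ``config.n_augmented`` augmented samples from a training pool.

    ``dataset`` is a sequence of ``(images, mask)`` pairs, each ``images`` a
    list of co-registered intensity grids.  Every output sample applies the
    chain mirror → elastic → scale+rotate with independent draws and records
    its provenance (source index and transform parameters).

    Returns ``(samples, provenance)`` where ``samples`` is a list of
    ``(images, mask)`` and ``provenance`` a list of dicts.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    samples, provenance = [], []
    for i in range(config.n_augmented):
        src = int(rng.integers(len(dataset)))
        images, mask = dataset[src]
        images = [np.asarray(g, dtype=float) for g in images]
        mirrored = bool(rng.random() < config.mirror_prob)
        if mirrored:
            images, mask = mirror_lr(images, mask, scheme)
        elastic_seed = int(rng.integers(2**31))
        images, mask = elastic_deform(
            images,
            mask,
            control_points=config.elastic_control_points,
            sigma=config.elastic_sigma,
            seed=elastic_seed,
        )
        images, mask, affine_params = random_affine(
            images,
            mask,
            scale_percent=config.scale_percent,
            rot_ranges_deg=(config.rot_lr_deg, config.rot_ap_deg, config.rot_si_deg),
            seed=rng,
        )
        samples.append((images, mask))
        provenance.append(
            {
                "index": i,
                "source": src,
                "mirrored": mirrored,
                "elastic": {
                    "control_points": config.elastic_control_points,
                    "sigma": config.elastic_sigma,
                    "seed": elastic_seed,
                },
                **affine_params,
            }
        )
    return samples, provenance


# -------------------------------------------------- intensity standardisation
def fit_landmarks(images, percentiles=LANDMARK_PERCENTILES) -> np.ndarray:
    """Standard-scale intensity landmarks: mean of per-image percentiles."""
    grids = [np.asarray(im, dtype=float) for im in images]
    if not grids:
        raise ValueError("need at least one image to fit landmarks")
    per_image = np.stack([np.percentile(g, percentiles) for g in grids])
    return per_image.mean(axis=0)


def histogram_standardize(image, landmarks, percentiles=LANDMARK_PERCENTILES):
    """Piecewise-linear intensity mapping onto standard landmarks.

    The image's own percentiles are mapped to the standard landmarks and
    intermediate intensities interpolated linearly; the mapping is monotone
    non-decreasing, so intensity ordering is preserved.  A constant image
    is returned unchanged with a warning.
    """
    img = np.asarray(image, dtype=float)
    src = np.percentile(img, percentiles)
    if src[-1] - src[0] <= 0:
        warnings.warn(
            "constant image: histogram standardisation is the identity",
            UserWarning,
            stacklevel=2,
        )
        return img.copy()
    # enforce strictly increasing source nodes for interpolation
    src = np.maximum.accumulate(src)
    eps = 1e-9 * (src[-1] - src[0])
    for i in range(1, len(src)):
        if src[i] <= src[i - 1]:
            src[i] = src[i - 1] + eps
    dst = np.asarray(landmarks, dtype=float)
    out = np.interp(img, src, dst)
    # extend the edge segments linearly so intensity tails are not clamped
    lo = img < src[0]
    hi = img > src[-1]
    if lo.any():
        slope = (dst[1] - dst[0]) / (src[1] - src[0])
        out[lo] = dst[0] + slope * (img[lo] - src[0])
    if hi.any():
        slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        out[hi] = dst[-1] + slope * (img[hi] - src[-1])
    return out


# ------------------------------------------------------------------ labels
def normalize_labels(mask, scheme: MuscleLabelScheme):
    """Map scheme labels onto contiguous training indices 0..K.

    Background maps to 0 and the scheme labels, in ascending order, to
    1..K.  Returns ``(indexed_mask, index_to_label)`` with an invertible
    lookup.  Unknown labels raise.
    """
    m = _mask_grid(mask)
    ordered = sorted(scheme.label_set)
    unknown = set(np.unique(m).tolist()) - set(ordered) - {scheme.background_label}
    if unknown:
        raise ValueError(f"mask contains labels outside the scheme: {sorted(unknown)}")
    lut = np.zeros(max(ordered) + 1, dtype=m.dtype)
    index_to_label = {0: scheme.background_label}
    for idx, label in enumerate(ordered, start=1):
        lut[label] = idx
        index_to_label[idx] = label
    return _wrap_mask(lut[m], mask), index_to_label


def denormalize_labels(indexed_mask, index_to_label: dict):
    """Invert :func:`normalize_labels`."""
    m = _mask_grid(indexed_mask)
    lut = np.zeros(max(index_to_label) + 1, dtype=m.dtype)
    for idx, label in index_to_label.items():
        lut[idx] = label
    return _wrap_mask(lut[m], indexed_mask)
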