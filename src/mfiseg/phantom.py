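"""Synthetic Dixon phantoms, simulated raters, and synthetic cohorts.

Real cervical-spine Dixon scans with expert segmentations are not freely
available, so every downstream module is exercised on simulated data with
known ground truth:

* :func:`generate_phantom` builds a desk-scale 3D grid (default
  64 x 48 x 12 voxels at 0.7 x 0.7 x 3.0 mm) containing bilaterally paired
  elliptic muscle columns for the seven cervical muscle groups, a
  vertebral-body compartment, a subcutaneous fat ring and air background.
  Each muscle has a known true fat fraction (deep muscles higher), and the
  fat/water signals get independent additive zero-mean Gaussian noise.
* :func:`perturb_mask` emulates an imperfect human rater via
  boundary-localised morphological noise (shift, erosion/dilation, boundary
  voxel flips).
* :func:`generate_cohort` draws per-subject muscle-group MFI tables with
  injected sex, age and BMI effects for the characterisation statistics.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .dixon import DixonVolume, SegmentationMask
from .labels import MuscleLabelScheme, default_scheme

__all__ = [
    "MuscleRegion",
    "PhantomSpec",
    "RaterPerturbSpec",
    "CohortSpec",
    "generate_phantom",
    "perturb_mask",
    "generate_cohort",
    "DEEP_GROUPS",
]

#: Muscle groups lying deep against the vertebrae (higher expected MFI).
DEEP_GROUPS = ("MFSS", "LC", "SSCap")

#: Default per-group true fat fractions, deep groups higher.
DEFAULT_FAT_FRACTIONS = {
    "MFSS": 0.17,
    "LC": 0.14,
    "SSCap": 0.15,
    "SPCap": 0.10,
    "LS": 0.07,
    "SCM": 0.09,
    "TR": 0.08,
}

# Axial layout of the seven bilateral groups: (name, |dx| from midline,
# dy from centre (+ = anterior), rx, ry) in voxels of the 64 x 48 default
# plane; scaled with the grid.  Posterior extensors sit at negative dy.
_MUSCLE_LAYOUT = {
    "MFSS": (5.0, -7.0, 2.8, 2.8),
    "LC": (4.0, 7.0, 2.5, 2.5),
    "SSCap": (9.5, -12.5, 2.8, 2.4),
    "SPCap": (16.0, -8.5, 2.8, 2.4),
    "LS": (20.0, -2.5, 2.4, 2.4),
    "SCM": (14.0, 8.0, 2.8, 2.4),
    "TR": (16.0, -15.0, 2.4, 2.0),
}


@dataclass(frozen=True)
class MuscleRegion:
    """One elliptic muscle column: label, centre/radii in voxels, z range."""

    label: int
    name: str
    side: str
    cx: float
    cy: float
    rx: float
    ry: float
    z0: int
    z1: int  # inclusive
    fat_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"{self.name}/{self.side}: fat fraction outside [0,1]")
        if self.rx <= 0 or self.ry <= 0:
            raise ValueError(f"{self.name}/{self.side}: radii must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, composition and noise of one synthetic Dixon scan."""

    grid_shape: tuple[int, int, int] = (64, 48, 12)
    spacing: tuple[float, float, float] = (0.7, 0.7, 3.0)
    muscles: tuple[MuscleRegion, ...] = ()
    tissue_signal: float = 100.0
    soft_tissue_fraction: float = 0.25
    subcutaneous_fraction: float = 0.90
    bone_fraction: float = 0.40
    bone_signal: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def cervical(
        cls,
        grid_shape: tuple[int, int, int] = (64, 48, 12),
        spacing: tuple[float, float, float] = (0.7, 0.7, 3.0),
        fat_fractions: dict[str, float] | None = None,
        noise_sd: float = 0.0,
        seed: int = 0,
        fraction_jitter_sd: float = 0.0,
        radius_jitter_frac: float = 0.0,
        scheme: MuscleLabelScheme | None = None,
    ) -> "PhantomSpec":
        """Default bilateral seven-group layout with optional per-phantom jitter.

        ``fraction_jitter_sd`` (percent-fraction units, e.g. 0.03) and
        ``radius_jitter_frac`` perturb the per-group truth so a cohort of
        phantoms has between-scan variance, as real subjects do.  The jitter
        is drawn from ``seed`` and applied identically to both sides,
        preserving left-right mirror symmetry.
        """
        nx, ny, nz = grid_shape
        if scheme is None:
            scheme = default_scheme(nz)
        fracs = dict(DEFAULT_FAT_FRACTIONS)
        if fat_fractions:
            fracs.update(fat_fractions)
        rng = np.random.default_rng(seed)
        sx, sy = nx / 64.0, ny / 48.0
        cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0
        muscles = []
        for group in scheme:
            dx, dy, rx, ry = _MUSCLE_LAYOUT[group.name]
            frac = fracs[group.name]
            if fraction_jitter_sd > 0:
                frac = float(np.clip(frac + rng.normal(0, fraction_jitter_sd), 0.01, 0.95))
            if radius_jitter_frac > 0:
                # clip keeps jittered neighbours disjoint in the default layout
                scale = float(np.clip(1.0 + rng.normal(0, radius_jitter_frac), 0.85, 1.15))
                rx, ry = rx * scale, ry * scale
            z0 = max(0, group.slice_range[0])
            z1 = min(nz - 1, group.slice_range[1])
            for side, label, sign in (
                ("left", group.left_label, -1.0),
                ("right", group.right_label, +1.0),
            ):
                muscles.append(
                    MuscleRegion(
                        label=label,
                        name=group.name,
                        side=side,
                        cx=cx0 + sign * dx * sx,
                        cy=cy0 + dy * sy,
                        rx=rx * sx,
                        ry=ry * sy,
                        z0=z0,
                        z1=z1,
                        fat_fraction=frac,
                    )
                )
        return cls(
            grid_shape=grid_shape,
            spacing=spacing,
            muscles=tuple(muscles),
            noise_sd=noise_sd,
            seed=seed,
        )

    @classmethod
    def training(
        cls,
        grid_shape: tuple[int, int, int] = (48, 48, 12),
        spacing: tuple[float, float, float] = (0.7, 0.7, 3.0),
        noise_sd: float = 2.0,
        seed: int = 0,
        fraction_jitter_sd: float = 0.02,
        radius_jitter_frac: float = 0.10,
        center_jitter_voxels: float = 1.5,
    ) -> "PhantomSpec":
        """Compact three-structure layout for desk-scale network training.

        Three muscle columns (labels 1-3) with well separated fat fractions
        and deliberately asymmetric positions, so a segmentation model must
        combine intensity and position cues; per-phantom jitter of
        fractions, radii and centres provides anatomical variability.
        """
        nx, ny, nz = grid_shape
        rng = np.random.default_rng(seed)
        cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0
        sx, sy = nx / 48.0, ny / 48.0
        base = [
            # label, name, dx, dy, rx, ry, fat fraction
            (1, "deep", 0.0, -6.0, 5.0, 4.0, 0.45),
            (2, "mid", -9.0, 5.0, 4.5, 4.0, 0.12),
            (3, "sup", 10.0, 6.0, 4.0, 3.5, 0.28),
        ]
        muscles = []
        for label, name, dx, dy, rx, ry, frac in base:
            if fraction_jitter_sd > 0:
                frac = float(np.clip(frac + rng.normal(0, fraction_jitter_sd), 0.02, 0.9))
            scale = float(np.clip(1.0 + rng.normal(0, radius_jitter_frac), 0.6, 1.4))
            jx = float(rng.normal(0, center_jitter_voxels))
            jy = float(rng.normal(0, center_jitter_voxels))
            muscles.append(
                MuscleRegion(
                    label=label,
                    name=name,
                    side="na",
                    cx=cx0 + dx * sx + jx,
                    cy=cy0 + dy * sy + jy,
                    rx=rx * sx * scale,
                    ry=ry * sy * scale,
                    z0=1,
                    z1=nz - 2,
                    fat_fraction=frac,
                )
            )
        return cls(
            grid_shape=grid_shape,
            spacing=spacing,
            muscles=tuple(muscles),
            noise_sd=noise_sd,
            seed=seed,
        )


@dataclass(frozen=True)
class RaterPerturbSpec:
    """Boundary-localised segmentation noise emulating an imperfect rater."""

    boundary_shift_voxels: int = 0
    morph_prob: float = 0.0       # probability of one erosion/dilation pass
    morph_mode: str = "both"      # "both", "dilate" or "erode"
    flip_rate: float = 0.0        # boundary voxel flip rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_shift_voxels < 0:
            raise ValueError("boundary_shift_voxels must be >= 0")
        for r in (self.morph_prob, self.flip_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.morph_mode not in ("both", "dilate", "erode"):
            raise ValueError("morph_mode must be 'both', 'dilate' or 'erode'")


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for per-subject muscle-group MFI tables.

    MFI(subject, group) = baseline(group) + sex_effect * I(female)
    + age_slope(group) * (age - age_mean) + bmi_slope * (bmi - bmi_mean)
    + subject random effect + residual, truncated to [0, 100].
    """

    n_subjects: int = 84
    female_prop: float = 61.0 / 84.0
    age_mean: float = 34.2
    age_sd: float = 10.7
    age_range: tuple[float, float] = (18.0, 65.0)
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    bmi_range: tuple[float, float] = (16.0, 45.0)
    baselines: dict = field(
        default_factory=lambda: {
            g: 100.0 * f for g, f in DEFAULT_FAT_FRACTIONS.items()
        }
    )
    sex_effect: float = 1.8
    age_slope_deep: float = 0.10
    age_slope_superficial: float = 0.02
    bmi_slope: float = 0.03
    subject_sd: float = 1.5
    residual_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for sd in (self.age_sd, self.bmi_sd, self.subject_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    def age_slope(self, group: str) -> float:
        return self.age_slope_deep if group in DEEP_GROUPS else self.age_slope_superficial


# --------------------------------------------------------------- generators
def _paint_ellipse(canvas: np.ndarray, region: MuscleRegion, value: int) -> None:
    nx, ny, nz = canvas.shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    inside = ((x - region.cx) / region.rx) ** 2 + ((y - region.cy) / region.ry) ** 2 <= 1.0
    zsel = slice(region.z0, region.z1 + 1)
    prior = canvas[:, :, zsel][inside]
    if np.any(prior != 0):
        raise ValueError(
            f"muscle geometry overlap: region {region.name}/{region.side} "
            f"(label {value}) intersects an existing region"
        )
    block = canvas[:, :, zsel]
    block[inside] = value
    canvas[:, :, zsel] = block


def generate_phantom(spec: PhantomSpec):
    """Build one synthetic Dixon scan with ground truth.

    Returns ``(dixon, mask, truth)`` where ``truth`` is a DataFrame with one
    row per muscle label: name, side, true fat fraction, voxel count and
    volume in ml — exact for the noiseless construction.

    Voxelwise fat = fraction * S and water = (1 - fraction) * S for the
    compartment signal S, with independent additive N(0, noise_sd) noise on
    the fat and water grids.  Overlapping muscle geometries are rejected.
    """
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for region in spec.muscles:
        _paint_ellipse(labels, region, region.label)

    # compartments: air outside the body ellipse, subcutaneous fat ring,
    # soft tissue fill, vertebral body at centre
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx_out, ry_out = 0.45 * nx, 0.44 * ny
    rx_in, ry_in = 0.41 * nx, 0.39 * ny
    r_out = ((x - cx0) / rx_out) ** 2 + ((y - cy0) / ry_out) ** 2
    r_in = ((x - cx0) / rx_in) ** 2 + ((y - cy0) / ry_in) ** 2
    body = np.broadcast_to(r_out <= 1.0, spec.grid_shape)
    subq = np.broadcast_to((r_out <= 1.0) & (r_in > 1.0), spec.grid_shape)
    bone_r = ((x - cx0) / (0.05 * nx)) ** 2 + ((y - cy0) / (0.07 * ny)) ** 2
    bone = np.broadcast_to(bone_r <= 1.0, spec.grid_shape)

    frac = np.zeros(spec.grid_shape, dtype=float)
    signal = np.zeros(spec.grid_shape, dtype=float)
    frac[body] = spec.soft_tissue_fraction
    signal[body] = spec.tissue_signal
    frac[subq] = spec.subcutaneous_fraction
    frac[bone & (labels == 0)] = spec.bone_fraction
    signal[bone & (labels == 0)] = spec.bone_signal
    for region in spec.muscles:
        sel = labels == region.label
        frac[sel] = region.fat_fraction
        signal[sel] = spec.tissue_signal

    fat = frac * signal
    water = (1.0 - frac) * signal
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fat = fat + rng.normal(0.0, spec.noise_sd, size=fat.shape)
        water = water + rng.normal(0.0, spec.noise_sd, size=water.shape)

    dixon = DixonVolume(fat=fat, water=water, spacing=spec.spacing)
    mask = SegmentationMask(labels=labels, spacing=spec.spacing)
    vox_ml = dixon.voxel_volume_mm3 / 1000.0
    truth = pd.DataFrame(
        [
            {
                "label": m.label,
                "group": m.name,
                "side": m.side,
                "fat_fraction": m.fat_fraction,
                "voxel_count": int((labels == m.label).sum()),
                "volume_ml": float((labels == m.label).sum()) * vox_ml,
            }
            for m in spec.muscles
        ]
    )
    return dixon, mask, truth


def perturb_mask(mask: SegmentationMask, spec: RaterPerturbSpec) -> SegmentationMask:
    """Simulate an imperfect rater's version of a label map.

    Per label, in order: integer in-plane shift (uniform in
    ``[-b, b]`` per axis), optional single erosion/dilation pass, then
    random flips of boundary voxels (region boundary voxels dropped to
    background, adjacent background voxels claimed) at ``flip_rate``.
    Labels are processed in ascending order onto a fresh canvas; a voxel
    already claimed stays with the earlier label, so the label set can only
    shrink, never grow.
    """
    rng = np.random.default_rng(spec.seed)
    src = mask.labels
    out = np.zeros_like(src)
    struct = ndimage.generate_binary_structure(3, 1)
    for label in sorted(np.unique(src)):
        if label == 0:
            continue
        region = src == label
        b = spec.boundary_shift_voxels
        if b > 0:
            shift = (int(rng.integers(-b, b + 1)), int(rng.integers(-b, b + 1)), 0)
            region = ndimage.shift(
                region.astype(np.uint8), shift, order=0, mode="constant", cval=0
            ).astype(bool)
        if spec.morph_prob > 0 and rng.random() < spec.morph_prob:
            if spec.morph_mode == "dilate":
                dilate = True
            elif spec.morph_mode == "erode":
                dilate = False
            else:
                dilate = bool(rng.random() < 0.5)
            if dilate:
                region = ndimage.binary_dilation(region, structure=struct)
            else:
                eroded = ndimage.binary_erosion(region, structure=struct)
                if eroded.any():  # never annihilate a region by erosion
                    region = eroded
        if spec.flip_rate > 0:
            inner = region & ~ndimage.binary_erosion(region, structure=struct)
            outer = ndimage.binary_dilation(region, structure=struct) & ~region
            drop = inner & (rng.random(region.shape) < spec.flip_rate)
            grow = outer & (rng.random(region.shape) < spec.flip_rate)
            region = (region & ~drop) | grow
        out[region & (out == 0)] = label
    return SegmentationMask(labels=out, spacing=mask.spacing, affine=mask.affine)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic subject table with per-group (bilaterally averaged) MFI.

    Columns: ``subject_id, sex ('F'/'M'), age, bmi`` plus one MFI column per
    muscle group.  Age and BMI come from truncated normals; sex is assigned
    by rounding ``n * female_prop`` so the sex split is exact for the
    requested proportion.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_f = int(round(n * spec.female_prop))
    female = np.zeros(n, dtype=bool)
    female[rng.permutation(n)[:n_f]] = True

    def trunc_normal(mean, sd, lo, hi, size):
        if sd == 0:
            return np.full(size, float(mean))
        out = rng.normal(mean, sd, size)
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out

    age = trunc_normal(spec.age_mean, spec.age_sd, *spec.age_range, n)
    bmi = trunc_normal(spec.bmi_mean, spec.bmi_sd, *spec.bmi_range, n)
    subject_effect = rng.normal(0.0, spec.subject_sd, n)

    data = {
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "sex": np.where(female, "F", "M"),
        "age": age,
        "bmi": bmi,
    }
    for group, baseline in spec.baselines.items():
        mfi = (
            baseline
            + spec.sex_effect * female
            + spec.age_slope(group) * (age - spec.age_mean)
            + spec.bmi_slope * (bmi - spec.bmi_mean)
            + subject_effect
            + rng.normal(0.0, spec.residual_sd, n)
        )
        data[group] = np.clip(mfi, 0.0, 100.0)
    return pd.DataFrame(data)
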