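"""Dixon fat-water signal algebra and per-muscle quantification.

Two-point Dixon MRI acquires echoes with the fat and water magnetisation
in-phase (IP = W + F) and out-of-phase (OOP = W - F).  Fat-only and
water-only images follow algebraically: F = (IP - OOP) / 2 and
W = (IP + OOP) / 2.  Muscle fat infiltration (MFI) for a labelled region is
the ratio of the mean fat-only signal to the sum of mean fat-only and mean
water-only signal, expressed in percent:

    MFI = 100 * mean(F) / (mean(F) + mean(W))

computed over the voxels carrying the muscle's label.  Muscle volume is the
labelled voxel count times the voxel volume, in millilitres.

Negative fat or water values can arise when noisy IP/OOP images are
decomposed; they are kept by default (zero-mean noise then cancels in the
means) but counted, and clipping is available as an explicit option.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import MuscleLabelScheme

__all__ = [
    "DixonVolume",
    "SegmentationMask",
    "compose_dixon",
    "decompose_dixon",
    "muscle_mfi",
    "muscle_volume",
    "measure_all",
    "average_bilateral",
]

log = logging.getLogger(__name__)

#: Columns of a per-muscle measures table.
MEASURE_COLUMNS = [
    "label",
    "group",
    "side",
    "mfi_percent",
    "volume_ml",
    "voxel_count",
    "flags",
]


def _check_3d(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"{name} must be a 3D grid, got shape {a.shape}")
    return a


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing}")
    return spacing


@dataclass
class DixonVolume:
    """Co-registered fat-only and water-only 3D grids with voxel spacing in mm."""

    fat: np.ndarray
    water: np.ndarray
    spacing: tuple[float, float, float] = (0.7, 0.7, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fat = _check_3d("fat", self.fat)
        self.water = _check_3d("water", self.water)
        if self.fat.shape != self.water.shape:
            raise ValueError(
                f"fat {self.fat.shape} and water {self.water.shape} shapes differ"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fat.shape

    @property
    def in_phase(self) -> np.ndarray:
        return self.water + self.fat

    @property
    def out_of_phase(self) -> np.ndarray:
        return self.water - self.fat

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @classmethod
    def from_ip_oop(
        cls,
        ip: np.ndarray,
        oop: np.ndarray,
        spacing=(0.7, 0.7, 3.0),
        affine: np.ndarray | None = None,
        clip_negative: bool = False,
    ) -> "DixonVolume":
        fat, water = decompose_dixon(ip, oop, clip_negative=clip_negative)
        return cls(fat=fat, water=water, spacing=spacing, affine=affine)


@dataclass
class SegmentationMask:
    """Integer 3D label grid on the same lattice as a :class:`DixonVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (0.7, 0.7, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label grid must be integer-valued")
            labels = np.round(labels).astype(np.int32)
        self.labels = labels
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def validate_against(self, scheme: MuscleLabelScheme) -> None:
        extra = set(self.present_labels().tolist()) - set(scheme.label_set) - {
            scheme.background_label
        }
        if extra:
            raise ValueError(f"mask contains labels outside the scheme: {sorted(extra)}")


# ------------------------------------------------------------------ algebra
def compose_dixon(water: np.ndarray, fat: np.ndarray):
    """In-phase and out-of-phase images from water-only and fat-only signal.

    Returns ``(ip, oop)`` with ``ip = water + fat`` and ``oop = water - fat``.
    """
    water = _check_3d("water", water)
    fat = _check_3d("fat", fat)
    if water.shape != fat.shape:
        raise ValueError(f"shape mismatch: water {water.shape} vs fat {fat.shape}")
    return water + fat, water - fat


def decompose_dixon(ip: np.ndarray, oop: np.ndarray, clip_negative: bool = False):
    """Fat-only and water-only signal from in-phase and out-of-phase images.

    Returns ``(fat, water)`` with ``fat = (ip - oop) / 2`` and
    ``water = (ip + oop) / 2``.  Negative outputs (possible under noise) are
    kept by default; the number of negative voxels is logged.  With
    ``clip_negative=True`` they are clamped at zero instead.
    """
    ip = _check_3d("ip", ip)
    oop = _check_3d("oop", oop)
    if ip.shape != oop.shape:
        raise ValueError(f"shape mismatch: ip {ip.shape} vs oop {oop.shape}")
    fat = (ip - oop) / 2.0
    water = (ip + oop) / 2.0
    n_neg = int((fat < 0).sum() + (water < 0).sum())
    if n_neg:
        log.warning("decompose_dixon: %d negative fat/water voxels", n_neg)
        if clip_negative:
            fat = np.clip(fat, 0.0, None)
            water = np.clip(water, 0.0, None)
    return fat, water


# ------------------------------------------------------------- quantification
def muscle_mfi(dixon: DixonVolume, mask: SegmentationMask, label: int) -> float:
    """Percent muscle fat infiltration of one labelled region.

    Ratio of means: ``100 * mean(fat) / (mean(fat) + mean(water))`` over the
    voxels with ``label``.  Returns ``nan`` (with a warning for a
    non-positive denominator) when undefined: empty region or
    ``mean(fat) + mean(water) <= 0``.
    """
    if dixon.shape != mask.shape:
        raise ValueError(f"shape mismatch: dixon {dixon.shape} vs mask {mask.shape}")
    sel = mask.labels == label
    n = int(sel.sum())
    if n == 0:
        return math.nan
    mean_fat = float(dixon.fat[sel].mean())
    mean_water = float(dixon.water[sel].mean())
    denom = mean_fat + mean_water
    if denom <= 0:
        warnings.warn(
            f"label {label}: non-positive mean signal (fat+water={denom:.3g}); "
            "MFI undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return 100.0 * mean_fat / denom


def muscle_volume(mask: SegmentationMask, label: int) -> float:
    """Volume of one labelled region in millilitres (voxel count x voxel volume)."""
    n = int((mask.labels == label).sum())
    return n * mask.voxel_volume_mm3 / 1000.0


def measure_all(
    dixon: DixonVolume,
    mask: SegmentationMask,
    scheme: MuscleLabelScheme,
    scan_id: str | None = None,
) -> pd.DataFrame:
    """Per-muscle MFI and volume table: one row per scheme label.

    Labels present in the mask but absent from the scheme are excluded with
    a warning.  Empty or degenerate regions get ``mfi_percent = nan`` and a
    flag.  Columns: label, group, side, mfi_percent, volume_ml, voxel_count,
    flags (and scan_id when given).
    """
    if dixon.shape != mask.shape:
        raise ValueError(f"shape mismatch: dixon {dixon.shape} vs mask {mask.shape}")
    extra = (
        set(mask.present_labels().tolist())
        - set(scheme.label_set)
        - {scheme.background_label}
    )
    if extra:
        warnings.warn(
            f"mask labels not in scheme, excluded: {sorted(extra)}",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for group in scheme:
            for side, label in (("left", group.left_label), ("right", group.right_label)):
                n = int((mask.labels == label).sum())
                mfi = muscle_mfi(dixon, mask, label)
                flags = ""
                if n == 0:
                    flags = "empty"
                elif math.isnan(mfi):
                    flags = "undefined_mfi"
                rows.append(
                    {
                        "label": label,
                        "group": group.name,
                        "side": side,
                        "mfi_percent": mfi,
                        "volume_ml": muscle_volume(mask, label),
                        "voxel_count": n,
                        "flags": flags,
                    }
                )
    df = pd.DataFrame(rows, columns=MEASURE_COLUMNS)
    if scan_id is not None:
        df.insert(0, "scan_id", scan_id)
    return df


def average_bilateral(
    measures: pd.DataFrame, scheme: MuscleLabelScheme
) -> pd.DataFrame:
    """Average the left and right MFI (and sum volumes) per muscle group.

    Left-right MFI averaging limits the number of downstream comparisons.
    If one side's MFI is undefined the defined side is used and the row is
    flagged ``one_sided``; if both are undefined the group's MFI is ``nan``
    with flag ``undefined``.
    """
    rows = []
    for group in scheme:
        sub = measures[measures["group"] == group.name]
        left = sub[sub["side"] == "left"]
        right = sub[sub["side"] == "right"]
        lv = float(left["mfi_percent"].iloc[0]) if len(left) else math.nan
        rv = float(right["mfi_percent"].iloc[0]) if len(right) else math.nan
        vol = float(sub["volume_ml"].sum())
        if math.isnan(lv) and math.isnan(rv):
            mfi, flags = math.nan, "undefined"
        elif math.isnan(lv) or math.isnan(rv):
            mfi, flags = (rv if math.isnan(lv) else lv), "one_sided"
        else:
            mfi, flags = (lv + rv) / 2.0, ""
        rows.append(
            {
                "group": group.name,
                "mfi_percent": mfi,
                "volume_ml": vol,
                "flags": flags,
            }
        )
    return pd.DataFrame(rows, columns=["group", "mfi_percent", "volume_ml", "flags"])
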