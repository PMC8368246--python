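"""NIfTI and tabular I/O.

All volumetric data moves through NIfTI-1 (``.nii`` / ``.nii.gz``) via
nibabel; voxel spacing is carried in the affine (RAS-oriented diagonal
affine when writing synthetic data).  Tables are CSV with explicit
headers; nested reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dixon import DixonVolume, SegmentationMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_dixon",
    "write_dixon",
    "read_mask",
    "write_mask",
    "write_json",
]


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path):
    """Read a 3D NIfTI volume.

    Returns ``(grid, spacing, affine)``.  Raises on non-NIfTI or non-3D
    input with a message naming the expectation.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ValueError(f"{path} is not a readable NIfTI-1 file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D data of shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), spacing, np.asarray(img.affine)


def write_volume(grid, path, spacing=(0.7, 0.7, 3.0), affine=None, dtype=None):
    """Write a 3D grid as NIfTI-1; ``.nii.gz`` paths are gzip-compressed."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {grid.shape}")
    if affine is None:
        affine = _default_affine(spacing)
    if dtype is not None:
        grid = grid.astype(dtype)
    img = nib.Nifti1Image(grid, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_dixon(fat_path, water_path) -> DixonVolume:
    fat, spacing, affine = read_volume(fat_path)
    water, spacing_w, _ = read_volume(water_path)
    if fat.shape != water.shape:
        raise ValueError(
            f"fat {fat.shape} and water {water.shape} grids have different shapes"
        )
    if not np.allclose(spacing, spacing_w, atol=1e-4):
        raise ValueError(f"fat spacing {spacing} differs from water spacing {spacing_w}")
    return DixonVolume(fat=fat.astype(float), water=water.astype(float),
                       spacing=spacing, affine=affine)


def write_dixon(dixon: DixonVolume, out_dir, stem: str = "scan", gzip: bool = True):
    """Write the fat/water/IP/OOP quartet; returns the four paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if gzip else ".nii"
    paths = {}
    for name, grid in (
        ("fat", dixon.fat),
        ("water", dixon.water),
        ("ip", dixon.in_phase),
        ("oop", dixon.out_of_phase),
    ):
        p = out_dir / f"{stem}_{name}{ext}"
        write_volume(grid, p, spacing=dixon.spacing, affine=dixon.affine)
        paths[name] = p
    return paths


def read_mask(path) -> SegmentationMask:
    data, spacing, affine = read_volume(path)
    return SegmentationMask(labels=np.round(data).astype(np.int16),
                            spacing=spacing, affine=affine)


def write_mask(mask: SegmentationMask, path):
    write_volume(mask.labels.astype(np.int16), path,
                 spacing=mask.spacing, affine=mask.affine)


def write_json(obj, path) -> None:
    def convert(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=convert))
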