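"""Muscle label schemes.

A segmentation mask assigns every voxel either the background label 0 or a
positive integer identifying one side of one muscle group.  The default
scheme covers the seven bilateral cervical muscle groups commonly assessed
in whiplash and other cervical spine conditions, each restricted to the
axial slices crossing a predetermined vertebral-level range (segmenting a
muscle only where it is consistently present and separable from its
neighbours).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

__all__ = ["MuscleGroup", "MuscleLabelScheme", "default_scheme"]


@dataclass(frozen=True)
class MuscleGroup:
    """One bilateral muscle group.

    Parameters
    ----------
    name : str
        Short group name (e.g. ``"MFSS"``).
    left_label, right_label : int
        Positive integer labels for the left and right muscles.
    slice_range : tuple[int, int]
        Inclusive axial (z) slice interval to which the segmentation of this
        group is restricted, standing in for the vertebral-level restriction.
    vertebral_levels : str
        Human-readable vertebral span (documentation only).
    """

    name: str
    left_label: int
    right_label: int
    slice_range: tuple[int, int] = (0, 10**9)
    vertebral_levels: str = ""

    def __post_init__(self) -> None:
        if self.left_label <= 0 or self.right_label <= 0:
            raise ValueError("labels must be positive integers")
        if self.left_label == self.right_label:
            raise ValueError(
                f"group {self.name!r}: left and right labels must differ"
            )
        if self.slice_range[0] > self.slice_range[1]:
            raise ValueError(f"group {self.name!r}: empty slice range")


@dataclass(frozen=True)
class MuscleLabelScheme:
    """A set of bilateral muscle groups plus the background label (always 0)."""

    groups: tuple[MuscleGroup, ...]
    background_label: int = 0

    def __post_init__(self) -> None:
        labels = [l for g in self.groups for l in (g.left_label, g.right_label)]
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be pairwise distinct across groups")
        if self.background_label in labels:
            raise ValueError("background label collides with a muscle label")

    def __iter__(self) -> Iterator[MuscleGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> tuple[int, ...]:
        """All muscle labels, left then right per group, in group order."""
        return tuple(
            l for g in self.groups for l in (g.left_label, g.right_label)
        )

    @property
    def label_set(self) -> frozenset[int]:
        return frozenset(self.labels)

    def group_of(self, label: int) -> MuscleGroup:
        for g in self.groups:
            if label in (g.left_label, g.right_label):
                return g
        raise KeyError(f"label {label} not in scheme")

    def side_of(self, label: int) -> str:
        g = self.group_of(label)
        return "left" if label == g.left_label else "right"

    def mirror_label(self, label: int) -> int:
        """The label of the contralateral muscle (identity for background)."""
        if label == self.background_label:
            return label
        g = self.group_of(label)
        return g.right_label if label == g.left_label else g.left_label

    # ----------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "background_label": self.background_label,
            "groups": [
                {
                    "name": g.name,
                    "left_label": g.left_label,
                    "right_label": g.right_label,
                    "slice_range": list(g.slice_range),
                    "vertebral_levels": g.vertebral_levels,
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleLabelScheme":
        groups = tuple(
            MuscleGroup(
                name=g["name"],
                left_label=int(g["left_label"]),
                right_label=int(g["right_label"]),
                slice_range=tuple(g.get("slice_range", (0, 10**9))),
                vertebral_levels=g.get("vertebral_levels", ""),
            )
            for g in d["groups"]
        )
        return cls(groups=groups, background_label=int(d.get("background_label", 0)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "MuscleLabelScheme":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


#: Default 14-label cervical scheme: seven bilateral groups, background 0.
#: Slice ranges are placeholders mapped onto the phantom's axial extent by
#: the simulator; vertebral spans are those used for the manual protocol.
_DEFAULT_GROUPS = (
    # name, left, right, vertebral span
    ("MFSS", 2, 1, "C4-C6"),   # multifidus + semispinalis cervicis (deep extensor)
    ("LC", 4, 3, "C3-C6"),     # longus colli + longus capitis (deep flexor)
    ("SSCap", 8, 7, "C3-C5"),  # semispinalis capitis
    ("SPCap", 6, 5, "C3-C5"),  # splenius capitis
    ("LS", 14, 13, "C5-C6"),   # levator scapulae
    ("SCM", 10, 9, "C4-C6"),   # sternocleidomastoid
    ("TR", 12, 11, "C6"),      # trapezius
)


def default_scheme(n_slices: int | None = None) -> MuscleLabelScheme:
    """The default 14-label cervical muscle scheme.

    If ``n_slices`` is given, each group's slice restriction is scaled onto
    ``[0, n_slices)`` (deeper-listed groups get the narrower central bands
    used by the phantom generator); otherwise slice ranges are unbounded.
    """
    groups = []
    for name, left, right, levels in _DEFAULT_GROUPS:
        if n_slices is None:
            rng = (0, 10**9)
        else:
            # central band covering ~2/3 of slices; single-level TR narrower
            lo = n_slices // 6
            hi = n_slices - 1 - n_slices // 6
            if name == "TR":
                mid = n_slices // 2
                lo, hi = max(0, mid - max(1, n_slices // 8)), min(
                    n_slices - 1, mid + max(1, n_slices // 8)
                )
            rng = (lo, hi)
        groups.append(
            MuscleGroup(
                name=name,
                left_label=left,
                right_label=right,
                slice_range=rng,
                vertebral_levels=levels,
            )
        )
    return MuscleLabelScheme(groups=tuple(groups))
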