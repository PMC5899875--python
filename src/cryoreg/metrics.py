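"""Quantitative registration evaluation.

Volume difference, Dice overlap, symmetric mean surface distance, paired
landmark error and ROI statistics over scalar maps.  Standard deviations
are population (divide by N) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import Volume

__all__ = [
    "BinaryMask",
    "LandmarkSet",
    "volume_difference",
    "dice",
    "mean_surface_distance",
    "landmark_error",
    "roi_stats",
]


@dataclass
class BinaryMask:
    """A boolean 3D array with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def foreground_volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3

    @classmethod
    def from_volume(cls, v: Volume, threshold: float = 0.5) -> "BinaryMask":
        return cls(np.asarray(v.data) > threshold, v.spacing, v.origin)


@dataclass
class LandmarkSet:
    """Labelled physical 3D points (mm)."""

    points: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be Nx3")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")

    def __len__(self) -> int:
        return len(self.points)


def _check_nonempty(*masks: BinaryMask) -> None:
    for m in masks:
        if not m.data.any():
            raise ValueError("empty mask")


def volume_difference(a: BinaryMask, b: BinaryMask) -> float:
    """2 |V_a - V_b| / (V_a + V_b); depends only on foreground volumes."""
    _check_nonempty(a, b)
    va, vb = a.foreground_volume_mm3(), b.foreground_volume_mm3()
    return 2.0 * abs(va - vb) / (va + vb)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2 |A ∩ B| / (|A| + |B|) on a common grid."""
    if a.data.shape != b.data.shape:
        raise ValueError("dice requires masks on a common grid")
    sa, sb = int(a.data.sum()), int(b.data.sum())
    if sa + sb == 0:
        raise ValueError("both masks are empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (sa + sb)


def boundary_points(mask: BinaryMask) -> np.ndarray:
    """Physical coordinates (mm) of foreground voxels with a 6-connected background neighbour."""
    fg = mask.data
    filled = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    surf = fg & ~filled
    idx = np.argwhere(surf)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def mean_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric mean of nearest-neighbour boundary distances (mm), both directions averaged."""
    _check_nonempty(a, b)
    pa, pb = boundary_points(a), boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def landmark_error(a: LandmarkSet, b: LandmarkSet):
    """Per-label 3D Euclidean distances; returns (mean mm, population sd mm, distances)."""
    if sorted(a.labels) != sorted(b.labels):
        raise ValueError("landmark sets have mismatched labels")
    order_b = {lab: i for i, lab in enumerate(b.labels)}
    pb = b.points[[order_b[lab] for lab in a.labels]]
    d = np.linalg.norm(a.points - pb, axis=1)
    return float(d.mean()), float(d.std()), d


def roi_stats(map_volume: Volume, roi: BinaryMask):
    """Voxelwise (mean, population sd) of a scalar map over an ROI on the same grid."""
    if tuple(map_volume.shape) != roi.data.shape:
        raise ValueError("ROI and map must share a grid")
    if not roi.data.any():
        raise ValueError("empty ROI")
    vals = np.asarray(map_volume.data, dtype=float)[roi.data]
    return float(vals.mean()), float(vals.std())
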