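"""Post-registration analysis and QC.

Checkerboard renders of co-registered images, thresholded connected-
component tumor labelling with size classification, and linked lookup of
corresponding patches across co-registered channel volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .blockmatch import AffineTransform
from .ffd import FFDTransform
from .histo2d import Image2D
from .volume_io import Volume

__all__ = [
    "TumorRecord",
    "LinkedStudy",
    "checkerboard",
    "label_tumors",
    "classify_by_size",
    "linked_lookup",
    "per_tumor_signal_report",
]

SIZE_THRESHOLDS_MM = (0.5, 2.0)
_PLANES = {"axial": 2, "coronal": 1, "sagittal": 0}


@dataclass
class TumorRecord:
    """A labelled connected component with physical measurements.

    ``equivalent_diameter`` is the diameter of the sphere with the
    component's volume: (6 V / pi)^(1/3).
    """

    label: int
    centroid_mm: tuple[float, float, float]
    volume_mm3: float
    equivalent_diameter_mm: float
    n_voxels: int
    size_class: str | None = None
    channel_means: dict = field(default_factory=dict)


@dataclass
class LinkedStudy:
    """A reference volume plus co-registered channels resolved in its frame.

    ``channels`` maps name -> volume; ``transforms`` maps name ->
    (affine, ffd) pair taking reference physical coordinates into that
    channel's physical frame (either entry may be None).
    """

    reference: Volume
    channels: dict
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.channels:
            self.transforms.setdefault(name, (None, None))

    def map_point(self, name: str, point_mm: np.ndarray) -> np.ndarray:
        affine, ffd = self.transforms[name]
        p = np.atleast_2d(np.asarray(point_mm, dtype=float))
        if ffd is not None:
            p = ffd.map_points(p)
        if affine is not None:
            p = affine.apply(p)
        return p


def _extract_plane(data: np.ndarray, plane: str, index: int) -> np.ndarray:
    axis = _PLANES[plane]
    return np.take(data, index, axis=axis)


def checkerboard(a, b, tile_size_mm: float, plane: str = "axial",
                 index: int | None = None) -> Image2D:
    """Alternate square tiles from two co-registered images.

    For 3D inputs a plane (axial/coronal/sagittal) and slice index select a
    2D section first.  Tile edges are aligned to the image origin.
    """
    if isinstance(a, Volume):
        if a.shape != b.shape:
            raise ValueError("checkerboard requires a common grid")
        axis = _PLANES[plane]
        if index is None:
            index = a.shape[axis] // 2
        da = _extract_plane(np.asarray(a.data), plane, index)
        db = _extract_plane(np.asarray(b.data), plane, index)
        spacings = [s for i, s in enumerate(a.spacing) if i != axis]
        spacing = spacings[0]
    else:
        if a.shape != b.shape:
            raise ValueError("checkerboard requires a common grid")
        da, db = np.asarray(a.data), np.asarray(b.data)
        spacing = a.spacing
        spacings = [a.spacing, a.spacing]
    tiles = [max(int(round(tile_size_mm / s)), 0) for s in spacings]
    if any(t < 1 for t in tiles):
        raise ValueError("tile smaller than one pixel")
    ix = (np.arange(da.shape[0]) // tiles[0]) % 2
    iy = (np.arange(da.shape[1]) // tiles[1]) % 2
    use_b = (ix[:, None] + iy[None, :]) % 2 == 1
    out = da.astype(float).copy()
    out[use_b] = db.astype(float)[use_b]
    return Image2D(out, spacing)


def label_tumors(channel: Volume, threshold: float, min_voxels: int = 1,
                 return_volume: bool = False):
    """26-connected components of ``channel >= threshold`` with physical measurements.

    Components smaller than ``min_voxels`` are discarded; surviving ones are
    renumbered 1..K.  With ``return_volume`` the renumbered label volume is
    returned alongside the records.
    """
    data = np.asarray(channel.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("label_tumors expects a scalar volume")
    fg = data >= threshold
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    voxel_vol = float(np.prod(channel.spacing))
    records = []
    remap = np.zeros(n + 1, dtype=np.int32)
    if n > 0:
        counts = np.bincount(labels.ravel())
        centroids = ndimage.center_of_mass(fg, labels, range(1, n + 1))
        out_label = 0
        for lab in range(1, n + 1):
            nv = int(counts[lab])
            if nv < min_voxels:
                continue
            out_label += 1
            remap[lab] = out_label
            vol = nv * voxel_vol
            centroid = (np.asarray(channel.origin)
                        + np.asarray(centroids[lab - 1]) * np.asarray(channel.spacing))
            records.append(TumorRecord(
                label=out_label,
                centroid_mm=tuple(float(c) for c in centroid),
                volume_mm3=vol,
                equivalent_diameter_mm=float((6.0 * vol / np.pi) ** (1.0 / 3.0)),
                n_voxels=nv,
            ))
    if return_volume:
        return records, remap[labels]
    return records


def classify_by_size(records: list[TumorRecord],
                     thresholds: tuple[float, float] = SIZE_THRESHOLDS_MM):
    """Partition records into small/medium/large by equivalent diameter.

    Boundaries are [0, t0) small, [t0, t1] medium, (t1, inf) large.
    Returns ``(counts, records)`` with the records annotated in place.
    """
    t0, t1 = thresholds
    if not 0 < t0 < t1:
        raise ValueError("thresholds must be increasing and positive")
    counts = {"small": 0, "medium": 0, "large": 0}
    for rec in records:
        d = rec.equivalent_diameter_mm
        if d < t0:
            rec.size_class = "small"
        elif d <= t1:
            rec.size_class = "medium"
        else:
            rec.size_class = "large"
        counts[rec.size_class] += 1
    return counts, records


def linked_lookup(study: LinkedStudy, point_mm, patch_size_mm: float):
    """Extract per-channel interpolated patches centred at a reference-frame point.

    Returns a dict name -> {"patch", "valid", "center_value"}; channels whose
    frame does not contain the mapped point are flagged ``missing``.  Patches
    extending past a channel's domain are filled with NaN where invalid.
    """
    point = np.asarray(point_mm, dtype=float)
    ref = study.reference
    rel = (point - np.asarray(ref.origin)) / np.asarray(ref.spacing)
    if np.any(rel < 0) or np.any(rel > np.asarray(ref.shape) - 1):
        raise ValueError("point outside the reference domain")

    results = {}
    for name, vol in study.channels.items():
        center = study.map_point(name, point)[0]
        spacing = np.asarray(vol.spacing)
        half = patch_size_mm / 2.0
        n_side = np.maximum((np.floor(half / spacing)).astype(int) * 2 + 1, 1)
        offsets = np.stack(np.meshgrid(
            *[(np.arange(n) - n // 2) * s for n, s in zip(n_side, spacing)],
            indexing="ij"), axis=-1)
        pts = center + offsets
        vox = (pts - np.asarray(vol.origin)) / spacing
        lim = np.asarray(vol.shape, dtype=float) - 1
        valid = np.all((vox >= 0) & (vox <= lim), axis=-1)
        cvox = (center - np.asarray(vol.origin)) / spacing
        missing = bool(np.any(cvox < 0) or np.any(cvox > lim))
        patch = np.full(offsets.shape[:-1], np.nan)
        if valid.any():
            patch[valid] = ndimage.map_coordinates(
                np.asarray(vol.data, dtype=float), vox[valid].T, order=1, mode="nearest")
        results[name] = {
            "patch": patch,
            "valid": valid,
            "missing": missing,
            "center_value": (None if missing else float(ndimage.map_coordinates(
                np.asarray(vol.data, dtype=float), cvox[:, None], order=1)[0])),
        }
    return results


def per_tumor_signal_report(study: LinkedStudy, records: list[TumorRecord],
                            label_volume: np.ndarray,
                            detection_thresholds: dict,
                            dilate_voxels: int = 0) -> pd.DataFrame:
    """Mean/max per-channel signal inside each tumor component plus detection flags.

    ``label_volume`` is the integer component map in the reference frame
    (labels matching ``records``).  A channel counts as detected when its
    mean over the (optionally dilated) component exceeds its threshold.
    """
    ref = study.reference
    labels = np.asarray(label_volume)
    if labels.shape != tuple(ref.shape):
        raise ValueError("label volume must live on the reference grid")
    rows = []
    for rec in records:
        comp = labels == rec.label
        if dilate_voxels > 0:
            comp = ndimage.binary_dilation(comp, iterations=dilate_voxels)
        idx = np.argwhere(comp).astype(float)
        pts = np.asarray(ref.origin) + idx * np.asarray(ref.spacing)
        row = {
            "label": rec.label,
            "equivalent_diameter_mm": rec.equivalent_diameter_mm,
            "volume_mm3": rec.volume_mm3,
            "size_class": rec.size_class,
        }
        for name, vol in study.channels.items():
            mapped = study.map_point(name, pts)
            vox = (mapped - np.asarray(vol.origin)) / np.asarray(vol.spacing)
            lim = np.asarray(vol.shape, dtype=float) - 1
            valid = np.all((vox >= 0) & (vox <= lim), axis=-1)
            if valid.any():
                vals = ndimage.map_coordinates(np.asarray(vol.data, dtype=float),
                                               vox[valid].T, order=1, mode="nearest")
                mean_v, max_v = float(vals.mean()), float(vals.max())
            else:
                mean_v, max_v = np.nan, np.nan
            row[f"{name}_mean"] = mean_v
            row[f"{name}_max"] = max_v
            thr = detection_thresholds.get(name)
            row[f"{name}_detected"] = bool(thr is not None and np.isfinite(mean_v)
                                           and mean_v > thr)
            rec.channel_means[name] = mean_v
        rows.append(row)
    return pd.DataFrame(rows)
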