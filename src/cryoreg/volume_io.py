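"""Volume containers, file I/O, and intensity/geometry preprocessing.

Coordinate convention used throughout the package: voxel indices are
0-based and node-centered, so the physical position of voxel ``(i, j, k)``
is ``origin + index * spacing`` (all in millimetres).  Axis order of
``data`` is (x, y, z); colour volumes carry a trailing channel axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Volume",
    "WindowSpec",
    "read_volume",
    "write_volume",
    "rgb_to_gray",
    "window_to_byte",
    "lanczos_resample",
    "crop_to_box",
]

#: ITU-R BT.709 luma coefficients for R, G, B.
BT709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass
class Volume:
    """A 3D scalar or RGB voxel array with physical geometry.

    Parameters
    ----------
    data : ndarray
        Array of shape ``(nx, ny, nz)`` for scalar volumes or
        ``(nx, ny, nz, 3)`` for colour volumes.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"volume data must be 3D scalar or 4D colour, got ndim={self.data.ndim}"
            )
        if self.data.ndim == 4 and self.data.shape[-1] != 3:
            raise ValueError(
                f"colour volumes must have exactly 3 channels, got {self.data.shape[-1]}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def is_color(self) -> bool:
        return self.data.ndim == 4

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    def physical_extent(self) -> tuple[float, float, float]:
        """Physical span from first to last voxel centre per axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class WindowSpec:
    """Linear intensity window: ``lo`` maps to 0 and ``hi`` to 255."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got ({self.lo}, {self.hi})")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tiff", ".tif"):
        if name.lower().endswith(suffix):
            name = name[: -len(suffix)]
            break
    return path.with_name(name + ".spacing.json")


def read_volume(path, spacing_override=None) -> Volume:
    """Read a NIfTI or multipage-TIFF volume.

    TIFF files carry no physical spacing, so they require either
    ``spacing_override`` or a JSON sidecar ``<name>.spacing.json`` with keys
    ``x_mm``, ``y_mm``, ``z_mm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim not in (3, 4):
            raise ValueError(f"expected 3D/4D NIfTI payload, got ndim={data.ndim}")
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)
        else:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume(data, spacing, origin)
    if name.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
        # tifffile returns pages-first (z, y, x[, c]); transpose to (x, y, z)
        if data.ndim == 4:
            data = np.transpose(data, (2, 1, 0, 3))
        elif data.ndim == 3:
            data = np.transpose(data, (2, 1, 0))
        else:
            raise ValueError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
        origin = (0.0, 0.0, 0.0)
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)
        else:
            sidecar = _sidecar_path(path)
            if not sidecar.exists():
                raise ValueError(
                    f"TIFF volume {path} needs spacing via override or sidecar {sidecar.name}"
                )
            meta = json.loads(sidecar.read_text())
            spacing = (float(meta["x_mm"]), float(meta["y_mm"]), float(meta["z_mm"]))
            origin = tuple(
                float(meta.get(k, 0.0)) for k in ("origin_x_mm", "origin_y_mm", "origin_z_mm")
            )
        return Volume(data, spacing, origin)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI (spacing/origin in the affine) or TIFF + sidecar."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
        return
    if name.endswith((".tif", ".tiff")):
        import tifffile

        data = volume.data
        if data.ndim == 4:
            pages = np.transpose(data, (2, 1, 0, 3))
        else:
            pages = np.transpose(data, (2, 1, 0))
        tifffile.imwrite(str(path), pages)
        meta = {
            "x_mm": volume.spacing[0],
            "y_mm": volume.spacing[1],
            "z_mm": volume.spacing[2],
            "origin_x_mm": volume.origin[0],
            "origin_y_mm": volume.origin[1],
            "origin_z_mm": volume.origin[2],
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
        return
    raise ValueError(f"unsupported output format: {path}")


def rgb_to_gray(color: Volume) -> Volume:
    """Convert a 3-channel volume to grayscale with BT.709 luma weights."""
    if not color.is_color:
        raise ValueError("rgb_to_gray requires a 3-channel colour volume")
    w = np.asarray(BT709_WEIGHTS)
    gray = np.tensordot(color.data.astype(float), w, axes=([3], [0]))
    return Volume(gray, color.spacing, color.origin)


def window_to_byte(v: Volume, w: WindowSpec) -> Volume:
    """Map intensities linearly so ``[lo, hi] -> [0, 255]``, clamped, rounded half-up."""
    scaled = (np.asarray(v.data, dtype=float) - w.lo) * (255.0 / (w.hi - w.lo))
    clipped = np.clip(scaled, 0.0, 255.0)
    out = np.floor(clipped + 0.5).astype(np.uint8)
    return Volume(out, v.spacing, v.origin)


def _lanczos_kernel(x: np.ndarray, a: int, stretch: float) -> np.ndarray:
    """Lanczos-windowed sinc with support ``a`` taps, stretched for antialiasing."""
    t = x / stretch
    out = np.sinc(t) * np.sinc(t / a)
    out[np.abs(t) >= a] = 0.0
    return out


def _resample_axis_lanczos(data: np.ndarray, axis: int, n_out: int, ratio: float, a: int = 3):
    """Separable Lanczos resample of one axis onto ``n_out`` samples.

    ``ratio`` is out_spacing / in_spacing; when > 1 (downsampling) the kernel
    is stretched by the ratio, acting as the antialiasing prefilter.
    """
    n_in = data.shape[axis]
    stretch = max(ratio, 1.0)
    # output sample i sits at input coordinate i * ratio
    centers = np.arange(n_out) * ratio
    half = int(math.ceil(a * stretch))
    offsets = np.arange(-half, half + 1)
    # weight matrix (n_out, taps); rows renormalised so constants are exact
    base = np.floor(centers).astype(int)
    taps_idx = base[:, None] + offsets[None, :]
    wts = _lanczos_kernel(taps_idx - centers[:, None], a, stretch)
    row_sums = wts.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    wts = wts / row_sums
    taps_idx = np.clip(taps_idx, 0, n_in - 1)  # edge clamp

    moved = np.moveaxis(data, axis, 0)
    flat = moved.reshape(n_in, -1)
    out = np.einsum("ot,otf->of", wts, flat[taps_idx], optimize=True)
    out = out.reshape((n_out,) + moved.shape[1:])
    return np.moveaxis(out, 0, axis)


def lanczos_resample(v: Volume, target_spacing) -> Volume:
    """Resample onto ``target_spacing`` with a separable antialiasing Lanczos filter.

    The output grid spans the same physical extent as the input (same origin;
    last sample at or before the input's last sample).  Negative-lobe
    overshoot is clamped to the input's value range.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    data = np.asarray(v.data, dtype=float)
    out = data
    for axis in range(3):
        ratio = target_spacing[axis] / v.spacing[axis]
        extent = (v.shape[axis] - 1) * v.spacing[axis]
        n_out = int(math.floor(extent / target_spacing[axis] + 1e-9)) + 1
        if n_out <= 1:
            raise ValueError(f"resample would collapse axis {axis} to {n_out} voxel(s)")
        if abs(ratio - 1.0) < 1e-12:
            continue
        out = _resample_axis_lanczos(out, axis, n_out, ratio)
    lo, hi = float(data.min()), float(data.max())
    out = np.clip(out, lo, hi)
    return Volume(out, target_spacing, v.origin)


def crop_to_box(v: Volume, box) -> Volume:
    """Extract voxel-index bounds ``((x0, x1), (y0, y1), (z0, z1))``, end-exclusive.

    The origin advances by the box offset times spacing, so physical
    coordinates of retained voxels are unchanged.
    """
    box = [(int(lo), int(hi)) for lo, hi in box]
    for axis, (lo, hi) in enumerate(box):
        if lo < 0 or hi > v.shape[axis] or lo >= hi:
            raise ValueError(f"invalid crop bounds {box[axis]} for axis {axis} of size {v.shape[axis]}")
    (x0, x1), (y0, y1), (z0, z1) = box
    data = v.data[x0:x1, y0:y1, z0:z1]
    origin = tuple(o + lo * s for o, (lo, _), s in zip(v.origin, box, v.spacing))
    return Volume(data.copy(), v.spacing, origin)
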