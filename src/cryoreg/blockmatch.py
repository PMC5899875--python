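"""Rigid/affine registration by block matching.

Local displacements are estimated by exhaustive search maximising the
absolute normalized cross-correlation between small blocks; a global rigid
or affine map is then fitted to the surviving displacements with trimmed
least squares.  The multiscale driver alternates fit / transform / re-match
cycles from coarse to fine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = [
    "AffineTransform",
    "BlockMatchConfig",
    "BlockMatchSet",
    "abs_ncc",
    "block_displacement_field",
    "fit_transform_trimmed",
    "register_affine_multiscale",
    "resample_affine",
    "downsample_volume",
]


@dataclass
class AffineTransform:
    """Physical-space affine map ``x -> matrix @ x + translation`` (mm).

    By convention transforms in this package map *reference* physical
    coordinates to *moving* physical coordinates.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``x -> self(other(x))``."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def to_json(self, path=None) -> dict:
        payload = {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "convention": "maps reference physical coordinates (mm) to moving physical coordinates (mm); y = matrix @ x + translation",
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    @classmethod
    def from_json(cls, source) -> "AffineTransform":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text())
        return cls(np.asarray(source["matrix"]), np.asarray(source["translation"]))


@dataclass
class BlockMatchConfig:
    block_size: int = 20
    search_size: int = 30
    block_overlap: int = 3
    n_levels: int = 3
    n_iterations: int = 30
    variance_keep_fraction: float = 0.5
    reject_fraction: float = 0.5
    model: str = "affine"

    def __post_init__(self) -> None:
        if self.search_size < self.block_size:
            raise ValueError("search_size must be >= block_size")
        if not 0 < self.variance_keep_fraction <= 1:
            raise ValueError("variance_keep_fraction must be in (0, 1]")
        if not 0 <= self.reject_fraction < 1:
            raise ValueError("reject_fraction must be in [0, 1)")
        if self.block_overlap >= self.block_size:
            raise ValueError("block_overlap must be smaller than block_size")
        if self.model not in ("rigid", "affine"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class BlockMatchSet:
    """Block centres (mm), their displacements (mm), |NCC| scores and variances."""

    centers: np.ndarray
    displacements: np.ndarray
    scores: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.displacements = np.atleast_2d(np.asarray(self.displacements, dtype=float))
        self.scores = np.atleast_1d(np.asarray(self.scores, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        n = len(self.centers)
        if not (len(self.displacements) == len(self.scores) == len(self.variances) == n):
            raise ValueError("all BlockMatchSet fields must have equal length")
        if n and (self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.centers)


def abs_ncc(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """|Pearson correlation| of the flattened intensities of two equal-shape blocks."""
    a = np.asarray(block_a, dtype=float).ravel()
    b = np.asarray(block_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("blocks must have equal shape")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ZeroDivisionError("zero-variance block is unmatchable")
    return float(min(abs(float((a * b).sum()) / denom), 1.0))


def _match_one_block(block: np.ndarray, region: np.ndarray, zero_offset):
    """Best integer shift of ``block`` within ``region`` by |NCC|.

    ``zero_offset`` is the region-relative position corresponding to zero
    displacement.  Returns (offset relative to region origin, score).  Ties
    are broken by smallest displacement magnitude, then lexicographic offset.
    """
    from skimage.feature import match_template

    ncc = np.abs(match_template(region, block, pad_input=False))
    ncc = np.nan_to_num(ncc, nan=-1.0)
    best = ncc.max()
    if best < 0:
        return None
    cand = np.argwhere(ncc >= best - 1e-12)
    disp = cand - np.asarray(zero_offset)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], (disp**2).sum(axis=1)))
    pick = cand[order[0]]
    return pick, float(ncc[tuple(pick)])


def block_displacement_field(ref: Volume, mov: Volume, cfg: BlockMatchConfig) -> BlockMatchSet:
    """Estimate local displacements of high-variance reference blocks.

    ``ref`` and ``mov`` must live on the same voxel grid (the multiscale
    driver guarantees this by resampling ``mov`` through the current
    transform before each match round).  Displacements are in mm.
    """
    if ref.shape != mov.shape:
        raise ValueError("block matching requires volumes on a common grid")
    bs, ss = cfg.block_size, cfg.search_size
    stride = bs - cfg.block_overlap
    rdata = np.asarray(ref.data, dtype=float)
    mdata = np.asarray(mov.data, dtype=float)
    spacing = np.asarray(ref.spacing)

    starts = [np.arange(0, max(n - bs, 0) + 1, stride) for n in ref.shape]
    blocks = []
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                blk = rdata[sx:sx + bs, sy:sy + bs, sz:sz + bs]
                blocks.append(((sx, sy, sz), blk.var()))
    if not blocks:
        raise ValueError("volume too small for the configured block size")
    variances = np.array([v for _, v in blocks])
    n_keep = max(int(np.ceil(cfg.variance_keep_fraction * len(blocks))), 1)
    keep_idx = np.argsort(-variances, kind="stable")[:n_keep]

    margin = (ss - bs) // 2
    centers, disps, scores, kept_vars = [], [], [], []
    for bi in keep_idx:
        (sx, sy, sz), var = blocks[bi]
        if var <= 0:
            continue
        lo = np.array([sx, sy, sz]) - margin
        hi = lo + ss
        # clamp the search window to the moving volume: near the border the
        # set of candidate shifts shrinks, but the block is never padded
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(mov.shape))
        if ((hi - lo) < bs).any():
            continue
        region = mdata[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        block = rdata[sx:sx + bs, sy:sy + bs, sz:sz + bs]
        hit = _match_one_block(block, region, np.array([sx, sy, sz]) - lo)
        if hit is None:
            continue
        offset, score = hit
        shift_vox = lo + offset - np.array([sx, sy, sz])
        center_vox = np.array([sx, sy, sz]) + (bs - 1) / 2.0
        centers.append(ref.index_to_physical(center_vox))
        disps.append(shift_vox * spacing)
        scores.append(score)
        kept_vars.append(var)
    if not centers:
        raise ValueError("no blocks survived the variance filter / search bounds")
    return BlockMatchSet(np.array(centers), np.array(disps), np.array(scores), np.array(kept_vars))


def _fit_affine_ls(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    n = len(src)
    hom = np.hstack([src, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(hom, dst, rcond=None)
    return AffineTransform(sol[:3].T, sol[3])


def _fit_rigid_ls(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    # Kabsch: rotation + translation, no scaling
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return AffineTransform(rot, mu_d - rot @ mu_s)


def fit_transform_trimmed(matches: BlockMatchSet, model: str = "affine",
                          reject_fraction: float = 0.5,
                          max_refits: int = 50) -> AffineTransform:
    """Robustly fit a global transform to centre -> centre + displacement pairs.

    Iteratively least-squares fits, drops the ``reject_fraction`` of pairs
    with the largest residuals, and refits until the inlier set stabilises.
    """
    if model not in ("rigid", "affine"):
        raise ValueError(f"unknown model {model!r}")
    src = matches.centers
    dst = matches.centers + matches.displacements
    n = len(src)
    min_pts = 3 if model == "rigid" else 4
    n_keep = max(int(np.ceil((1.0 - reject_fraction) * n)), min_pts)
    if n < min_pts:
        raise ValueError(f"{model} fit needs at least {min_pts} matches, got {n}")
    fitter = _fit_rigid_ls if model == "rigid" else _fit_affine_ls

    inliers = np.arange(n)
    for _ in range(max_refits):
        if model == "affine":
            spread = np.linalg.matrix_rank(src[inliers] - src[inliers].mean(axis=0), tol=1e-9)
            if spread < 3 and len(inliers) >= 4:
                raise ValueError("degenerate geometry: block centres are coplanar")
        t = fitter(src[inliers], dst[inliers])
        resid = np.linalg.norm(t.apply(src) - dst, axis=1)
        new_inliers = np.argsort(resid, kind="stable")[:n_keep]
        new_inliers.sort()
        if len(new_inliers) == len(inliers) and np.array_equal(new_inliers, inliers):
            break
        inliers = new_inliers
    return fitter(src[inliers], dst[inliers])


def resample_affine(mov: Volume, transform: AffineTransform, out_like: Volume,
                    order: int = 1, fill: float = 0.0) -> Volume:
    """Pull-back resample ``mov`` through ``transform`` onto ``out_like``'s grid."""
    # voxel_out -> physical_ref -> physical_mov -> voxel_mov
    m = np.diag(1.0 / np.asarray(mov.spacing)) @ transform.matrix @ np.diag(out_like.spacing)
    off = (transform.matrix @ np.asarray(out_like.origin) + transform.translation
           - np.asarray(mov.origin)) / np.asarray(mov.spacing)
    data = ndimage.affine_transform(np.asarray(mov.data, dtype=float), m, offset=off,
                                    output_shape=out_like.shape, order=order,
                                    mode="constant", cval=fill)
    return Volume(data, out_like.spacing, out_like.origin)


def downsample_volume(v: Volume, sigma: float = 1.0) -> Volume:
    """Gaussian-smooth (sigma in voxels) then take every second voxel per axis."""
    sm = ndimage.gaussian_filter(np.asarray(v.data, dtype=float), sigma)
    data = sm[::2, ::2, ::2]
    return Volume(data, tuple(2 * s for s in v.spacing), v.origin)


def _scaled_config(cfg: BlockMatchConfig, factor: int, shape) -> BlockMatchConfig:
    bs = max(cfg.block_size // factor, 4)
    bs = min(bs, max(min(shape) - 2, 4))
    ss = max(cfg.search_size // factor, bs + 2)
    ov = min(cfg.block_overlap, bs - 1)
    return BlockMatchConfig(block_size=bs, search_size=ss, block_overlap=ov,
                            n_levels=1, n_iterations=cfg.n_iterations,
                            variance_keep_fraction=cfg.variance_keep_fraction,
                            reject_fraction=cfg.reject_fraction, model=cfg.model)


def _max_update_displacement(delta: AffineTransform, vol: Volume) -> float:
    corners = np.array([[i * (vol.shape[0] - 1), j * (vol.shape[1] - 1), k * (vol.shape[2] - 1)]
                        for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float)
    pts = vol.index_to_physical(corners)
    return float(np.linalg.norm(delta.apply(pts) - pts, axis=1).max())


def register_affine_multiscale(ref: Volume, mov: Volume, cfg: BlockMatchConfig,
                               init: AffineTransform | None = None) -> AffineTransform:
    """Coarse-to-fine rigid then affine block-matching registration.

    Each level runs up to ``cfg.n_iterations`` fit/transform/re-match cycles,
    short-circuiting when the update moves no corner of the volume by more
    than 0.1 voxel.
    """
    t = AffineTransform.identity() if init is None else init
    pyramid_ref = [ref]
    pyramid_mov = [mov]
    for _ in range(cfg.n_levels - 1):
        pyramid_ref.append(downsample_volume(pyramid_ref[-1]))
        pyramid_mov.append(downsample_volume(pyramid_mov[-1]))
    stages = ["rigid"] if cfg.model == "rigid" else ["rigid", "affine"]

    for stage in stages:
        for level in range(cfg.n_levels - 1, -1, -1):
            r, m = pyramid_ref[level], pyramid_mov[level]
            lcfg = _scaled_config(cfg, 2**level, r.shape)
            thresh = 0.1 * min(r.spacing)
            for _ in range(cfg.n_iterations):
                warped = resample_affine(m, t, r)
                try:
                    matches = block_displacement_field(r, warped, lcfg)
                    delta = fit_transform_trimmed(matches, stage, lcfg.reject_fraction)
                except ValueError:
                    break
                t = t.compose(delta)
                if _max_update_displacement(delta, r) < thresh:
                    break
    return t
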