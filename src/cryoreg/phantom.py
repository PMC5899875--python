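"""Seeded synthetic fixtures with known ground truth.

Generates everything the registration and analysis modules need: paired
multimodal-style 3D volumes under a known affine + smooth B-spline warp,
organ and tumor masks, 2D blockface/histology pairs, and before/after
freezing CT pairs with per-organ density changes.  Every generator is a
pure function of its spec: the same seed gives byte-identical output.

Ground-truth warps map *moving* physical coordinates to *reference*
physical coordinates (the moving image is generated by pulling the
reference through that map), so a recovered reference->moving transform
is evaluated against them without numerical inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _bspline as bsp
from .blockmatch import AffineTransform
from .ffd import FFDTransform, _det3
from .histo2d import FFD2D, Image2D, Similarity2D
from .metrics import BinaryMask, LandmarkSet
from .volume_io import Volume

__all__ = [
    "PhantomSpec",
    "TumorSpec",
    "HistologySpec",
    "CTFreezeSpec",
    "PhantomPair",
    "TumorRecordTruth",
    "make_phantom_pair",
    "make_tumor_field",
    "make_histology_pair",
    "make_ct_freeze_pair",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    seed: int = 0
    shape: tuple[int, int, int] = (96, 64, 64)
    spacing: float = 0.2  # mm, isotropic
    n_organs: int = 4
    rotation_deg: float = 0.0          # truth affine: rotation about z through the centre
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warp_amplitude_vox: float = 0.0    # max smooth-warp displacement, voxels
    warp_scale_vox: float = 16.0       # control-lattice spacing of the truth warp
    intensity_remap: str | None = None  # None | "monotone" | "inverted-per-organ"
    noise_sd: float = 0.0
    n_landmarks: int = 20
    lung_like: bool = False            # add a heavily textured organ with boosted warp

    def __post_init__(self) -> None:
        if self.warp_amplitude_vox >= 0.4 * self.warp_scale_vox and self.warp_amplitude_vox > 0:
            raise ValueError("warp amplitude must stay below 0.4x the warp lattice "
                             "spacing to guarantee invertibility")


@dataclass
class TumorSpec:
    seed: int = 0
    n_tumors: int = 20
    diameter_range_mm: tuple[float, float] = (0.2, 3.0)
    diameters_mm: list[float] | None = None  # explicit diameters override sampling
    organ_weights: list[float] | None = None  # aligned with the organ masks passed in
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.diameter_range_mm[0] <= 0:
            raise ValueError("diameters must be positive")
        if self.diameters_mm is not None:
            if len(self.diameters_mm) != self.n_tumors:
                raise ValueError("diameters_mm must list one diameter per tumor")
            if any(d <= 0 for d in self.diameters_mm):
                raise ValueError("diameters must be positive")


@dataclass
class HistologySpec:
    seed: int = 0
    shape: tuple[int, int] = (192, 160)
    spacing: float = 0.05  # mm per pixel
    tx_px: float = 0.0
    ty_px: float = 0.0
    theta_deg: float = 0.0
    scale: float = 1.0
    warp_amplitude_px: float = 0.0
    warp_scale_px: float = 48.0
    speckle_density: float = 0.02  # fraction of pixels given cellular speckle
    noise_sd: float = 0.0
    n_landmarks: int = 20


@dataclass
class CTFreezeSpec:
    seed: int = 0
    shape: tuple[int, int, int] = (64, 48, 48)
    spacing: float = 0.3
    organ_hu: dict = field(default_factory=lambda: {
        "liver": 60.0, "kidney": 45.0, "brain": 35.0, "muscle": 50.0})
    volume_factors: dict = field(default_factory=dict)  # organ -> V_after/V_before
    noise_sd: float = 15.0

    def __post_init__(self) -> None:
        for organ, f in self.volume_factors.items():
            if f <= 0:
                raise ValueError(f"volume factor for {organ!r} must be positive")


# ---------------------------------------------------------------------------
# reference anatomy
# ---------------------------------------------------------------------------

def _coord_grids(shape):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")


def _ellipsoid(shape, center, radii, grids=None):
    gx, gy, gz = grids if grids is not None else _coord_grids(shape)
    return (((gx - center[0]) / radii[0]) ** 2
            + ((gy - center[1]) / radii[1]) ** 2
            + ((gz - center[2]) / radii[2]) ** 2) <= 1.0


def _vessel_tube(shape, rng, radius_vox=1.5):
    """A smooth random polyline rendered as a bright tube (strong local edges)."""
    nx, ny, nz = shape
    n_pts = 40
    t = np.linspace(0, 1, n_pts)
    ax = 0.5 + 0.3 * np.sin(2 * math.pi * (rng.uniform(0.5, 2.0) * t + rng.uniform()))
    ay = 0.5 + 0.3 * np.sin(2 * math.pi * (rng.uniform(0.5, 2.0) * t + rng.uniform()))
    az = np.linspace(0.2, 0.8, n_pts) + 0.05 * np.sin(2 * math.pi * (2 * t + rng.uniform()))
    path = np.stack([ax * (nx - 1), ay * (ny - 1), az * (nz - 1)], axis=1)
    canvas = np.zeros(shape, dtype=bool)
    # densify the polyline and stamp voxels
    for a, b in zip(path[:-1], path[1:]):
        steps = int(np.ceil(np.linalg.norm(b - a))) + 1
        for s in np.linspace(0, 1, steps):
            p = np.round(a + s * (b - a)).astype(int)
            if np.all(p >= 0) and np.all(p < np.asarray(shape)):
                canvas[tuple(p)] = True
    dist = ndimage.distance_transform_edt(~canvas)
    return dist <= radius_vox


def _reference_anatomy(spec: PhantomSpec, rng: np.random.Generator):
    """Build the reference volume (byte range), body mask and organ masks."""
    shape = spec.shape
    grids = _coord_grids(shape)
    nx, ny, nz = shape
    center = np.array([(n - 1) / 2.0 for n in shape])
    body = _ellipsoid(shape, center, (0.45 * nx, 0.42 * ny, 0.42 * nz), grids)
    data = np.zeros(shape)
    data[body] = 70.0

    organ_masks = []
    n_organs = spec.n_organs + (1 if spec.lung_like else 0)
    base_int = np.linspace(110, 220, max(n_organs, 1))
    for i in range(n_organs):
        oc = center + np.array([
            rng.uniform(-0.22, 0.22) * nx,
            rng.uniform(-0.2, 0.2) * ny,
            rng.uniform(-0.2, 0.2) * nz,
        ])
        radii = (rng.uniform(0.08, 0.16) * nx,
                 rng.uniform(0.1, 0.2) * ny,
                 rng.uniform(0.1, 0.2) * nz)
        mask = _ellipsoid(shape, oc, radii, grids) & body
        organ_masks.append(mask)
        data[mask] = base_int[i]

    # smooth internal texture so block matching has structure everywhere
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    texture *= 25.0 / max(texture.std(), 1e-9)
    data[body] += texture[body]
    if spec.lung_like and organ_masks:
        lung = organ_masks[-1]
        fine = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
        data[lung] += 35.0 * fine[lung] / max(fine.std(), 1e-9)

    for _ in range(3):
        tube = _vessel_tube(shape, rng) & body
        data[tube] = 245.0
    data = np.clip(data, 0.0, 255.0)
    return data, body, organ_masks


# ---------------------------------------------------------------------------
# ground-truth warp (moving -> reference)
# ---------------------------------------------------------------------------

@dataclass
class TruthWarp:
    """Moving->reference map W(y) = affine(y) + u(y); u a B-spline field."""

    affine: AffineTransform                 # moving -> reference
    ffd: FFDTransform | None                # displacement over the moving domain

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = self.affine.apply(pts)
        if self.ffd is not None:
            out = out + self.ffd.displacement_at(pts)
        return out

    def jacobian_det_map(self, domain: Volume | None = None) -> Volume:
        """det of dW/dy at moving voxel centres (volume-change ground truth).

        For a pure-affine truth pass the moving volume as ``domain``.
        """
        if self.ffd is None:
            if domain is None:
                raise ValueError("affine-only truth needs an explicit domain")
            det = float(np.linalg.det(self.affine.matrix))
            return Volume(np.full(domain.shape, det), domain.spacing, domain.origin)
        jac = self.ffd.jacobian_grid()  # I + du/dy
        jac = jac - np.eye(3) + self.affine.matrix  # affine linear part + du/dy
        return Volume(_det3(jac), self.ffd.domain_spacing, self.ffd.domain_origin)

    def min_jacobian_det(self) -> float:
        if self.ffd is None:
            return float(np.linalg.det(self.affine.matrix))
        return float(np.min(self.jacobian_det_map().data))


@dataclass
class PhantomPair:
    ref: Volume
    mov: Volume
    truth: TruthWarp
    truth_affine_ref_to_mov: AffineTransform
    body_mask_ref: BinaryMask
    body_mask_mov: BinaryMask
    organ_masks_ref: list[BinaryMask]
    organ_masks_mov: list[BinaryMask]
    landmarks_ref: LandmarkSet
    landmarks_mov: LandmarkSet


def _truth_affine(spec: PhantomSpec, domain: Volume) -> AffineTransform:
    """Reference->moving affine: rotation about z through the volume centre, then scale + shift."""
    a = math.radians(spec.rotation_deg)
    rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    m = np.diag(spec.scale) @ rot
    c = np.asarray(domain.origin) + (np.asarray(domain.shape) - 1) / 2.0 * np.asarray(domain.spacing)
    t = c - m @ c + np.asarray(spec.translation_mm)
    return AffineTransform(m, t)


def _truth_ffd(spec: PhantomSpec, domain: Volume, rng: np.random.Generator,
               lung_mask: np.ndarray | None) -> FFDTransform | None:
    if spec.warp_amplitude_vox <= 0:
        return None
    t = FFDTransform.identity(domain, spec.warp_scale_vox)
    cp = rng.standard_normal(t.control_points.shape)
    cp = ndimage.gaussian_filter(cp, sigma=(1.0, 1.0, 1.0, 0.0))  # smooth lattice noise
    if lung_mask is not None and spec.lung_like:
        # boost lattice coefficients whose support touches the lung-like organ
        # (before normalisation, so the boosted region carries the peak
        # displacement and the global amplitude bound still holds)
        idx = np.argwhere(lung_mask)
        if len(idx):
            lo = idx.min(axis=0) / np.asarray(t.grid_spacing) - 1
            hi = idx.max(axis=0) / np.asarray(t.grid_spacing) + 3
            sl = tuple(slice(max(int(np.floor(l)), 0), int(np.ceil(h)) + 1)
                       for l, h in zip(lo, hi))
            cp[sl] *= 1.8
    trial = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing, t.domain_origin)
    peak = np.abs(trial.displacement_field()).max()
    amp = spec.warp_amplitude_vox * spec.spacing
    cp = cp * (amp / max(peak, 1e-9))
    return FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing, t.domain_origin)


def _sample_volume(data: np.ndarray, vol: Volume, points_mm: np.ndarray, order=1) -> np.ndarray:
    vox = (points_mm - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    return ndimage.map_coordinates(data, vox.reshape(-1, 3).T, order=order,
                                   mode="constant", cval=0.0).reshape(points_mm.shape[:-1])


def make_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Reference volume plus a moving copy pushed through a known affine + smooth warp."""
    rng = np.random.default_rng(spec.seed)
    sp = (spec.spacing,) * 3
    ref_data, body, organ_masks = _reference_anatomy(spec, rng)
    ref = Volume(ref_data, sp)

    affine_r2m = _truth_affine(spec, ref)
    lung = organ_masks[-1] if spec.lung_like and organ_masks else None
    warp_ffd = _truth_ffd(spec, ref, rng, lung)
    truth = TruthWarp(affine_r2m.inverse(), warp_ffd)
    if truth.min_jacobian_det() <= 0:
        raise ValueError("ground-truth warp is not invertible; lower warp amplitude")

    # moving volume: pull reference through W on the same grid geometry
    idx = np.stack(_coord_grids(spec.shape), axis=-1)
    mov_phys = idx * spec.spacing
    ref_pts = truth.apply(mov_phys.reshape(-1, 3)).reshape(mov_phys.shape)
    mov_data = _sample_volume(ref_data, ref, ref_pts, order=1)
    body_f = _sample_volume(body.astype(float), ref, ref_pts, order=1) > 0.5
    organ_mov = [_sample_volume(m.astype(float), ref, ref_pts, order=1) > 0.5
                 for m in organ_masks]

    if spec.intensity_remap in ("monotone", "inverted-per-organ"):
        mov_data = 255.0 * np.power(np.clip(mov_data, 0, 255) / 255.0, 0.65)
        if spec.intensity_remap == "inverted-per-organ" and organ_mov:
            inv = organ_mov[0]
            mov_data[inv] = 255.0 - mov_data[inv]
    elif spec.intensity_remap is not None:
        raise ValueError(f"unknown intensity remap {spec.intensity_remap!r}")
    if spec.noise_sd > 0:
        mov_data = mov_data + rng.normal(0.0, spec.noise_sd, size=mov_data.shape)
    mov = Volume(np.clip(mov_data, 0.0, 255.0), sp)

    landmarks_mov, landmarks_ref = _pick_landmarks(spec, rng, mov, body_f, truth)
    return PhantomPair(
        ref=ref, mov=mov, truth=truth, truth_affine_ref_to_mov=affine_r2m,
        body_mask_ref=BinaryMask(body, sp), body_mask_mov=BinaryMask(body_f, sp),
        organ_masks_ref=[BinaryMask(m, sp) for m in organ_masks],
        organ_masks_mov=[BinaryMask(m, sp) for m in organ_mov],
        landmarks_ref=landmarks_ref, landmarks_mov=landmarks_mov,
    )


def _pick_landmarks(spec, rng, mov: Volume, body_mov: np.ndarray, truth: TruthWarp):
    """Seeded high-gradient points inside the moving body, mapped to the reference frame."""
    interior = ndimage.binary_erosion(body_mov, iterations=3)
    grad = ndimage.gaussian_gradient_magnitude(np.asarray(mov.data, dtype=float), 1.0)
    cand = np.argwhere(interior)
    if len(cand) < spec.n_landmarks:
        raise ValueError("body too small for requested landmark count")
    pick = rng.choice(len(cand), size=min(len(cand), 30 * spec.n_landmarks), replace=False)
    cand = cand[pick]
    order = np.argsort(-grad[tuple(cand.T)], kind="stable")
    chosen = cand[order[: spec.n_landmarks]]
    q = chosen * spec.spacing
    p = truth.apply(q)
    labels = [f"L{i}" for i in range(len(q))]
    return LandmarkSet(q, labels), LandmarkSet(p, labels)


# ---------------------------------------------------------------------------
# tumors
# ---------------------------------------------------------------------------

@dataclass
class TumorRecordTruth:
    label: int
    center_mm: np.ndarray
    diameter_mm: float
    organ: int  # index into the organ-mask list, -1 for body


def make_tumor_field(body_mask: BinaryMask, spec: TumorSpec,
                     organ_masks: list[BinaryMask] | None = None):
    """Place non-overlapping spheres with known centres and diameters.

    Returns ``(label_volume, records)``; the label volume is int-typed with
    background 0 and one label per tumor.
    """
    if not body_mask.data.any():
        raise ValueError("empty body mask")
    rng = np.random.default_rng(spec.seed)
    shape = body_mask.data.shape
    spacing = np.asarray(body_mask.spacing)
    labels = np.zeros(shape, dtype=np.int32)
    grids = _coord_grids(shape)
    records: list[TumorRecordTruth] = []

    region_masks = [body_mask.data]
    region_ids = [-1]
    weights = [1.0]
    if organ_masks:
        region_masks = [m.data for m in organ_masks]
        region_ids = list(range(len(organ_masks)))
        weights = spec.organ_weights or [1.0] * len(organ_masks)
        weights = list(np.asarray(weights, dtype=float) / np.sum(weights))

    for i in range(spec.n_tumors):
        placed = False
        for _ in range(spec.max_retries):
            region = rng.choice(len(region_masks), p=np.asarray(weights) / np.sum(weights))
            idx = np.argwhere(region_masks[region])
            if not len(idx):
                continue
            center = idx[rng.integers(len(idx))].astype(float)
            diameter = (spec.diameters_mm[i] if spec.diameters_mm is not None
                        else rng.uniform(*spec.diameter_range_mm))
            r_vox = diameter / 2.0 / spacing
            sphere = (((grids[0] - center[0]) / max(r_vox[0], 0.5)) ** 2
                      + ((grids[1] - center[1]) / max(r_vox[1], 0.5)) ** 2
                      + ((grids[2] - center[2]) / max(r_vox[2], 0.5)) ** 2) <= 1.0
            # tumors must lie entirely within the body (no clipped spheres) and
            # keep a one-voxel gap so 26-connected labelling cannot merge them
            if not sphere.any() or (sphere & ~body_mask.data).any():
                continue
            dilated = ndimage.binary_dilation(
                sphere, structure=ndimage.generate_binary_structure(3, 3))
            if (labels[dilated] != 0).any():
                continue
            labels[sphere] = i + 1
            records.append(TumorRecordTruth(i + 1, center * spacing, diameter,
                                            region_ids[region]))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place tumor {i} without overlap "
                               f"after {spec.max_retries} retries")
    return labels, records


# ---------------------------------------------------------------------------
# 2D histology pair
# ---------------------------------------------------------------------------

@dataclass
class HistologyPair:
    blockface: Image2D
    histology: Image2D
    truth_sim: Similarity2D              # reference (blockface) -> moving (histology)
    truth_warp: FFD2D | None             # moving-frame residual displacement (mm)
    landmarks_ref: np.ndarray            # mm, blockface frame
    landmarks_mov: np.ndarray            # mm, histology frame


def _anatomy_2d(spec: HistologySpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.shape
    gx, gy = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    data = np.zeros(shape)
    body = (((gx - cx) / (0.42 * shape[0])) ** 2 + ((gy - cy) / (0.4 * shape[1])) ** 2) <= 1
    data[body] = 90.0
    for i in range(4):
        oc = (cx + rng.uniform(-0.22, 0.22) * shape[0],
              cy + rng.uniform(-0.22, 0.22) * shape[1])
        rad = (rng.uniform(0.06, 0.14) * shape[0], rng.uniform(0.06, 0.14) * shape[1])
        blob = (((gx - oc[0]) / rad[0]) ** 2 + ((gy - oc[1]) / rad[1]) ** 2) <= 1
        data[blob & body] = 130.0 + 30.0 * i
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    data[body] += 20.0 * tex[body] / max(tex.std(), 1e-9)
    return np.clip(data, 0, 255)


def make_histology_pair(spec: HistologySpec) -> HistologyPair:
    """Shared 2D anatomy rendered as a blockface image and a warped, speckled histology image."""
    rng = np.random.default_rng(spec.seed)
    anatomy = _anatomy_2d(spec, rng)
    blockface = Image2D(anatomy.copy(), spec.spacing)

    center = blockface.center_mm()
    truth_sim = Similarity2D(spec.tx_px * spec.spacing, spec.ty_px * spec.spacing,
                             spec.theta_deg, spec.scale, tuple(center))
    sim_inv_m = np.linalg.inv(truth_sim.scale * truth_sim._rot())

    warp = None
    if spec.warp_amplitude_px > 0:
        if spec.warp_amplitude_px >= 0.4 * spec.warp_scale_px:
            raise ValueError("2D warp amplitude too large for invertibility")
        t = FFD2D.identity(blockface, spec.warp_scale_px)
        cp = rng.standard_normal(t.control_points.shape)
        cp = ndimage.gaussian_filter(cp, sigma=(1.0, 1.0, 0.0))  # smooth lattice noise
        # normalise so the max *field* displacement equals the requested amplitude
        probe = np.stack(np.meshgrid(np.arange(spec.shape[0], dtype=float),
                                     np.arange(spec.shape[1], dtype=float),
                                     indexing="ij"), axis=-1).reshape(-1, 2)
        trial = FFD2D(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)
        peak = np.abs(trial.displacement_at(probe * spec.spacing)).max()
        cp *= spec.warp_amplitude_px * spec.spacing / max(peak, 1e-9)
        warp = FFD2D(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)

    # histology(q) = anatomy(W(q)), W(q) = sim^{-1}(q) + v(q)
    idx = np.stack(np.meshgrid(np.arange(spec.shape[0], dtype=float),
                               np.arange(spec.shape[1], dtype=float), indexing="ij"), axis=-1)
    q = idx * spec.spacing
    p = ((q.reshape(-1, 2) - (np.array([truth_sim.tx, truth_sim.ty]) + center))
         @ sim_inv_m.T + center).reshape(q.shape)
    if warp is not None:
        p = p + warp.displacement_at(q.reshape(-1, 2)).reshape(q.shape)
    pix = p / spec.spacing
    histo = ndimage.map_coordinates(anatomy, pix.reshape(-1, 2).T, order=1,
                                    mode="constant", cval=0.0).reshape(spec.shape)

    # stain-like monotone remap + fine cellular speckle without blockface correspondence
    histo = 255.0 * np.power(np.clip(histo, 0, 255) / 255.0, 0.75)
    n_speckle = int(spec.speckle_density * histo.size)
    if n_speckle:
        sx = rng.integers(0, spec.shape[0], n_speckle)
        sy = rng.integers(0, spec.shape[1], n_speckle)
        histo[sx, sy] = np.clip(histo[sx, sy] + rng.uniform(-80, 80, n_speckle), 0, 255)
    if spec.noise_sd > 0:
        histo = histo + rng.normal(0.0, spec.noise_sd, size=histo.shape)
    histology = Image2D(np.clip(histo, 0, 255), spec.spacing)

    # landmarks: moving-frame points q mapped to reference frame through W
    margin = 0.2
    qx = rng.uniform(margin * spec.shape[0], (1 - margin) * spec.shape[0], spec.n_landmarks)
    qy = rng.uniform(margin * spec.shape[1], (1 - margin) * spec.shape[1], spec.n_landmarks)
    q_mm = np.stack([qx, qy], axis=1) * spec.spacing
    p_mm = (q_mm - (np.array([truth_sim.tx, truth_sim.ty]) + center)) @ sim_inv_m.T + center
    if warp is not None:
        p_mm = p_mm + warp.displacement_at(q_mm)
    return HistologyPair(blockface, histology, truth_sim, warp, p_mm, q_mm)


# ---------------------------------------------------------------------------
# CT freeze pair
# ---------------------------------------------------------------------------

def make_ct_freeze_pair(spec: CTFreezeSpec):
    """Before/after-freezing CT volumes with per-organ density (volume) changes.

    A volume factor f = V_after/V_before scales density by 1/f, so
    CT_after = (1000 + CT_before)/f - 1000.  Returns
    ``(before, after, roi_masks, true_percent_changes)``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    sp = (spec.spacing,) * 3
    grids = _coord_grids(shape)
    center = np.array([(n - 1) / 2.0 for n in shape])
    body = _ellipsoid(shape, center, tuple(0.44 * n for n in shape), grids)

    before = np.full(shape, -1000.0)  # air
    before[body] = 20.0  # soft-tissue background
    after_clean = before.copy()
    rois = {}
    truths = {}
    organs = list(spec.organ_hu.items())
    offsets = np.linspace(-0.25, 0.25, max(len(organs), 1))
    for i, ((name, hu), off) in enumerate(zip(organs, offsets)):
        oc = center + np.array([off * shape[0], (i % 2) * 0.1 * shape[1], 0.0])
        radii = tuple(0.12 * n for n in shape)
        mask = _ellipsoid(shape, oc, radii, grids) & body
        before[mask] = hu
        f = spec.volume_factors.get(name, 1.0)
        after_clean[mask] = (1000.0 + hu) / f - 1000.0
        rois[name] = BinaryMask(ndimage.binary_erosion(mask, iterations=1), sp)
        truths[name] = 100.0 * (f - 1.0)
    other = body.copy()
    for roi in rois.values():
        other &= ~roi.data

    noise_b = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else 0.0
    noise_a = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else 0.0
    from .ct_volume import HUVolume

    return (HUVolume(before + noise_b, sp), HUVolume(after_clean + noise_a, sp),
            rois, truths)
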