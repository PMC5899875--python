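"""2D histology-to-blockface registration.

Pipeline: grayscale open/close morphological preconditioning (suppresses
fine cellular texture without blockface correspondence), Sobel edge
magnitude, Nelder-Mead similarity fit maximising edge NCC, then a
multiresolution 2D B-spline FFD refinement of the residual distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from . import _bspline as bsp

__all__ = [
    "Image2D",
    "Similarity2D",
    "FFD2D",
    "FFD2DConfig",
    "gray_open_close",
    "edge_magnitude",
    "register_similarity_2d",
    "register_ffd_2d",
    "apply_transform_2d",
    "edge_overlap_qc",
]


@dataclass
class Image2D:
    """A 2D scalar or 3-channel image with isotropic pixel size (mm)."""

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("image must be 2D scalar or 3-channel")
        if self.data.ndim == 3 and self.data.shape[-1] != 3:
            raise ValueError("colour images must have 3 channels")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def is_color(self) -> bool:
        return self.data.ndim == 3

    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1) / 2.0 * self.spacing


@dataclass
class Similarity2D:
    """Similarity map (mm): x -> scale * R(theta) (x - c) + c + (tx, ty).

    ``c`` is the physical centre of the reference image the transform was
    fitted against (stored as ``center``); theta in degrees.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    scale: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def _rot(self) -> np.ndarray:
        a = math.radians(self.theta)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        return (pts - c) @ (self.scale * self._rot()).T + c + np.array([self.tx, self.ty])

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "Similarity2D":
        return cls(0.0, 0.0, 0.0, 1.0, tuple(center))


@dataclass
class FFD2D:
    """2D cubic B-spline lattice of displacements (mm) over a reference pixel grid."""

    control_points: np.ndarray
    grid_spacing: tuple[float, float]
    domain_shape: tuple[int, int]
    domain_spacing: float

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.grid_spacing = tuple(float(g) for g in np.broadcast_to(self.grid_spacing, (2,)))
        self.domain_shape = tuple(int(n) for n in self.domain_shape)
        self.domain_spacing = float(self.domain_spacing)
        if any(g < 2 for g in self.grid_spacing):
            raise ValueError("grid_spacing must be >= 2 pixels")
        expected = tuple(bsp.n_control_points(n, g)
                         for n, g in zip(self.domain_shape, self.grid_spacing))
        if self.control_points.shape != expected + (2,):
            raise ValueError("lattice does not cover the image domain")

    @classmethod
    def identity(cls, img: Image2D, grid_spacing=16.0) -> "FFD2D":
        gs = tuple(float(g) for g in np.broadcast_to(grid_spacing, (2,)))
        shape = tuple(bsp.n_control_points(n, g) for n, g in zip(img.shape, gs))
        return cls(np.zeros(shape + (2,)), gs, img.shape, img.spacing)

    def displacement_at(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        vox = pts / self.domain_spacing
        return bsp.evaluate_at_points(self.control_points, vox, self.grid_spacing)

    def map_points(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts + self.displacement_at(pts)

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.control_points, axis=-1).max())


@dataclass
class FFD2DConfig:
    w_be: float = 0.05
    grid_spacing: float = 16.0  # pixels
    n_levels: int = 3
    max_iterations: int = 200
    tolerance: float = 1e-4
    fd_step_px: float = 0.25


# ---------------------------------------------------------------------------
# preconditioning
# ---------------------------------------------------------------------------

def gray_open_close(img: Image2D, radius: int = 3, n_iter: int = 2) -> Image2D:
    """Alternating grayscale opening and closing with a disk structuring element."""
    if img.is_color:
        raise ValueError("gray_open_close expects a scalar image")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    from skimage.morphology import closing, disk, opening

    footprint = disk(radius)
    out = np.asarray(img.data, dtype=float)
    for _ in range(int(n_iter)):
        out = opening(out, footprint)
        out = closing(out, footprint)
    return Image2D(out, img.spacing)


def edge_magnitude(img: Image2D) -> Image2D:
    """Sobel gradient magnitude; nonnegative, zero on constant images."""
    if img.is_color:
        raise ValueError("edge_magnitude expects a scalar image")
    from skimage.filters import sobel

    return Image2D(sobel(np.asarray(img.data, dtype=float)), img.spacing)


# ---------------------------------------------------------------------------
# similarity registration
# ---------------------------------------------------------------------------

def _warp_similarity(mov: Image2D, sim: Similarity2D, out_shape, out_spacing,
                     order: int = 1):
    """Pull-back sample of ``mov`` at sim(grid of out geometry); returns (data, valid)."""
    idx = np.stack(np.meshgrid(np.arange(out_shape[0], dtype=float),
                               np.arange(out_shape[1], dtype=float), indexing="ij"), axis=-1)
    phys = idx * out_spacing
    mapped = sim.apply(phys.reshape(-1, 2)).reshape(phys.shape)
    pix = mapped / mov.spacing
    lim = np.asarray(mov.shape, dtype=float) - 1
    valid = np.all((pix >= 0) & (pix <= lim), axis=-1)
    data = ndimage.map_coordinates(np.asarray(mov.data, dtype=float),
                                   pix.reshape(-1, 2).T, order=order,
                                   mode="constant", cval=0.0).reshape(out_shape)
    return data, valid


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum()) / denom


def _downsample_image(img: Image2D) -> Image2D:
    sm = ndimage.gaussian_filter(np.asarray(img.data, dtype=float), 1.0)
    return Image2D(sm[::2, ::2], img.spacing * 2)


def register_similarity_2d(ref_edges: Image2D, mov_edges: Image2D,
                           init: Similarity2D | None = None,
                           n_levels: int = 3) -> Similarity2D:
    """Maximise edge NCC over (tx, ty, theta, scale) with Nelder-Mead, coarse to fine.

    Simplex coordinates are scaled (translations in pixels, angle in degrees,
    scale x100) so default steps are comparable across parameters.
    """
    center = ref_edges.center_mm()
    if init is None:
        init = Similarity2D.identity(center)
    pyr_ref, pyr_mov = [ref_edges], [mov_edges]
    for _ in range(n_levels - 1):
        pyr_ref.append(_downsample_image(pyr_ref[-1]))
        pyr_mov.append(_downsample_image(pyr_mov[-1]))

    params = np.array([init.tx, init.ty, init.theta, init.scale])
    for level in range(n_levels - 1, -1, -1):
        r, m = pyr_ref[level], pyr_mov[level]
        rdata = np.asarray(r.data, dtype=float)
        px = r.spacing

        def objective(x):
            sim = Similarity2D(x[0] * px, x[1] * px, x[2], x[3] / 100.0, tuple(center))
            warped, valid = _warp_similarity(m, sim, r.shape, r.spacing)
            if valid.sum() < 16:
                return 1.0
            return -_ncc(rdata[valid], warped[valid])

        x0 = np.array([params[0] / px, params[1] / px, params[2], params[3] * 100.0])
        starts = [x0]
        if level == n_levels - 1:
            # the NCC landscape can trade rotation against scale into a false
            # basin; multi-start at the coarsest level is cheap insurance
            for dtheta in (-10.0, -5.0, 5.0, 10.0):
                starts.append(x0 + np.array([0.0, 0.0, dtheta, 0.0]))
            for dscale in (-6.0, 6.0):
                starts.append(x0 + np.array([0.0, 0.0, 0.0, dscale]))
        best = None
        for start in starts:
            res = optimize.minimize(objective, start, method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-7,
                                             "maxiter": 800})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun) or best.fun >= 1.0:
            # degenerate simplex / no overlap: retry once from a perturbed start
            best = optimize.minimize(objective, x0 + np.array([1.0, 1.0, 0.5, 0.5]),
                                     method="Nelder-Mead",
                                     options={"xatol": 1e-3, "fatol": 1e-7,
                                              "maxiter": 800})
            if not np.isfinite(best.fun) or best.fun >= 1.0:
                raise RuntimeError("similarity registration failed: no overlapping content")
        x = best.x
        params = np.array([x[0] * px, x[1] * px, x[2], x[3] / 100.0])
    return Similarity2D(params[0], params[1], params[2], params[3], tuple(center))


# ---------------------------------------------------------------------------
# FFD refinement
# ---------------------------------------------------------------------------

class _Ncc2DProblem:
    """Edge-NCC + bending-energy cost for a 2D lattice on one pyramid level."""

    _BE_OPS = [((2, 0), 1.0), ((0, 2), 1.0), ((1, 1), 2.0)]

    def __init__(self, ref: Image2D, mov: Image2D, sim: Similarity2D,
                 grid_spacing, cfg: FFD2DConfig):
        self.ref = np.asarray(ref.data, dtype=float)
        self.mov = np.asarray(mov.data, dtype=float)
        self.mov_spacing = mov.spacing
        self.spacing = ref.spacing
        self.sim = sim
        self.cfg = cfg
        self.shape = ref.shape
        self.n_eval = int(np.prod(self.shape))
        self.gs = tuple(float(g) for g in np.broadcast_to(grid_spacing, (2,)))
        self.mats = {}
        for derivs in [(0, 0)] + [d for d, _ in self._BE_OPS]:
            self.mats[derivs] = [bsp.weight_matrix(n, g, g * ref.spacing, deriv=d)
                                 for n, g, d in zip(self.shape, self.gs, derivs)]
        self.W = self.mats[(0, 0)]
        self.support = []
        for W in self.W:
            nz = [np.nonzero(W[:, m])[0] for m in range(W.shape[1])]
            self.support.append([(int(r[0]), int(r[-1]) + 1) if len(r) else (0, 0)
                                 for r in nz])
        idx = np.stack(np.meshgrid(np.arange(self.shape[0], dtype=float),
                                   np.arange(self.shape[1], dtype=float),
                                   indexing="ij"), axis=-1)
        self.phys = idx * ref.spacing
        self.fd_step = cfg.fd_step_px * ref.spacing
        # NCC pixel set frozen at the similarity alignment (see the 3D
        # problem's note: a moving set is discontinuous, clamped never-overlap
        # pixels fabricate background correlations)
        pix0 = sim.apply(self.phys.reshape(-1, 2)).reshape(self.phys.shape) / mov.spacing
        lim = np.asarray(self.mov.shape, dtype=float) - 1
        self.valid0 = np.all((pix0 >= -0.5) & (pix0 <= lim + 0.5), axis=-1)
        if self.valid0.sum() < 16:
            raise RuntimeError("no overlap under the similarity initialisation")

    def _sample(self, cp):
        # NCC over the full grid with edge-clamped sampling: an overlap-only
        # objective is discontinuous at the valid-set border and lets the
        # optimizer cheat by pushing badly matching pixels out of the overlap.
        disp = bsp.separable_eval(cp, self.W)
        mapped = self.sim.apply((self.phys + disp).reshape(-1, 2)).reshape(self.phys.shape)
        pix = mapped / self.mov_spacing
        # raw coordinates kept for the gradient; mode="nearest" does the clamp
        warped = ndimage.map_coordinates(self.mov, pix.reshape(-1, 2).T, order=1,
                                         mode="nearest").reshape(self.shape)
        return pix, self.valid0, warped

    def cost(self, cp):
        be = 0.0
        for derivs, mult in self._BE_OPS:
            d2 = bsp.separable_eval(cp, self.mats[derivs])
            be += mult * float((d2 * d2).sum())
        pix, valid, warped = self._sample(cp)
        a = self.ref[valid]
        b = warped[valid]
        ncc = _ncc(a, b)
        total = -ncc + self.cfg.w_be * be / self.n_eval
        state = {"pix": pix, "valid": valid, "warped": warped}
        return total, state

    def gradient(self, cp, state):
        valid = state["valid"]
        pix, warped = state["pix"], state["warped"]
        a_full = self.ref
        n = int(valid.sum())
        s_a = float(a_full[valid].sum())
        s_aa = float((a_full[valid] ** 2).sum())
        s_b = float(warped[valid].sum())
        s_bb = float((warped[valid] ** 2).sum())
        s_ab = float((a_full[valid] * warped[valid]).sum())
        var_a = s_aa - s_a**2 / n
        delta = self.fd_step
        rot = self.sim.scale * self.sim._rot()
        dirs = (rot / self.mov_spacing) * delta  # columns: pixel offset per mm of u-axis

        grad_ncc = np.zeros_like(cp)
        ncp = cp.shape[:2]
        wcols = [[W[s0:s1, m] for m, (s0, s1) in enumerate(sup)]
                 for W, sup in zip(self.W, self.support)]
        for mx in range(ncp[0]):
            x0, x1 = self.support[0][mx]
            for my in range(ncp[1]):
                y0, y1 = self.support[1][my]
                box = (slice(x0, x1), slice(y0, y1))
                vbox = valid[box].ravel()
                if not vbox.any():
                    continue
                w2 = (wcols[0][mx][:, None] * wcols[1][my][None, :]).ravel()
                sel = vbox & (w2 > 1e-12)
                if not sel.any():
                    continue
                w_sel = w2[sel]
                coords0 = pix[box].reshape(-1, 2)[sel].T
                a_sel = a_full[box].ravel()[sel]
                b0 = warped[box].ravel()[sel]
                for axis in range(2):
                    dv = dirs[:, axis][:, None] * w_sel[None, :]
                    nccs = []
                    for sgn in (1.0, -1.0):
                        coords = coords0 + sgn * dv
                        b1 = ndimage.map_coordinates(self.mov, coords, order=1,
                                                     mode="nearest")
                        db = b1 - b0
                        sb = s_b + float(db.sum())
                        sbb = s_bb + float((b1**2 - b0**2).sum())
                        sab = s_ab + float((a_sel * db).sum())
                        var_b = sbb - sb**2 / n
                        denom = math.sqrt(max(var_a * var_b, 0.0))
                        nccs.append(0.0 if denom == 0 else (sab - s_a * sb / n) / denom)
                    grad_ncc[mx, my, axis] = (nccs[0] - nccs[1]) / (2 * delta)

        grad = -grad_ncc
        for derivs, mult in self._BE_OPS:
            mats = self.mats[derivs]
            d2 = bsp.separable_eval(cp, mats)
            grad += (self.cfg.w_be / self.n_eval) * 2.0 * mult * bsp.separable_adjoint(d2, mats)
        return grad


def register_ffd_2d(ref_edges: Image2D, mov_edges: Image2D, init: Similarity2D,
                    cfg: FFD2DConfig | None = None) -> FFD2D:
    """Multiresolution B-spline FFD maximising edge NCC after the similarity stage.

    The returned lattice refines ``init``: the moving image is sampled at
    ``init(x + u(x))``.  The accepted-cost trace per level is attached as
    ``cost_trace`` (nonincreasing within each level).
    """
    cfg = cfg or FFD2DConfig()
    pyr_ref, pyr_mov = [ref_edges], [mov_edges]
    for _ in range(cfg.n_levels - 1):
        pyr_ref.append(_downsample_image(pyr_ref[-1]))
        pyr_mov.append(_downsample_image(pyr_mov[-1]))

    cp = None
    traces = []
    for level in range(cfg.n_levels - 1, -1, -1):
        r, m = pyr_ref[level], pyr_mov[level]
        t_level = FFD2D.identity(r, cfg.grid_spacing)
        if cp is None:
            cp = t_level.control_points
        else:
            cp = bsp.subdivide(cp, t_level.control_points.shape[:2])
        prob = _Ncc2DProblem(r, m, init, cfg.grid_spacing, cfg)
        trace = []
        cp = _descend_2d(prob, cp, cfg, trace)
        traces.append(trace)

    result = FFD2D(cp, (cfg.grid_spacing,) * 2, ref_edges.shape, ref_edges.spacing)
    result.cost_trace = traces
    return result


def _descend_2d(prob: _Ncc2DProblem, cp, cfg: FFD2DConfig, trace):
    cost, state = prob.cost(cp)
    if state is None:
        raise RuntimeError("no overlap at FFD initialisation")
    trace.append(cost)
    step = 0.1 * prob.spacing
    alpha = None
    for _ in range(cfg.max_iterations):
        g = prob.gradient(cp, state)
        gmax = float(np.abs(g).max())
        if gmax == 0:
            break
        alpha = (step / gmax) if alpha is None else alpha * 2.0
        accepted = False
        for _h in range(20):
            trial = cp - alpha * g
            c_trial, s_trial = prob.cost(trial)
            if c_trial < cost:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        improvement = cost - c_trial
        cp, cost, state = trial, c_trial, s_trial
        trace.append(cost)
        if improvement < cfg.tolerance:
            break
    return cp


# ---------------------------------------------------------------------------
# application + QC
# ---------------------------------------------------------------------------

def apply_transform_2d(img: Image2D, sim: Similarity2D, ffd: FFD2D | None,
                       out_geometry: Image2D, order: int = 1,
                       fill: float = 0.0) -> Image2D:
    """Warp ``img`` onto ``out_geometry`` through FFD then similarity in one interpolation."""
    shape = out_geometry.shape
    idx = np.stack(np.meshgrid(np.arange(shape[0], dtype=float),
                               np.arange(shape[1], dtype=float), indexing="ij"), axis=-1)
    phys = idx * out_geometry.spacing
    if ffd is not None:
        phys = phys + ffd.displacement_at(phys.reshape(-1, 2)).reshape(phys.shape)
    phys = sim.apply(phys.reshape(-1, 2)).reshape(phys.shape)
    pix = phys / img.spacing
    data = np.asarray(img.data, dtype=float)
    if img.is_color:
        out = np.stack([ndimage.map_coordinates(data[..., c], pix.reshape(-1, 2).T,
                                                order=order, mode="constant", cval=fill
                                                ).reshape(shape) for c in range(3)], axis=-1)
    else:
        out = ndimage.map_coordinates(data, pix.reshape(-1, 2).T, order=order,
                                      mode="constant", cval=fill).reshape(shape)
    return Image2D(out, out_geometry.spacing)


def edge_overlap_qc(ref_edges: Image2D, mov_edges: Image2D,
                    threshold: float = 0.5) -> Image2D:
    """Coincidence rendering: white = edges agree, red = reference only, black elsewhere.

    ``threshold`` is a fraction of each image's maximum edge strength.
    """
    a = np.asarray(ref_edges.data, dtype=float)
    b = np.asarray(mov_edges.data, dtype=float)
    if a.shape != b.shape:
        raise ValueError("edge images must share a grid")
    ea = a > threshold * (a.max() or 1.0)
    eb = b > threshold * (b.max() or 1.0)
    rgb = np.zeros(a.shape + (3,), dtype=np.uint8)
    rgb[ea & eb] = (255, 255, 255)
    rgb[ea & ~eb] = (255, 0, 0)
    rgb[~ea & eb] = (0, 255, 0)
    return Image2D(rgb, ref_edges.spacing)
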