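"""Nonrigid free-form-deformation registration.

The transform is a lattice of control-point displacements interpolated by
uniform cubic B-splines.  The optimizer minimises

    C = -(1 - w1 - w2) * NMI + w1 * BE/N + w2 * JL/N

by gradient descent with backtracking line search, coarse to fine: NMI is
the normalized mutual information of the reference and the warped moving
volume, BE the bending energy (squared second derivatives of the
deformation) and JL the summed |log |det J|| penalty, both averaged over
the N evaluation points (voxel centres) so one weight pair works at every
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _bspline as bsp
from .blockmatch import AffineTransform, downsample_volume
from .volume_io import Volume

__all__ = [
    "FFDTransform",
    "FFDConfig",
    "CostBreakdown",
    "FoldingError",
    "nmi",
    "bending_energy",
    "jacobian_log_penalty",
    "jacobian_det_map",
    "total_cost",
    "optimize_ffd",
    "compose_and_resample",
]

_FOLD_EPS = 1e-6

# second-derivative operator table for the bending energy:
# (axis derivative orders, multiplicity)
_BE_OPS = [
    ((2, 0, 0), 1.0), ((0, 2, 0), 1.0), ((0, 0, 2), 1.0),
    ((1, 1, 0), 2.0), ((1, 0, 1), 2.0), ((0, 1, 1), 2.0),
]


class FoldingError(RuntimeError):
    """Raised when a deformation folds (non-positive / vanishing Jacobian)."""

    def __init__(self, message: str, location=None):
        super().__init__(message)
        self.location = location


@dataclass
class FFDConfig:
    w1: float = 0.045          # bending-energy weight
    w2: float = 0.055          # log-Jacobian weight
    grid_spacing: float = 5.0  # voxels between control points
    n_levels: int = 3
    max_iterations: int = 500
    tolerance: float = 0.001
    n_bins: int = 256
    fd_step_voxels: float = 0.4  # finite-difference step for the NMI gradient

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("regularizer weights must be nonnegative")
        if self.w1 + self.w2 >= 1:
            raise ValueError("w1 + w2 must be < 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.grid_spacing < 2:
            raise ValueError("grid_spacing must be >= 2 voxels")


@dataclass
class CostBreakdown:
    """Cost terms: ``nmi`` raw, ``be``/``jl`` per-evaluation-point means."""

    total: float
    nmi: float
    be: float
    jl: float


@dataclass
class FFDTransform:
    """Cubic B-spline free-form deformation of a reference voxel grid.

    ``control_points`` holds mm displacement vectors on a lattice whose
    cell size is ``grid_spacing`` voxels of the domain grid; the transform
    maps reference physical point x to x + u(x).
    """

    control_points: np.ndarray
    grid_spacing: tuple[float, float, float]
    domain_shape: tuple[int, int, int]
    domain_spacing: tuple[float, float, float]
    domain_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.grid_spacing = tuple(float(g) for g in np.broadcast_to(self.grid_spacing, (3,)))
        self.domain_shape = tuple(int(n) for n in self.domain_shape)
        self.domain_spacing = tuple(float(s) for s in self.domain_spacing)
        self.domain_origin = tuple(float(o) for o in self.domain_origin)
        if any(g < 2 for g in self.grid_spacing):
            raise ValueError("grid_spacing must be >= 2 voxels")
        expected = tuple(bsp.n_control_points(n, g)
                         for n, g in zip(self.domain_shape, self.grid_spacing))
        if self.control_points.shape != expected + (3,):
            raise ValueError(
                f"lattice shape {self.control_points.shape} does not cover the domain; "
                f"expected {expected + (3,)}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls, domain: Volume, grid_spacing=5.0) -> "FFDTransform":
        gs = tuple(float(g) for g in np.broadcast_to(grid_spacing, (3,)))
        shape = tuple(bsp.n_control_points(n, g) for n, g in zip(domain.shape, gs))
        return cls(np.zeros(shape + (3,)), gs, domain.shape, domain.spacing, domain.origin)

    # -- lattice machinery --------------------------------------------------
    def _mats(self, derivs=(0, 0, 0)) -> list[np.ndarray]:
        return [bsp.weight_matrix(n, g, g * s, deriv=d)
                for n, g, s, d in zip(self.domain_shape, self.grid_spacing,
                                      self.domain_spacing, derivs)]

    def displacement_field(self) -> np.ndarray:
        """Displacement (mm) at every domain voxel centre, shape (nx, ny, nz, 3)."""
        return bsp.separable_eval(self.control_points, self._mats())

    def displacement_at(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        vox = (pts - np.asarray(self.domain_origin)) / np.asarray(self.domain_spacing)
        return bsp.evaluate_at_points(self.control_points, vox, self.grid_spacing)

    def map_points(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts + self.displacement_at(pts)

    def jacobian_grid(self) -> np.ndarray:
        """J(x) = I + du/dx at every voxel centre, shape (nx, ny, nz, 3, 3)."""
        nx, ny, nz = self.domain_shape
        jac = np.zeros((nx, ny, nz, 3, 3))
        for b in range(3):
            derivs = [0, 0, 0]
            derivs[b] = 1
            du = bsp.separable_eval(self.control_points, self._mats(derivs))
            jac[..., :, b] = du
        jac[..., 0, 0] += 1.0
        jac[..., 1, 1] += 1.0
        jac[..., 2, 2] += 1.0
        return jac

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> dict:
        payload = {
            "control_points": self.control_points.tolist(),
            "grid_spacing": list(self.grid_spacing),
            "domain_shape": list(self.domain_shape),
            "domain_spacing": list(self.domain_spacing),
            "domain_origin": list(self.domain_origin),
            "convention": "maps reference physical x (mm) to x + u(x); u is a cubic "
                          "B-spline interpolation of control-point displacements (mm)",
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload))
        return payload

    @classmethod
    def from_json(cls, source) -> "FFDTransform":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text())
        return cls(np.asarray(source["control_points"]), tuple(source["grid_spacing"]),
                   tuple(source["domain_shape"]), tuple(source["domain_spacing"]),
                   tuple(source["domain_origin"]))


# ---------------------------------------------------------------------------
# cost terms
# ---------------------------------------------------------------------------

def _as_array(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume) else v, dtype=float)


def _bin_image(data: np.ndarray, n_bins: int) -> np.ndarray:
    """Hard-bin byte-range intensities into ``n_bins`` equal bins over [0, 256).

    The epsilon shields integer-valued data from one-ulp interpolation error
    (sampling a grid at exactly its own nodes must reproduce the bins).
    """
    b = np.floor((np.clip(data, 0.0, 255.0) + 1e-6) * (n_bins / 256.0)).astype(np.int64)
    return np.clip(b, 0, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    nz = counts[counts > 0]
    return float(np.log(n) - (nz * np.log(nz)).sum() / n)


def nmi(ref, mov_resampled, n_bins: int = 256, mask=None) -> float:
    """Normalized mutual information (H1 + H2) / H12 of two same-grid images.

    Intensities are expected to be pre-mapped to [0, 255] so the joint
    histogram bins fill sensibly.  Ranges in [1, 2]: 1 for independent
    images, 2 for deterministically related ones.
    """
    a = _as_array(ref)
    b = _as_array(mov_resampled)
    if a.shape != b.shape:
        raise ValueError("nmi requires images on a common grid")
    if mask is not None:
        m = np.asarray(mask.data if isinstance(mask, Volume) else mask).astype(bool)
        if not m.any():
            raise ValueError("empty mask")
        a, b = a[m], b[m]
    ba = _bin_image(a.ravel(), n_bins)
    bb = _bin_image(b.ravel(), n_bins)
    joint = np.bincount(ba * n_bins + bb, minlength=n_bins * n_bins)
    h1 = _entropy_from_counts(np.bincount(ba, minlength=n_bins))
    h2 = _entropy_from_counts(np.bincount(bb, minlength=n_bins))
    h12 = _entropy_from_counts(joint)
    if h12 <= 0:
        raise ValueError("degenerate single-bin histogram; NMI undefined")
    return (h1 + h2) / h12


def bending_energy(t: FFDTransform) -> float:
    """Sum over voxel centres of squared second derivatives of the deformation.

    Zero for any globally affine field.
    """
    total = 0.0
    for derivs, mult in _BE_OPS:
        d2 = bsp.separable_eval(t.control_points, t._mats(derivs))
        total += mult * float((d2 * d2).sum())
    return total


def _det3(j: np.ndarray) -> np.ndarray:
    return (j[..., 0, 0] * (j[..., 1, 1] * j[..., 2, 2] - j[..., 1, 2] * j[..., 2, 1])
            - j[..., 0, 1] * (j[..., 1, 0] * j[..., 2, 2] - j[..., 1, 2] * j[..., 2, 0])
            + j[..., 0, 2] * (j[..., 1, 0] * j[..., 2, 1] - j[..., 1, 1] * j[..., 2, 0]))


def jacobian_det_map(t: FFDTransform) -> Volume:
    """det J at every voxel centre; 1 means locally volume-preserving."""
    return Volume(_det3(t.jacobian_grid()), t.domain_spacing, t.domain_origin)


def jacobian_log_penalty(t: FFDTransform) -> float:
    """Sum of |log |det J|| over voxel centres; symmetric in expansion/compression."""
    det = _det3(t.jacobian_grid())
    bad = det < _FOLD_EPS
    if bad.any():
        loc = tuple(int(i) for i in np.argwhere(bad)[0])
        raise FoldingError(f"deformation folds at voxel {loc} (det={det[loc]:.3g})", loc)
    return float(np.abs(np.log(np.abs(det))).sum())


def total_cost(ref: Volume, mov: Volume, t: FFDTransform, cfg: FFDConfig,
               affine: AffineTransform | None = None) -> CostBreakdown:
    """Assemble the registration cost for volumes on a common (pre-aligned) grid.

    The moving volume is sampled at ``affine(x + u(x))`` (identity affine by
    default).  BE and JL are averaged over the domain's voxel count before
    weighting; the total is the minimised quantity.
    """
    if tuple(t.domain_shape) != tuple(ref.shape):
        raise ValueError("FFD domain does not match the reference grid")
    prob = _LevelProblem(ref, mov, t.grid_spacing, cfg,
                         affine or AffineTransform.identity())
    total, nmi_val, be_m, jl_m, _ = prob.cost(t.control_points)
    if not np.isfinite(total):
        raise FoldingError("deformation folds on the evaluation grid")
    return CostBreakdown(total, nmi_val, be_m, jl_m)


def compose_and_resample(mov: Volume, affine: AffineTransform | None,
                         ffd: FFDTransform | None, out_grid: Volume,
                         fill: float = 0.0, order: int = 1) -> Volume:
    """Warp ``mov`` onto ``out_grid`` through FFD then affine in one interpolation."""
    shape = out_grid.shape
    idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                               indexing="ij"), axis=-1)
    phys = np.asarray(out_grid.origin) + idx * np.asarray(out_grid.spacing)
    if ffd is not None:
        vox = (phys - np.asarray(ffd.domain_origin)) / np.asarray(ffd.domain_spacing)
        disp = bsp.evaluate_at_points(ffd.control_points, vox.reshape(-1, 3),
                                      ffd.grid_spacing).reshape(phys.shape)
        phys = phys + disp
    if affine is not None:
        phys = phys @ affine.matrix.T + affine.translation
    mvox = (phys - np.asarray(mov.origin)) / np.asarray(mov.spacing)
    data = _as_array(mov)
    if mov.is_color:
        out = np.stack([ndimage.map_coordinates(data[..., c], mvox.reshape(-1, 3).T,
                                                order=order, mode="constant", cval=fill
                                                ).reshape(shape) for c in range(3)], axis=-1)
    else:
        out = ndimage.map_coordinates(data, mvox.reshape(-1, 3).T, order=order,
                                      mode="constant", cval=fill).reshape(shape)
    return Volume(out, out_grid.spacing, out_grid.origin)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def _xlogx_sum(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = c[pos] * np.log(c[pos])
    return out


class _LevelProblem:
    """Cost and gradient of the FFD objective on one resolution level."""

    def __init__(self, ref: Volume, mov: Volume, grid_spacing, cfg: FFDConfig,
                 affine: AffineTransform):
        self.ref = ref
        self.mov_data = _as_array(mov)
        self.mov_origin = np.asarray(mov.origin)
        self.mov_spacing = np.asarray(mov.spacing)
        self.cfg = cfg
        self.affine = affine
        self.gs = tuple(float(g) for g in np.broadcast_to(grid_spacing, (3,)))
        self.shape = ref.shape
        self.n_eval = int(np.prod(self.shape))
        self.spacing = np.asarray(ref.spacing)

        self.W = [bsp.weight_matrix(n, g, g * s, deriv=0)
                  for n, g, s in zip(self.shape, self.gs, ref.spacing)]
        self.D1 = [bsp.weight_matrix(n, g, g * s, deriv=1)
                   for n, g, s in zip(self.shape, self.gs, ref.spacing)]
        self.D2 = [bsp.weight_matrix(n, g, g * s, deriv=2)
                   for n, g, s in zip(self.shape, self.gs, ref.spacing)]
        # per-axis voxel support range of each control point column
        self.support = []
        for W in self.W:
            nz = [np.nonzero(W[:, m])[0] for m in range(W.shape[1])]
            self.support.append([(int(r[0]), int(r[-1]) + 1) if len(r) else (0, 0)
                                 for r in nz])
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape],
                                   indexing="ij"), axis=-1)
        self.ref_phys = np.asarray(ref.origin) + idx * self.spacing
        self.ref_bins = _bin_image(_as_array(ref), cfg.n_bins)
        self.fd_step = cfg.fd_step_voxels * float(self.spacing.min())
        # histogram voxel set frozen at the affine pre-alignment: voxels whose
        # undeformed position falls inside the moving volume.  A set that moved
        # with the deformation would make the cost discontinuous (and let the
        # optimizer shrink its own overlap); clamped samples of voxels that
        # never overlap would fabricate background correlations.
        vox0 = ((self.ref_phys @ affine.matrix.T + affine.translation
                 - self.mov_origin) / self.mov_spacing)
        lim = np.asarray(self.mov_data.shape, dtype=float) - 1.0
        self.valid0 = np.all((vox0 >= -0.5) & (vox0 <= lim + 0.5), axis=-1)
        if not self.valid0.any():
            raise ValueError("no overlap between volumes under the affine pre-alignment")

    def _mats_for(self, derivs):
        table = {0: self.W, 1: self.D1, 2: self.D2}
        return [table[d][a] for a, d in enumerate(derivs)]

    def _warp_sample(self, cp: np.ndarray):
        # NMI is evaluated over the full reference grid with edge-clamped
        # sampling: an overlap-only histogram is discontinuous in the control
        # points whenever a voxel crosses the moving-volume border, which
        # stalls the line search at identity on same-grid volumes.
        disp = bsp.separable_eval(cp, self.W)
        phys = self.ref_phys + disp
        phys = phys @ self.affine.matrix.T + self.affine.translation
        vox = (phys - self.mov_origin) / self.mov_spacing
        # raw (unclamped) coordinates are kept so the finite-difference
        # gradient perturbs exactly what the cost path sees; mode="nearest"
        # performs the edge clamp during sampling
        samples = ndimage.map_coordinates(
            self.mov_data, vox.reshape(-1, 3).T, order=1,
            mode="nearest").reshape(self.shape)
        return vox, self.valid0, samples

    def _regularizers(self, cp: np.ndarray):
        be = 0.0
        for derivs, mult in _BE_OPS:
            d2 = bsp.separable_eval(cp, self._mats_for(derivs))
            be += mult * float((d2 * d2).sum())
        jac = np.zeros(self.shape + (3, 3))
        for b in range(3):
            derivs = [0, 0, 0]
            derivs[b] = 1
            jac[..., :, b] = bsp.separable_eval(cp, self._mats_for(derivs))
        for a in range(3):
            jac[..., a, a] += 1.0
        det = _det3(jac)
        return be, jac, det

    def cost(self, cp: np.ndarray):
        """Returns (total, nmi, be_mean, jl_mean, state); total=inf on folding."""
        be, jac, det = self._regularizers(cp)
        if det.min() < _FOLD_EPS:
            return np.inf, np.nan, np.nan, np.nan, None
        jl = float(np.abs(np.log(np.abs(det))).sum())
        vox, valid, samples = self._warp_sample(cp)
        if not valid.any():
            return np.inf, np.nan, np.nan, np.nan, None
        nb = self.cfg.n_bins
        rb = self.ref_bins[valid]
        mb = _bin_image(samples[valid], nb)
        joint = np.bincount(rb * nb + mb, minlength=nb * nb)
        h1 = _entropy_from_counts(np.bincount(rb, minlength=nb))
        h2 = _entropy_from_counts(np.bincount(mb, minlength=nb))
        h12 = _entropy_from_counts(joint)
        if h12 <= 0:
            return np.inf, np.nan, np.nan, np.nan, None
        nmi_val = (h1 + h2) / h12
        be_m, jl_m = be / self.n_eval, jl / self.n_eval
        w1, w2 = self.cfg.w1, self.cfg.w2
        total = -(1 - w1 - w2) * nmi_val + w1 * be_m + w2 * jl_m
        state = {"vox": vox, "valid": valid, "jac": jac, "det": det,
                 "joint": joint, "rb": rb, "mb": mb, "h1": h1}
        return total, nmi_val, be_m, jl_m, state

    # -- analytic gradients of the regularizer sums -------------------------
    def _be_gradient(self, cp: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(cp)
        for derivs, mult in _BE_OPS:
            mats = self._mats_for(derivs)
            d2 = bsp.separable_eval(cp, mats)
            grad += 2.0 * mult * bsp.separable_adjoint(d2, mats)
        return grad

    def _jl_gradient(self, jac: np.ndarray, det: np.ndarray) -> np.ndarray:
        # d|log|det||/dc = sign(log|det|) * tr(J^-1 dJ/dc)  (Jacobi's formula)
        sign = np.sign(np.log(np.abs(det)))
        inv = np.linalg.inv(jac)  # (..., 3, 3)
        grad = np.zeros(self.W[0].shape[1:] + tuple(w.shape[1] for w in self.W[1:]) + (3,))
        for b in range(3):
            derivs = [0, 0, 0]
            derivs[b] = 1
            f = sign[..., None] * inv[..., b, :]  # field over alpha
            grad += bsp.separable_adjoint(f, self._mats_for(derivs))
        return grad

    # -- finite-difference NMI gradient with incremental histograms ---------
    def _nmi_gradient(self, cp: np.ndarray, state: dict) -> np.ndarray:
        nb = self.cfg.n_bins
        vox, valid = state["vox"], state["valid"]
        joint, h1 = state["joint"], state["h1"]
        n_valid = int(valid.sum())
        mov_bins = np.full(self.shape, -1, dtype=np.int64)
        mov_bins[valid] = state["mb"]
        mc = np.bincount(state["mb"], minlength=nb)
        s_j = float(_xlogx_sum(joint).sum())
        s_m = float(_xlogx_sum(mc).sum())
        log_n = np.log(n_valid)
        delta = self.fd_step
        dirs = (self.affine.matrix / self.mov_spacing[:, None]) * delta  # rows scaled

        wcols = [[W[s0:s1, m] for m, (s0, s1) in enumerate(sup)]
                 for W, sup in zip(self.W, self.support)]
        grad = np.zeros_like(cp)
        ncp = cp.shape[:3]

        def perturbed_nmi(coords, rb_sel, mb0_sel):
            mb1 = _bin_image(ndimage.map_coordinates(self.mov_data, coords, order=1,
                                                     mode="nearest"), nb)
            changed = mb1 != mb0_sel
            if not changed.any():
                return None
            old_j = rb_sel[changed] * nb + mb0_sel[changed]
            new_j = rb_sel[changed] * nb + mb1[changed]
            ds_j = _delta_xlogx(joint, old_j, new_j)
            ds_m = _delta_xlogx(mc, mb0_sel[changed], mb1[changed])
            h2 = log_n - (s_m + ds_m) / n_valid
            h12 = log_n - (s_j + ds_j) / n_valid
            return (h1 + h2) / h12

        base_nmi = (h1 + (log_n - s_m / n_valid)) / (log_n - s_j / n_valid)
        for mx in range(ncp[0]):
            x0, x1 = self.support[0][mx]
            wx = wcols[0][mx]
            for my in range(ncp[1]):
                y0, y1 = self.support[1][my]
                wy = wcols[1][my]
                w_xy = wx[:, None] * wy[None, :]
                for mz in range(ncp[2]):
                    z0, z1 = self.support[2][mz]
                    box = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
                    vbox = valid[box].ravel()
                    if not vbox.any():
                        continue
                    w3 = (w_xy[:, :, None] * wcols[2][mz][None, None, :]).ravel()
                    sel = vbox & (w3 > 1e-12)
                    if not sel.any():
                        continue
                    w_sel = w3[sel]
                    coords0 = vox[box].reshape(-1, 3)[sel].T
                    rb_sel = self.ref_bins[box].ravel()[sel]
                    mb0_sel = mov_bins[box].ravel()[sel]
                    for a in range(3):
                        dv = dirs[:, a][:, None] * w_sel[None, :]
                        up = perturbed_nmi(coords0 + dv, rb_sel, mb0_sel)
                        dn = perturbed_nmi(coords0 - dv, rb_sel, mb0_sel)
                        if up is None and dn is None:
                            continue
                        up = base_nmi if up is None else up
                        dn = base_nmi if dn is None else dn
                        grad[mx, my, mz, a] = (up - dn) / (2 * delta)
        return grad

    def gradient(self, cp: np.ndarray, state: dict) -> np.ndarray:
        w1, w2 = self.cfg.w1, self.cfg.w2
        g = np.zeros_like(cp)
        w_nmi = 1 - w1 - w2
        if w_nmi > 0:
            g -= w_nmi * self._nmi_gradient(cp, state)
        if w1 > 0:
            g += (w1 / self.n_eval) * self._be_gradient(cp)
        if w2 > 0:
            g += (w2 / self.n_eval) * self._jl_gradient(state["jac"], state["det"])
        return g


def _delta_xlogx(counts: np.ndarray, idx_old: np.ndarray, idx_new: np.ndarray) -> float:
    """Change in sum(c log c) when one count moves idx_old -> idx_new per entry."""
    all_idx = np.concatenate([idx_old, idx_new])
    signs = np.concatenate([-np.ones(len(idx_old)), np.ones(len(idx_new))])
    uniq, inv = np.unique(all_idx, return_inverse=True)
    dc = np.bincount(inv, weights=signs, minlength=len(uniq))
    c0 = counts[uniq].astype(float)
    c1 = c0 + dc
    return float(_xlogx_sum(c1).sum() - _xlogx_sum(c0).sum())


def _descend(prob: _LevelProblem, cp: np.ndarray, cfg: FFDConfig, trace: list) -> np.ndarray:
    cost, *_rest = prob.cost(cp)
    state = _rest[-1]
    if state is None:
        raise FoldingError("initial deformation folds at this level")
    trace.append(cost)
    step_vox = 0.1 * float(prob.spacing.min())
    alpha = None
    for _ in range(cfg.max_iterations):
        g = prob.gradient(cp, state)
        gmax = float(np.abs(g).max())
        if gmax == 0:
            break
        alpha = (step_vox / gmax) if alpha is None else alpha * 2.0
        accepted = False
        for _halving in range(20):
            trial = cp - alpha * g
            c_trial, *_r = prob.cost(trial)
            if c_trial < cost:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        improvement = cost - c_trial
        cp, cost, state = trial, c_trial, _r[-1]
        trace.append(cost)
        if improvement < cfg.tolerance:
            break
    return cp


def optimize_ffd(ref: Volume, mov: Volume, init: AffineTransform | None,
                 cfg: FFDConfig) -> FFDTransform:
    """Multiscale gradient-descent FFD registration.

    ``init`` is the affine pre-alignment (reference -> moving, mm); the
    returned transform's displacements refine it, i.e. the moving volume is
    sampled at ``init(x + u(x))``.  The result carries a ``cost_trace``
    attribute with the accepted cost values per level (nonincreasing within
    each level).
    """
    affine = init or AffineTransform.identity()
    pyr_ref, pyr_mov = [ref], [mov]
    for _ in range(cfg.n_levels - 1):
        pyr_ref.append(downsample_volume(pyr_ref[-1]))
        pyr_mov.append(downsample_volume(pyr_mov[-1]))

    cp = None
    traces = []
    for level in range(cfg.n_levels - 1, -1, -1):
        r, m = pyr_ref[level], pyr_mov[level]
        t_level = FFDTransform.identity(r, cfg.grid_spacing)
        if cp is None:
            cp = t_level.control_points
        else:
            cp = bsp.subdivide(cp, t_level.control_points.shape[:3])
        prob = _LevelProblem(r, m, t_level.grid_spacing, cfg, affine)
        trace: list[float] = []
        cp = _descend(prob, cp, cfg, trace)
        traces.append(trace)

    final_domain = pyr_ref[0]
    result = FFDTransform(cp, (cfg.grid_spacing,) * 3, final_domain.shape,
                          final_domain.spacing, final_domain.origin)
    result.cost_trace = traces
    return result
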