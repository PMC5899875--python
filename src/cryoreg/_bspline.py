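"""Uniform cubic B-spline lattice machinery shared by the nonrigid transforms.

A lattice with grid spacing ``g`` (in voxels) over an axis of ``n`` voxels
has control points at lattice coordinates ``-1 .. floor((n-1)/g) + 2``; the
stored coefficient array index is the lattice coordinate plus one.  A voxel
at coordinate ``t`` (voxels) has local coordinate ``u = t/g - floor(t/g)``
and is influenced by the four control points ``floor(t/g) - 1 .. + 2``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "basis",
    "n_control_points",
    "weight_matrix",
    "separable_eval",
    "separable_adjoint",
    "evaluate_at_points",
    "subdivide",
]


def basis(u: np.ndarray, deriv: int = 0) -> np.ndarray:
    """The four cubic B-spline basis values (or u-derivatives) at local coordinate u.

    Returns an array of shape ``u.shape + (4,)``.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty(u.shape + (4,), dtype=float)
    if deriv == 0:
        out[..., 0] = (1 - u) ** 3 / 6.0
        out[..., 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
        out[..., 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
        out[..., 3] = u**3 / 6.0
    elif deriv == 1:
        out[..., 0] = -((1 - u) ** 2) / 2.0
        out[..., 1] = (3 * u**2 - 4 * u) / 2.0
        out[..., 2] = (-3 * u**2 + 2 * u + 1) / 2.0
        out[..., 3] = u**2 / 2.0
    elif deriv == 2:
        out[..., 0] = 1 - u
        out[..., 1] = 3 * u - 2
        out[..., 2] = 1 - 3 * u
        out[..., 3] = u
    else:
        raise ValueError(f"unsupported derivative order {deriv}")
    return out


def n_control_points(n_vox: int, grid_spacing: float) -> int:
    return int(np.floor((n_vox - 1) / grid_spacing)) + 4


def weight_matrix(n_vox: int, grid_spacing: float, step_mm: float, deriv: int = 0) -> np.ndarray:
    """Dense (n_vox, n_cp) interpolation matrix for one axis.

    ``step_mm`` is the physical lattice spacing (grid_spacing * voxel size);
    derivative matrices are scaled by ``step_mm**-deriv`` so they produce
    physical-space derivatives of fields whose coefficients are in mm.
    """
    t = np.arange(n_vox, dtype=float)
    s = t / grid_spacing
    i = np.floor(s).astype(int)
    u = s - i
    ncp = n_control_points(n_vox, grid_spacing)
    w = basis(u, deriv) / step_mm**deriv
    mat = np.zeros((n_vox, ncp))
    rows = np.repeat(np.arange(n_vox), 4)
    cols = (i[:, None] + np.arange(4)[None, :]).ravel()
    mat[rows, cols] = w.ravel()
    return mat


def separable_eval(cp: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Apply per-axis weight matrices to a coefficient array.

    ``cp`` has shape ``(nc_0, ..., nc_{d-1}, C)``; the result has shape
    ``(n_0, ..., n_{d-1}, C)``.
    """
    out = cp
    for axis, mat in enumerate(mats):
        out = np.moveaxis(np.tensordot(mat, out, axes=([1], [axis])), 0, axis)
    return out


def separable_adjoint(field: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Transpose of :func:`separable_eval` — scatter a field back onto the lattice."""
    out = field
    for axis, mat in enumerate(mats):
        out = np.moveaxis(np.tensordot(mat.T, out, axes=([1], [axis])), 0, axis)
    return out


def evaluate_at_points(cp: np.ndarray, coords_vox: np.ndarray, grid_spacing,
                       derivs=None, step_mm=None) -> np.ndarray:
    """Evaluate the lattice field (or a partial derivative) at arbitrary voxel coordinates.

    Parameters
    ----------
    cp : ndarray, shape (nc_0, ..., nc_{d-1}, C)
    coords_vox : ndarray, shape (N, d)
        Voxel coordinates; clamped to the lattice's supported range.
    grid_spacing : sequence of d floats (voxels per lattice cell)
    derivs : optional sequence of d ints
        Per-axis derivative order (0-2).
    step_mm : optional sequence of d floats
        Physical lattice spacing per axis; derivative axes are scaled by
        ``step_mm**-deriv`` (defaults to 1, i.e. lattice-coordinate derivatives).
    """
    d = coords_vox.shape[1]
    coords_vox = np.asarray(coords_vox, dtype=float)
    derivs = [0] * d if derivs is None else list(derivs)
    step_mm = [1.0] * d if step_mm is None else list(step_mm)
    idx = []
    wts = []
    for a in range(d):
        s = coords_vox[:, a] / float(grid_spacing[a])
        i = np.floor(s).astype(int)
        i = np.clip(i, 0, cp.shape[a] - 4)
        u = s - i
        idx.append(i)
        wts.append(basis(u, deriv=derivs[a]) / step_mm[a] ** derivs[a])
    out = np.zeros(coords_vox.shape[:1] + cp.shape[d:])
    for combo in np.ndindex(*([4] * d)):
        w = wts[0][:, combo[0]]
        for a in range(1, d):
            w = w * wts[a][:, combo[a]]
        gathered = cp[tuple(idx[a] + combo[a] for a in range(d))]
        out += w[:, None] * gathered
    return out


def _subdivide_axis(cp: np.ndarray, axis: int, n_new: int) -> np.ndarray:
    """Dyadic refinement along one axis (exact for uniform cubic B-splines).

    New coefficient at even lattice position 2i is (c[i-1] + 6 c[i] + c[i+1])/8;
    at odd position 2i+1 it is (c[i] + c[i+1])/2.  Edge coefficients are
    replicated where the old lattice runs out.
    """
    c = np.moveaxis(cp, axis, 0)
    padded = np.concatenate([c[:1], c, c[-1:], c[-1:]], axis=0)  # indices shifted by +1
    n_old = c.shape[0]
    out = np.empty((n_new,) + c.shape[1:], dtype=cp.dtype)
    for q in range(n_new):
        # new array index q -> new lattice coord q-1 -> old lattice coord (q-1)/2
        lat = q - 1
        if lat % 2 == 0:
            i = lat // 2 + 1  # old array index of c[i], in padded frame +1
            i = min(max(i, 0), n_old)
            out[q] = (padded[i - 1 + 1] + 6 * padded[i + 1] + padded[i + 1 + 1]) / 8.0
        else:
            i = (lat - 1) // 2 + 1
            i = min(max(i, 0), n_old)
            out[q] = (padded[i + 1] + padded[i + 1 + 1]) / 2.0
    return np.moveaxis(out, 0, axis)


def subdivide(cp: np.ndarray, new_shape) -> np.ndarray:
    """Refine a lattice to half spacing along every spatial axis."""
    out = cp
    d = cp.ndim - 1
    for axis in range(d):
        out = _subdivide_axis(out, axis, int(new_shape[axis]))
    return out
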