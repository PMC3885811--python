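"""Diffusion tensor estimation and tensor algebra.

The signal model is the monoexponential Stejskal–Tanner relation
``S = S0 * exp(-b * g^T D g)``; estimation solves the log-linearized system
per voxel by linear least squares (``lls``) or by one reweighting pass with
weights equal to the predicted squared signal (``wls``). Gradient directions
are rotated into the world frame by the measurement frame before the design
matrix is built. All tensor interpolation and averaging downstream uses the
Log-Euclidean framework: interpolate/average ``log(D)`` and exponentiate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (DWIVolume, DisplacementField, ScalarVolume, StructuralError,
                   TensorVolume, eigensystem_field, matrix_to_tensor6,
                   sample_trilinear, tensor6_to_matrix)

EPS_EIGENVALUE = 1e-12          # mm^2/s floor before logarithms

SCALAR_PROPERTIES = ("fa", "md", "rd", "ad", "ga", "fro", "lambda2", "lambda3")


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def design_matrix(gradients) -> np.ndarray:
    """Rows b*[gx^2, 2gxgy, 2gxgz, gy^2, 2gygz, gz^2] for non-baseline directions."""
    g = gradients.world_directions()[~gradients.is_baseline]
    b = gradients.b_value
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return b * np.stack([gx * gx, 2 * gx * gy, 2 * gx * gz,
                         gy * gy, 2 * gy * gz, gz * gz], axis=1)


def estimate_tensors(dwi: DWIVolume, method: str = "wls",
                     mask: Optional[np.ndarray] = None,
                     n_wls_iter: int = 1) -> TensorVolume:
    """Fit a diffusion tensor per voxel from the DWI signal.

    Requires at least one baseline and six non-collinear directions. Voxels
    with non-positive mean baseline are masked out.
    """
    table = dwi.gradients
    baseline = table.is_baseline
    if not baseline.any():
        raise StructuralError("tensor estimation requires a b=0 baseline")
    if (~baseline).sum() < 6:
        raise StructuralError("tensor estimation requires >= 6 gradient "
                              "directions")
    X = design_matrix(table)
    cond = np.linalg.cond(X)
    if cond > 1e6:
        raise StructuralError(
            f"gradient scheme is rank deficient (design condition number "
            f"{cond:.3g})")

    shape = dwi.data.shape[:3]
    s0 = dwi.data[..., baseline].mean(axis=3)
    valid = s0 > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    signals = dwi.data[..., ~baseline][valid]            # (nvox, m)
    s0v = s0[valid][:, np.newaxis]
    ratio = np.clip(signals / np.clip(s0v, 1e-30, None), 1e-10, None)
    y = -np.log(ratio)                                   # (nvox, m)

    pinv = np.linalg.pinv(X)
    d6 = y @ pinv.T                                      # (nvox, 6)
    if method == "wls":
        for _ in range(n_wls_iter):
            pred = s0v * np.exp(-(d6 @ X.T))
            w = pred ** 2                                # (nvox, m)
            A = np.einsum("vm,mi,mj->vij", w, X, X)
            rhs = ((w * y) @ X)
            d6 = np.linalg.solve(A, rhs[..., np.newaxis])[..., 0]
    elif method != "lls":
        raise ValueError(f"unknown estimation method {method!r}")

    tensors = np.zeros(shape + (6,))
    tensors[valid] = d6
    return TensorVolume(tensors, mask=valid, **dwi.spatial_kwargs())


# ---------------------------------------------------------------------------
# eigensystems and negative-eigenvalue filtering
# ---------------------------------------------------------------------------

@dataclass
class EigenSystem:
    """Sorted eigensystem of one tensor: λ1 ≥ λ2 ≥ λ3, unit right-handed vectors."""

    eigenvalues: np.ndarray      # (3,), descending, mm^2/s
    eigenvectors: np.ndarray     # (3, 3), rows e1, e2, e3


def eigensystem(tensor6: np.ndarray) -> EigenSystem:
    vals, vecs = eigensystem_field(np.asarray(tensor6, dtype=float))
    return EigenSystem(vals, vecs)


def filter_negative_eigenvalues(tv: TensorVolume) -> TensorVolume:
    """Clamp negative eigenvalues at zero and reconstitute the tensors.

    This is the step that guarantees FA lies in [0, 1] downstream.
    """
    vals, vecs = eigensystem_field(tv.tensors)
    vals = np.clip(vals, 0.0, None)
    mats = np.einsum("...ki,...k,...kj->...ij", vecs, vals, vecs)
    return TensorVolume(matrix_to_tensor6(mats), mask=tv.mask.copy(),
                        **tv.spatial_kwargs())


# ---------------------------------------------------------------------------
# scalar maps
# ---------------------------------------------------------------------------

def _scalars_from_eigenvalues(vals: np.ndarray, which: str) -> np.ndarray:
    l1, l2, l3 = vals[..., 0], vals[..., 1], vals[..., 2]
    mean = vals.mean(axis=-1)
    if which == "fa":
        num = np.linalg.norm(vals - mean[..., np.newaxis], axis=-1)
        den = np.linalg.norm(vals, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5) * num / den
        return np.where(den > 0, fa, 0.0)
    if which == "md":
        return mean
    if which == "ad":
        return l1
    if which == "rd":
        return (l2 + l3) / 2.0
    if which == "fro":
        return np.linalg.norm(vals, axis=-1)
    if which == "ga":
        logs = np.log(np.clip(vals, EPS_EIGENVALUE, None))
        logmean = logs.mean(axis=-1)
        return np.sqrt(((logs - logmean[..., np.newaxis]) ** 2).sum(axis=-1))
    if which == "lambda2":
        return l2
    if which == "lambda3":
        return l3
    raise ValueError(f"unknown property {which!r}; valid: "
                     f"{', '.join(SCALAR_PROPERTIES)}")


def scalar_map(tv: TensorVolume, which: str) -> ScalarVolume:
    """Scalar diffusion map (fa, md, rd, ad, ga, fro, lambda2, lambda3)."""
    which = which.lower()
    vals, _ = eigensystem_field(tv.tensors)
    data = _scalars_from_eigenvalues(vals, which)
    data = np.where(tv.mask, data, 0.0)
    return ScalarVolume(data, **tv.spatial_kwargs())


def scalars_from_eigenvalues(vals: np.ndarray, which: str) -> np.ndarray:
    """Closed-form scalar from eigenvalue triples (exposed for phantoms/tests)."""
    return _scalars_from_eigenvalues(np.asarray(vals, dtype=float),
                                     which.lower())


def color_fa(tv: TensorVolume) -> np.ndarray:
    """Directionally encoded color map: FA * |e1| per world (R, A, S) axis."""
    vals, vecs = eigensystem_field(tv.tensors)
    fa = _scalars_from_eigenvalues(vals, "fa")
    fa = np.where(tv.mask, fa, 0.0)
    return fa[..., np.newaxis] * np.abs(vecs[..., 0, :])


# ---------------------------------------------------------------------------
# Log-Euclidean algebra
# ---------------------------------------------------------------------------

def log_map(t6: np.ndarray) -> np.ndarray:
    """Matrix logarithm of SPD tensors (eigenvalues floored at EPS first)."""
    vals, vecs = eigensystem_field(np.asarray(t6, dtype=float))
    logs = np.log(np.clip(vals, EPS_EIGENVALUE, None))
    mats = np.einsum("...ki,...k,...kj->...ij", vecs, logs, vecs)
    return matrix_to_tensor6(mats)


def exp_map(log_t6: np.ndarray) -> np.ndarray:
    """Matrix exponential of log-tensors."""
    vals, vecs = eigensystem_field(np.asarray(log_t6, dtype=float))
    mats = np.einsum("...ki,...k,...kj->...ij", vecs, np.exp(vals), vecs)
    return matrix_to_tensor6(mats)


def le_mean(tensors: Sequence[np.ndarray],
            weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Log-Euclidean weighted mean exp(sum w_i log D_i); weights must sum to 1."""
    tensors = [np.asarray(t, dtype=float) for t in tensors]
    n = len(tensors)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise StructuralError(f"le_mean weights sum to {weights.sum()!r}, "
                              "expected 1")
    acc = np.zeros_like(tensors[0])
    for w, t in zip(weights, tensors):
        acc = acc + w * log_map(t)
    return exp_map(acc)


def le_mean_volumes(volumes: Sequence[TensorVolume],
                    weights: Optional[Sequence[float]] = None) -> TensorVolume:
    """Log-Euclidean mean of co-registered tensor volumes (grid of the first)."""
    ref = volumes[0]
    mean6 = le_mean([tv.tensors for tv in volumes], weights)
    mask = np.any([tv.mask for tv in volumes], axis=0)
    return TensorVolume(mean6, mask=mask, **ref.spatial_kwargs())


def _finite_strain_rotations(jacobians: np.ndarray) -> np.ndarray:
    """Rotation factor R of each local Jacobian F = R U (polar decomposition)."""
    U, _, Vt = np.linalg.svd(jacobians)
    R = U @ Vt
    # keep proper rotations even for reflecting Jacobians
    det = np.linalg.det(R)
    flip = det < 0
    if np.any(flip):
        U = U.copy()
        U[flip, :, -1] *= -1
        R = U @ Vt
    return R


def le_resample(tv: TensorVolume, field: DisplacementField,
                reorient: bool = True) -> TensorVolume:
    """Resample a tensor volume through a pull-back displacement field.

    For each voxel of the field's (atlas) grid the tensor is trilinearly
    interpolated in the log domain at the mapped subject-space position and
    exponentiated. With ``reorient=True`` the finite-strain rotation of the
    local mapping Jacobian is applied (identity for pure translations).
    Positions outside the subject volume produce zero tensors; their count is
    stored in the result's ``metadata['n_outside']``.
    """
    shape = field.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    atlas_world = field.index_to_world(idx)
    subject_world = field.map_points(atlas_world)
    subject_idx = tv.world_to_index(subject_world)

    inside = np.all((subject_idx >= -0.5) &
                    (subject_idx <= np.array(tv.shape) - 0.5), axis=1)

    log6 = log_map(tv.tensors)
    log6 = np.where(tv.mask[..., np.newaxis], log6, 0.0)
    # validity is decided by the half-voxel `inside` band; nearest-edge
    # sampling avoids spurious zeroing at coordinates like -1e-15
    sampled = sample_trilinear(log6, subject_idx, mode="nearest")
    mask_w = sample_trilinear(tv.mask.astype(float), subject_idx,
                              mode="nearest")
    valid = inside & (mask_w > 0.5)
    out6 = exp_map(sampled)
    out6[~valid] = 0.0

    if reorient:
        mats = tensor6_to_matrix(out6[valid])
        jac = _mapping_jacobians(field, idx[valid])
        R = _finite_strain_rotations(jac)
        # subject-space tensor D maps to atlas orientation R^T D R
        mats = np.einsum("vki,vkl,vlj->vij", R, mats, R)
        out6[valid] = matrix_to_tensor6(mats)

    tensors = out6.reshape(shape + (6,))
    mask = valid.reshape(shape)
    result = TensorVolume(tensors, mask=mask, **field.spatial_kwargs())
    result.metadata["n_outside"] = int((~inside).sum())
    return result


def _mapping_jacobians(field: DisplacementField, idx: np.ndarray) -> np.ndarray:
    """Local Jacobian of the atlas->subject mapping at the given voxel indices."""
    A = field.index_to_world_matrix
    grads = np.stack(
        [np.stack(np.gradient(field.field[..., c]), axis=-1)
         for c in range(3)], axis=-2)                      # (x,y,z,3,3)
    J = np.eye(3) + grads @ np.linalg.inv(A)
    return J[idx[:, 0], idx[:, 1], idx[:, 2]]
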