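"""In-package registration engines used by atlas building.

Two deliberately desk-scale engines behind a small functional interface:

* :func:`affine_register` — 12-parameter affine maximizing normalized
  correlation, multi-resolution (3 levels), first-moment (centroid)
  initialization, deterministic Powell optimization.
* :func:`greedy_diffeo_register` — greedy demons: the classic force
  ``(f - m)∇m / (|∇m|^2 + k (f - m)^2)``, Gaussian-smoothed updates composed
  into a pull-back displacement field, with step halving whenever the
  Jacobian determinant would become non-positive.

Fields follow the package-wide convention: a displacement field lives on the
fixed (atlas) grid and maps fixed-space world points into moving-space world
points (pull-back).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from scipy.optimize import minimize

from .core import (AffineTransform, DisplacementField, ScalarVolume,
                   sample_trilinear)

_TRANSLATION_SCALE = 2.0      # mm per unit of optimizer translation parameter
_LINEAR_SCALE = 0.05          # linear-part deviation per unit parameter


def normalized_correlation(a: np.ndarray, b: np.ndarray,
                           mask: Optional[np.ndarray] = None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den < 1e-12:
        return 0.0
    return float(a @ b / den)


def _centroid(vol: ScalarVolume) -> np.ndarray:
    w = np.clip(vol.data, 0, None)
    total = w.sum()
    if total <= 0:
        return vol.index_to_world(np.array(vol.shape, dtype=float) / 2)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in vol.shape],
                               indexing="ij"), axis=-1)
    com = (w[..., np.newaxis] * idx).sum(axis=(0, 1, 2)) / total
    return vol.index_to_world(com)


def _downsample(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sm = gaussian_filter(vol.data, sigma=factor / 2.0)
    data = zoom(sm, 1.0 / factor, order=1)
    return ScalarVolume(data, spacing=vol.spacing * factor,
                        origin=vol.origin, direction=vol.direction)


def _params_to_map(p: np.ndarray, center: np.ndarray):
    """Optimizer parameters -> world pull-back map fixed->moving (A, t) about center."""
    A = np.eye(3) + _LINEAR_SCALE * p[:9].reshape(3, 3)
    t = p[9:] * _TRANSLATION_SCALE
    return A, t - A @ center + center


def phase_correlation_shift(fixed: np.ndarray, moving: np.ndarray,
                            spacing: np.ndarray,
                            max_shift_fraction: float = 0.25) -> np.ndarray:
    """Integer-voxel translation s (mm) with moving(u) ~ fixed(u - s).

    Classic phase correlation on same-shape axis-aligned grids; used only to
    initialize the affine optimizer, which refines to subvoxel accuracy. The
    peak search is limited to lags within ``max_shift_fraction`` of the FOV:
    periodic anatomy (e.g., a bundle whose radius modulates with a fixed
    period) produces aliased peaks at large lags.
    """
    F = np.fft.fftn(fixed)
    M = np.fft.fftn(moving)
    cross = M * np.conj(F)
    denom = np.abs(cross)
    cross = np.where(denom > 1e-12, cross / np.where(denom > 0, denom, 1), 0)
    corr = np.real(np.fft.ifftn(cross))
    shape = np.array(corr.shape)
    lags = [np.minimum(np.arange(n), np.arange(n)[::-1] + 1) for n in shape]
    within = np.ones(corr.shape, dtype=bool)
    for ax, lag in enumerate(lags):
        view = [np.newaxis] * corr.ndim
        view[ax] = slice(None)
        within &= lag[tuple(view)] <= max_shift_fraction * shape[ax]
    corr = np.where(within, corr, -np.inf)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = np.array(peak, dtype=float)
    wrap = shift > shape / 2
    shift[wrap] -= shape[wrap]
    return shift * spacing


def affine_register(moving_fa: ScalarVolume, fixed_fa: ScalarVolume,
                    levels: Tuple[int, ...] = (4, 2, 1),
                    maxiter: int = 60) -> AffineTransform:
    """Affine transform mapping moving (subject) coords into fixed coords.

    Maximizes normalized correlation of the fixed image and the affinely
    warped moving image over 12 parameters. Deterministic: centroid
    initialization, Powell descent, fixed level schedule. If the optimizer
    stops without converging the best-so-far transform is returned with a
    ``converged`` attribute set to False.
    """
    center = _centroid(fixed_fa)
    if fixed_fa.shape == moving_fa.shape and \
            np.allclose(fixed_fa.spacing, moving_fa.spacing):
        init_t = phase_correlation_shift(fixed_fa.data, moving_fa.data,
                                         fixed_fa.spacing)
    else:
        init_t = _centroid(moving_fa) - _centroid(fixed_fa)
    p = np.zeros(12)
    p[9:] = init_t / _TRANSLATION_SCALE      # pull-back: fixed -> moving
    converged = True
    for factor in levels:
        fx = _downsample(fixed_fa, factor)
        mv = _downsample(moving_fa, factor)
        grid_idx = np.stack(np.meshgrid(*[np.arange(s) for s in fx.shape],
                                        indexing="ij"), axis=-1).reshape(-1, 3)
        fixed_world = fx.index_to_world(grid_idx)
        fixed_vals = fx.data.ravel()

        def objective(params):
            A, t = _params_to_map(params, center)
            moving_world = fixed_world @ A.T + t
            vals = sample_trilinear(mv.data, mv.world_to_index(moving_world),
                                    mode="constant", cval=0.0)
            # mild shrinkage toward identity keeps the optimizer out of
            # distant basins when the correlation surface is flat
            penalty = 1e-6 * float((params[:9] ** 2).sum())
            return -normalized_correlation(fixed_vals, vals) + penalty

        # two Powell passes per level: the restart resets the direction set,
        # which escapes stalls on anisotropic correlation surfaces
        for _restart in range(2):
            res = minimize(objective, p, method="Powell",
                           options={"maxiter": maxiter, "xtol": 1e-6,
                                    "ftol": 1e-9})
            p = res.x
        converged = converged and (res.status == 0)

    A, t = _params_to_map(p, center)
    # p parameterizes the pull-back fixed->moving; the subject->atlas affine
    # is its inverse.
    pullback = AffineTransform(A, t)
    out = pullback.inverse()
    out.converged = converged
    return out


def affine_to_field(transform_fixed_to_moving, reference: ScalarVolume
                    ) -> DisplacementField:
    """Densify any world->world map into a pull-back field on a reference grid."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in reference.shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = reference.index_to_world(idx)
    mapped = transform_fixed_to_moving(world)
    disp = (mapped - world).reshape(tuple(reference.shape) + (3,))
    return DisplacementField(disp, **reference.spatial_kwargs())


def warp_scalar(moving: ScalarVolume, field: DisplacementField
                ) -> ScalarVolume:
    """Resample a scalar image through a pull-back field onto the field grid."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in field.shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = field.index_to_world(idx)
    mapped = field.map_points(world)
    midx = moving.world_to_index(mapped)
    inside = np.all((midx >= -0.5) &
                    (midx <= np.array(moving.shape) - 0.5), axis=1)
    vals = sample_trilinear(moving.data, midx, mode="nearest")
    vals[~inside] = 0.0
    return ScalarVolume(vals.reshape(field.shape), **field.spatial_kwargs())


@dataclass
class DemonsParams:
    """Greedy demons schedule and regularization."""

    iterations: Tuple[int, ...] = (30, 20, 10)   # per level, coarse -> fine
    levels: Tuple[int, ...] = (4, 2, 1)
    sigma_fluid_vox: float = 1.0                  # update smoothing
    sigma_field_vox: float = 1.0                  # field smoothing
    step: float = 1.0                             # force scaling, mm-ish
    k: float = 1.0                                # force denominator weight
    intensity_tolerance: float = 0.002            # |diff| below this -> no force
    max_halvings: int = 8


def _demons_level(fixed: np.ndarray, moving: np.ndarray, disp: np.ndarray,
                  spacing: np.ndarray, params: DemonsParams, n_iter: int
                  ) -> np.ndarray:
    """Run demons iterations on one resolution level (axis-aligned grids)."""
    shape = fixed.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    for _ in range(n_iter):
        sample_idx = idx + disp / spacing
        warped = sample_trilinear(moving, sample_idx.reshape(-1, 3),
                                  mode="constant", cval=0.0).reshape(shape)
        grads = np.stack(np.gradient(warped, *spacing), axis=-1)
        diff = fixed - warped
        # differences below interpolation noise exert no force: keeps the
        # atlas loops from chasing their own resampling blur
        diff = np.where(np.abs(diff) < params.intensity_tolerance, 0.0, diff)
        g2 = (grads ** 2).sum(axis=-1)
        den = g2 + params.k * diff ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            force = (diff / den)[..., np.newaxis] * grads
        force[den < 1e-12] = 0.0
        for c in range(3):
            force[..., c] = gaussian_filter(force[..., c],
                                            params.sigma_fluid_vox)
        step = params.step
        for _halv in range(params.max_halvings):
            cand = disp + step * force
            for c in range(3):
                cand[..., c] = gaussian_filter(cand[..., c],
                                               params.sigma_field_vox)
            if _min_jacobian(cand, spacing) > 0:
                disp = cand
                break
            step /= 2.0
        else:
            raise RuntimeError(
                "demons update could not preserve a positive Jacobian after "
                f"{params.max_halvings} halvings")
    return disp


def _min_jacobian(disp: np.ndarray, spacing: np.ndarray) -> float:
    grads = np.stack([np.stack(np.gradient(disp[..., c], *spacing), axis=-1)
                      for c in range(3)], axis=-2)
    J = np.eye(3) + grads
    return float(np.linalg.det(J).min())


def greedy_diffeo_register(moving_fa: ScalarVolume, fixed_fa: ScalarVolume,
                           params: Optional[DemonsParams] = None
                           ) -> DisplacementField:
    """Greedy demons registration of (affinely pre-aligned) scalar images.

    Returns the pull-back displacement field on the fixed grid with strictly
    positive Jacobian determinant. Assumes both images share the fixed
    image's axis-aligned grid orientation (the atlas pipeline guarantees it).
    """
    params = params or DemonsParams()
    spacing_full = fixed_fa.spacing
    disp = None
    for factor, n_iter in zip(params.levels, params.iterations):
        fx = _downsample(fixed_fa, factor)
        mv = _downsample(moving_fa, factor)
        spacing = fx.spacing
        if disp is None:
            disp = np.zeros(tuple(fx.shape) + (3,))
        else:
            disp = np.stack(
                [zoom(disp[..., c],
                      np.array(fx.shape) / np.array(disp.shape[:3]),
                      order=1) for c in range(3)], axis=-1)
        disp = _demons_level(fx.data, mv.data, disp, spacing, params, n_iter)
    fld = DisplacementField(disp, spacing=spacing_full,
                            origin=fixed_fa.origin,
                            direction=fixed_fa.direction)
    return fld


def compose_fields(first: DisplacementField, second: DisplacementField
                   ) -> DisplacementField:
    """compose(f, g)(x) = g(f(x)), sampled on the grid of ``first``."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in first.shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = first.index_to_world(idx)
    mid = first.map_points(world)
    end = second.map_points(mid)
    disp = (end - world).reshape(tuple(first.shape) + (3,))
    return DisplacementField(disp, **first.spatial_kwargs())
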