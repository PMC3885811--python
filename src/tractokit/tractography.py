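"""Single-tensor streamline tractography seeded from label maps.

Streamlines follow the principal eigenvector of the trilinearly interpolated
log-tensor field (eigenvectors of log D equal those of D, so interpolation
stays in the Log-Euclidean framework) with second-order Runge-Kutta
integration, FA and curvature stopping, and deterministic seeding. Default
thresholds are package choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import (FiberBundle, LabelVolume, ScalarVolume, StructuralError,
                   TensorVolume, empty_bundle, sample_trilinear,
                   tensor6_to_matrix)
from .tensor import log_map


@dataclass
class TrackingParams:
    seed_fa_min: float = 0.20
    stop_fa_min: float = 0.15
    step_mm: float = 0.5
    max_angle_deg: float = 45.0
    min_length_mm: float = 10.0
    max_length_mm: float = 300.0
    seeds_per_voxel: int = 1

    def __post_init__(self):
        if not (0 < self.stop_fa_min <= self.seed_fa_min < 1):
            raise StructuralError("require 0 < stop_fa_min <= seed_fa_min < 1")
        if self.step_mm <= 0:
            raise StructuralError("step_mm must be positive")


def seeds_from_labelmap(labels: LabelVolume, label_value: int,
                        fa: ScalarVolume, params: TrackingParams
                        ) -> np.ndarray:
    """Deterministic world-space seed points for one label.

    One seed per matching voxel at the voxel centre (FA-gated); for
    ``seeds_per_voxel > 1`` additional seeds are jittered inside the voxel by
    a fixed, reproducible pattern.
    """
    sel = np.argwhere(labels.data == label_value)
    if len(sel) == 0:
        raise StructuralError(f"label value {label_value} not present")
    fa_vals = fa.data[sel[:, 0], sel[:, 1], sel[:, 2]]
    sel = sel[fa_vals >= params.seed_fa_min]
    if len(sel) == 0:
        raise StructuralError(
            f"no voxel of label {label_value} passes the FA >= "
            f"{params.seed_fa_min} seed gate")
    sel = sel[np.lexsort((sel[:, 2], sel[:, 1], sel[:, 0]))]
    k = params.seeds_per_voxel
    if k == 1:
        offsets = np.zeros((1, 3))
    else:
        rng = np.random.default_rng(1234)      # fixed: seeding is deterministic
        offsets = rng.uniform(-0.45, 0.45, (k, 3))
        offsets[0] = 0.0
    idx = (sel[:, np.newaxis, :] + offsets[np.newaxis, :, :]).reshape(-1, 3)
    return labels.index_to_world(idx)


class _TensorSampler:
    """Trilinear log-tensor sampling with per-point eigensystem."""

    def __init__(self, tv: TensorVolume):
        self.tv = tv
        log6 = log_map(tv.tensors)
        self.log6 = np.where(tv.mask[..., np.newaxis], log6, 0.0)
        self.maskf = tv.mask.astype(float)

    def probe(self, world_points: np.ndarray):
        """Return (e1 unit vectors, FA, in_mask) at world points."""
        pts = np.atleast_2d(world_points)
        idx = self.tv.world_to_index(pts)
        inside = np.all((idx >= 0) & (idx <= np.array(self.tv.shape) - 1),
                        axis=1)
        mask_w = sample_trilinear(self.maskf, idx, mode="constant")
        ok = inside & (mask_w > 0.999)
        e1 = np.zeros((len(pts), 3))
        fa = np.zeros(len(pts))
        if ok.any():
            log_t = sample_trilinear(self.log6, idx[ok], mode="nearest")
            mats = tensor6_to_matrix(log_t)
            vals, vecs = np.linalg.eigh(mats)
            lam = np.exp(vals[:, ::-1])        # descending eigenvalues of D
            e1[ok] = vecs[:, :, 2]             # largest eigenvalue's vector
            mean = lam.mean(axis=1, keepdims=True)
            num = np.linalg.norm(lam - mean, axis=1)
            den = np.linalg.norm(lam, axis=1)
            fa_ok = np.where(den > 0, np.sqrt(1.5) * num / den, 0.0)
            fa[ok] = fa_ok
        return e1, fa, ok


def _integrate(sampler: _TensorSampler, seed: np.ndarray, d0: np.ndarray,
               params: TrackingParams):
    """RK2 streamline from seed along initial direction d0."""
    cos_max = np.cos(np.radians(params.max_angle_deg))
    max_steps = int(params.max_length_mm / params.step_mm) + 2
    pts = [seed.copy()]
    fas = []
    e1, fa, ok = sampler.probe(seed)
    if not ok[0] or fa[0] < params.stop_fa_min:
        return np.array(pts), np.array([fa[0]])
    fas.append(fa[0])
    prev = d0 / np.linalg.norm(d0)
    p = seed.copy()
    for _ in range(max_steps):
        e1a, _, oka = sampler.probe(p)
        if not oka[0]:
            break
        d1 = _orient(e1a[0], prev)
        if d1 is None:
            break
        mid = p + 0.5 * params.step_mm * d1
        e1b, _, okb = sampler.probe(mid)
        if not okb[0]:
            break
        d2 = _orient(e1b[0], d1)
        if d2 is None or d2 @ prev < cos_max:
            break
        nxt = p + params.step_mm * d2
        _, fa_n, ok_n = sampler.probe(nxt)
        if not ok_n[0] or fa_n[0] < params.stop_fa_min:
            break
        pts.append(nxt)
        fas.append(fa_n[0])
        prev = d2
        p = nxt
    return np.array(pts), np.array(fas)


def _orient(e1: np.ndarray, prev: np.ndarray):
    n = np.linalg.norm(e1)
    if n < 1e-12:
        return None
    d = e1 / n
    return -d if d @ prev < 0 else d


def track(tv: TensorVolume, seeds: np.ndarray,
          params: Optional[TrackingParams] = None) -> FiberBundle:
    """Streamline tractography from world-space seeds on a filtered DTI.

    Each seed is integrated in both principal-eigenvector directions; the
    halves are joined at the seed. Fibers outside the length window are
    discarded; per-point FA is attached as point data. Deterministic:
    identical inputs produce bitwise-identical bundles.
    """
    params = params or TrackingParams()
    sampler = _TensorSampler(tv)
    fibers: List[np.ndarray] = []
    fa_arrays: List[np.ndarray] = []
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    for seed in seeds:
        e1, fa, ok = sampler.probe(seed)
        if not ok[0] or fa[0] < params.seed_fa_min:
            continue
        d0 = e1[0]
        if np.linalg.norm(d0) < 1e-12:
            continue
        fwd_pts, fwd_fa = _integrate(sampler, seed, d0, params)
        bwd_pts, bwd_fa = _integrate(sampler, seed, -d0, params)
        pts = np.vstack([bwd_pts[::-1], fwd_pts[1:]])
        fa_line = np.concatenate([bwd_fa[::-1], fwd_fa[1:]])
        if len(pts) < 2:
            continue
        length = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if params.min_length_mm <= length <= params.max_length_mm:
            fibers.append(pts)
            fa_arrays.append(fa_line)
    if not fibers:
        out = empty_bundle()
        out.metadata["empty"] = True
        return out
    return FiberBundle(fibers, {"FA": fa_arrays})
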