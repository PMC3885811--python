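"""Fiber bundle cleaning and clustering.

ROI keep/remove selection, hemisphere splitting about a plane, length
filtering, pairwise fiber distances (centre of gravity, mean-closest-point,
Hausdorff, and their Danielsson distance-map approximations) and clustering
by single-linkage thresholding or recursive two-way normalized cuts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import distance_transform_edt
from scipy.spatial.distance import cdist, squareform

from .core import FiberBundle, LabelVolume, StructuralError

DISTANCE_METHODS = ("cog", "mean_closest", "hausdorff",
                    "danielsson_mean", "danielsson_hausdorff")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _points_in_labelvolume(points: np.ndarray, roi: LabelVolume) -> np.ndarray:
    idx = np.round(roi.world_to_index(points)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(roi.shape)), axis=1)
    hit = np.zeros(len(points), dtype=bool)
    if inside.any():
        ii = idx[inside]
        hit[inside] = roi.data[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
    return hit


def _points_in_box(points: np.ndarray, box) -> np.ndarray:
    lo, hi = np.asarray(box[0], dtype=float), np.asarray(box[1], dtype=float)
    return np.all((points >= lo) & (points <= hi), axis=1)


def select_by_roi(bundle: FiberBundle,
                  roi: Union[LabelVolume, Tuple],
                  mode: str = "keep_through") -> FiberBundle:
    """Keep or remove fibers passing through an ROI (label volume or world box).

    A fiber passes through the ROI iff any of its points falls inside an ROI
    voxel (or inside the box). Iterative application composes.
    """
    if mode not in ("keep_through", "remove_through"):
        raise ValueError(f"unknown mode {mode!r}")
    test = _points_in_labelvolume if isinstance(roi, LabelVolume) \
        else _points_in_box
    if isinstance(roi, LabelVolume) and not (roi.data > 0).any():
        raise StructuralError("ROI is empty")
    through = np.array([test(f, roi).any() for f in bundle.fibers], dtype=bool)
    keep = through if mode == "keep_through" else ~through
    return bundle.select(np.flatnonzero(keep))


def split_hemispheres(bundle: FiberBundle, plane):
    """Partition fibers by the side of a plane (point + unit normal).

    Returns (left, right, crossing): fibers entirely on the negative side of
    the normal go left, entirely positive right, plane-intersecting fibers
    to crossing.
    """
    normal = np.asarray(plane.normal, dtype=float)
    if np.linalg.norm(normal) < 1e-12:
        raise StructuralError("plane normal must be nonzero")
    normal = normal / np.linalg.norm(normal)
    point = np.asarray(plane.point, dtype=float)
    left_idx, right_idx, cross_idx = [], [], []
    for i, f in enumerate(bundle.fibers):
        side = (f - point) @ normal
        if (side < 0).all():
            left_idx.append(i)
        elif (side > 0).all():
            right_idx.append(i)
        else:
            cross_idx.append(i)
    return (bundle.select(left_idx), bundle.select(right_idx),
            bundle.select(cross_idx))


def length_filter(bundle: FiberBundle, min_mm: float,
                  max_mm: float) -> FiberBundle:
    """Retain fibers whose arclength lies within [min_mm, max_mm]."""
    if not (0 <= min_mm < max_mm):
        raise StructuralError("require 0 <= min_mm < max_mm")
    lengths = bundle.fiber_lengths()
    keep = np.flatnonzero((lengths >= min_mm) & (lengths <= max_mm))
    return bundle.select(keep)


# ---------------------------------------------------------------------------
# pairwise fiber distances
# ---------------------------------------------------------------------------

@dataclass
class FiberDistanceMatrix:
    """Symmetric pairwise fiber distances (mm) with the method tag."""

    values: np.ndarray
    method: str


def _closest_point_stats(a: np.ndarray, b: np.ndarray):
    d = cdist(a, b)
    a_to_b = d.min(axis=1)
    b_to_a = d.min(axis=0)
    return a_to_b, b_to_a


def _danielsson_maps(bundle: FiberBundle, voxel_mm: float):
    """Per-fiber Euclidean distance maps on the bundle bounding grid."""
    pts = bundle.all_points()
    lo = pts.min(axis=0) - 2 * voxel_mm
    hi = pts.max(axis=0) + 2 * voxel_mm
    shape = np.maximum(np.ceil((hi - lo) / voxel_mm).astype(int) + 1, 4)
    maps = []
    for f in bundle.fibers:
        occ = np.ones(tuple(shape), dtype=bool)
        idx = np.clip(np.round((f - lo) / voxel_mm).astype(int), 0, shape - 1)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = False
        maps.append(distance_transform_edt(occ, sampling=voxel_mm))
    return maps, lo, shape


def fiber_distance_matrix(bundle: FiberBundle, method: str = "mean_closest",
                          voxel_mm: float = 1.0) -> FiberDistanceMatrix:
    """Pairwise distances between all fibers of a bundle.

    ``cog``: distance between fiber centroids. ``mean_closest``: mean
    closest-point distance, symmetrized by averaging both directions.
    ``hausdorff``: max closest-point distance, symmetrized by max.
    ``danielsson_*``: the same statistics evaluated against precomputed
    per-fiber voxelized distance maps instead of exact point pairs.
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown method {method!r}; valid: "
                         f"{', '.join(DISTANCE_METHODS)}")
    n = len(bundle)
    if n < 2:
        raise StructuralError("distance matrix needs >= 2 fibers")
    for i, f in enumerate(bundle.fibers):
        if len(f) < 2:
            raise StructuralError(f"fiber {i} has fewer than 2 points")
    d = np.zeros((n, n))
    if method == "cog":
        cogs = np.array([f.mean(axis=0) for f in bundle.fibers])
        d = cdist(cogs, cogs)
    elif method in ("mean_closest", "hausdorff"):
        for i in range(n):
            for j in range(i + 1, n):
                ab, ba = _closest_point_stats(bundle.fibers[i],
                                              bundle.fibers[j])
                if method == "mean_closest":
                    v = 0.5 * (ab.mean() + ba.mean())
                else:
                    v = max(ab.max(), ba.max())
                d[i, j] = d[j, i] = v
    else:
        maps, lo, shape = _danielsson_maps(bundle, voxel_mm)
        stat = np.mean if method == "danielsson_mean" else np.max
        raw = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                idx = np.clip(np.round((bundle.fibers[i] - lo) / voxel_mm
                                       ).astype(int), 0, shape - 1)
                raw[i, j] = stat(maps[j][idx[:, 0], idx[:, 1], idx[:, 2]])
        if method == "danielsson_mean":
            d = 0.5 * (raw + raw.T)
        else:
            d = np.maximum(raw, raw.T)
    np.fill_diagonal(d, 0.0)
    return FiberDistanceMatrix(values=d, method=method)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterParams:
    threshold_mm: float = 10.0        # single-linkage cut distance
    k: int = 2                        # normalized-cut target cluster count
    sigma_mm: Optional[float] = None  # affinity width; default median distance


def cluster(bundle: FiberBundle, method: str = "cog",
            params: Optional[ClusterParams] = None,
            voxel_mm: float = 1.0) -> np.ndarray:
    """Cluster fibers; returns integer labels, renumbered by first occurrence.

    Distance-based methods (cog / hausdorff / mean_closest and Danielsson
    variants) use single-linkage agglomeration cut at ``threshold_mm``;
    ``normalized_cut`` recursively bisects the exp(-d^2/sigma^2) affinity
    graph down to ``k`` clusters with deterministic tie-breaking.
    """
    params = params or ClusterParams()
    n = len(bundle)
    if method == "normalized_cut":
        if params.k > n:
            raise StructuralError(f"k={params.k} exceeds {n} fibers")
        d = fiber_distance_matrix(bundle, "mean_closest", voxel_mm).values
        labels = _recursive_ncut(d, params.k, params.sigma_mm)
    else:
        d = fiber_distance_matrix(bundle, method, voxel_mm).values
        Z = linkage(squareform(d, checks=False), method="single")
        labels = fcluster(Z, t=params.threshold_mm, criterion="distance")
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    out = np.empty(len(labels), dtype=int)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _recursive_ncut(d: np.ndarray, k: int, sigma: Optional[float]
                    ) -> np.ndarray:
    n = d.shape[0]
    if sigma is None:
        off = d[np.triu_indices(n, 1)]
        sigma = np.median(off) if len(off) else 1.0
        sigma = max(sigma, 1e-9)
    W = np.exp(-(d / sigma) ** 2)
    labels = np.zeros(n, dtype=int)
    while labels.max() + 1 < k:
        # split the largest cluster; ties -> the one with the lowest index
        sizes = np.bincount(labels)
        candidates = np.flatnonzero(sizes == sizes.max())
        target = min(candidates,
                     key=lambda c: int(np.flatnonzero(labels == c)[0]))
        members = np.flatnonzero(labels == target)
        if len(members) < 2:
            raise StructuralError("cannot split a singleton cluster further")
        part = _ncut_bisect(W[np.ix_(members, members)])
        new_label = labels.max() + 1
        labels[members[part]] = new_label
    return labels


def _ncut_bisect(W: np.ndarray) -> np.ndarray:
    """Two-way normalized cut: boolean mask of the side to relabel."""
    deg = W.sum(axis=1)
    deg = np.maximum(deg, 1e-12)
    d_isqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(W)) - d_isqrt[:, np.newaxis] * W * d_isqrt[np.newaxis, :]
    vals, vecs = np.linalg.eigh(L)
    fiedler = d_isqrt * vecs[:, 1]
    order = np.argsort(fiedler, kind="stable")
    best_cost, best_cut = np.inf, 1
    total = W.sum()
    for cut in range(1, len(W)):
        a = order[:cut]
        b = order[cut:]
        assoc_a = W[a].sum()
        assoc_b = W[b].sum()
        cut_w = W[np.ix_(a, b)].sum()
        cost = cut_w / max(assoc_a, 1e-12) + cut_w / max(assoc_b, 1e-12)
        if cost < best_cost - 1e-15:
            best_cost, best_cut = cost, cut
    side = np.zeros(len(W), dtype=bool)
    side[order[best_cut:]] = True
    # deterministic orientation: the side containing fiber 0 keeps its label
    if side[0]:
        side = ~side
    return side
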