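"""Origin-plane arclength parameterization and diffusion property profiles.

The atlas bundle is parameterized by signed arclength from each fiber's
intersection with an origin plane, giving along-tract correspondence across
fibers and subjects. Parameterized fibers are deformed into each subject's
original space through the Global Displacement Field (arclengths travel
unchanged: correspondence is by atlas arclength), and diffusion properties
are sampled there from scalar maps computed on the original subject tensors
— never on resampled ones. Profile values are Gaussian-in-arclength weighted
means on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (DisplacementField, FiberBundle, StructuralError,
                   TensorVolume, sample_trilinear, segment_lengths)
from .tensor import SCALAR_PROPERTIES, scalar_map

LOCATION_INDEX = "FiberLocationIndex"


@dataclass
class OriginPlane:
    """Plane assigning arclength zero: point (mm) and unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise StructuralError("plane normal must be nonzero")
        self.normal = n / nn

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


# ---------------------------------------------------------------------------
# origin plane determination
# ---------------------------------------------------------------------------

def _mid_tangents(bundle: FiberBundle) -> np.ndarray:
    """Unit tangent of each fiber at its mid-arclength point."""
    tangents = []
    for f in bundle.fibers:
        seg = segment_lengths(f)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        mid = cum[-1] / 2.0
        j = int(np.searchsorted(cum, mid, side="right") - 1)
        j = min(j, len(seg) - 1)
        t = f[j + 1] - f[j]
        tangents.append(t / np.linalg.norm(t))
    return np.array(tangents)


def _count_intersections(bundle: FiberBundle, plane: OriginPlane) -> int:
    n = 0
    for f in bundle.fibers:
        h = plane.signed_distance(f)
        if (h.min() < 0) and (h.max() > 0):
            n += 1
    return n


def auto_origin_plane(bundle: FiberBundle) -> OriginPlane:
    """Origin plane through the bundle centroid, normal to the bundle course.

    The normal is the mean mid-arclength tangent (antipodally aligned before
    averaging). If some fiber misses the centroid plane, candidate planes
    through each fiber midpoint are swept and the one intersecting most
    fibers wins (count stored nowhere — the caller can recount); if no plane
    reaches 50% intersections an error advises a manual plane.
    """
    if len(bundle) == 0:
        raise StructuralError("empty bundle")
    tangents = _mid_tangents(bundle)
    ref = tangents[0]
    aligned = np.where((tangents @ ref)[:, np.newaxis] < 0, -tangents,
                       tangents)
    normal = aligned.mean(axis=0)
    normal /= np.linalg.norm(normal)
    centroid = bundle.all_points().mean(axis=0)
    plane = OriginPlane(centroid, normal)
    if _count_intersections(bundle, plane) == len(bundle):
        return plane
    best, best_n = plane, _count_intersections(bundle, plane)
    for f in bundle.fibers:
        seg = segment_lengths(f)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        j = int(np.searchsorted(cum, cum[-1] / 2.0, side="right") - 1)
        cand = OriginPlane(f[min(j, len(f) - 1)], normal)
        n = _count_intersections(bundle, cand)
        if n > best_n:
            best, best_n = cand, n
    if best_n <= 0.5 * len(bundle):
        raise StructuralError(
            f"no origin plane intersects more than half the fibers (best "
            f"{best_n}/{len(bundle)}); set the plane manually")
    return best


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

def parameterize(bundle: FiberBundle, plane: OriginPlane) -> FiberBundle:
    """Signed-arclength parameterization from the plane intersection.

    Each retained fiber gets a ``FiberLocationIndex`` point-data array: the
    cumulative arclength from the interpolated plane-intersection point,
    signed by the side of the plane, with fibers oriented so the positive
    side is consistent bundle-wide. Fibers crossing the plane more than once
    use the crossing nearest their mid-arclength; fibers that never cross
    (or lie in the plane) are excluded and reported in
    ``metadata['excluded_fibers']``.
    """
    keep_idx: List[int] = []
    loc_arrays: List[np.ndarray] = []
    orientations: List[int] = []
    excluded: List[int] = []
    n_multi = 0
    for i, f in enumerate(bundle.fibers):
        h = plane.signed_distance(f)
        seg = segment_lengths(f)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if np.all(np.abs(h) < 1e-12):
            excluded.append(i)
            continue
        cross = np.flatnonzero(np.signbit(h[:-1]) != np.signbit(h[1:]))
        cross = [j for j in cross if h[j] != h[j + 1]]
        if not cross:
            excluded.append(i)
            continue
        if len(cross) > 1:
            n_multi += 1
            mid = cum[-1] / 2.0
            cross = sorted(
                cross, key=lambda j: abs(
                    cum[j] + abs(h[j] / (h[j] - h[j + 1])) * seg[j] - mid))
        j = cross[0]
        t = h[j] / (h[j] - h[j + 1])
        s_zero = cum[j] + t * seg[j]
        s = cum - s_zero
        # orient so that points on the positive side of the normal carry
        # positive arclength; the sign of the h-change at the crossing is
        # robust even when a sample sits exactly on the plane
        orient = 1 if h[j + 1] > h[j] else -1
        s = s * orient
        keep_idx.append(i)
        loc_arrays.append(s)
        orientations.append(orient)
    if not keep_idx:
        raise StructuralError("no fiber intersects the origin plane")
    out = bundle.select(keep_idx)
    out.set_point_data(LOCATION_INDEX, loc_arrays)
    out.metadata["excluded_fibers"] = excluded
    out.metadata["n_multi_crossing"] = n_multi
    out.metadata["orientations"] = orientations
    out.metadata["plane_point"] = plane.point.tolist()
    out.metadata["plane_normal"] = plane.normal.tolist()
    return out


def deform_fibers_to_subject(pb: FiberBundle, fld: DisplacementField
                             ) -> FiberBundle:
    """Map parameterized fibers into subject space; arclengths are copied.

    Points outside the field grid are extrapolated by the nearest-edge
    displacement; their count lands in ``metadata['n_outside_field']``.
    """
    if LOCATION_INDEX not in pb.point_data:
        raise StructuralError("bundle is not parameterized")
    out_fibers = []
    n_outside = 0
    for f in pb.fibers:
        idx = fld.world_to_index(f)
        outside = np.any((idx < 0) | (idx > np.array(fld.shape) - 1), axis=1)
        n_outside += int(outside.sum())
        out_fibers.append(fld.map_points(f))
    out = FiberBundle(out_fibers,
                      {k: [a.copy() for a in v]
                       for k, v in pb.point_data.items()},
                      dict(pb.metadata))
    out.metadata["n_outside_field"] = n_outside
    return out


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """One subject's along-tract profiles on a common arclength grid."""

    label: str
    grid: np.ndarray                      # uniform arclength grid, mm
    values: Dict[str, np.ndarray]         # property -> per-bin weighted mean
    weight_mass: np.ndarray               # per-bin total kernel weight
    missing: np.ndarray = dc_field(default=None)  # per-bin missing flag

    def __post_init__(self):
        if self.missing is None:
            self.missing = self.weight_mass < 1e-6


def profile_grid(pb: FiberBundle, step_mm: float = 1.0) -> np.ndarray:
    """Uniform grid between the 2nd and 98th percentile of arclengths."""
    arcs = np.concatenate(pb.point_data[LOCATION_INDEX])
    lo, hi = np.percentile(arcs, [2, 98])
    start = np.ceil(lo / step_mm) * step_mm
    return np.arange(start, hi + 1e-9, step_mm)


def extract_profiles(pb_subject: FiberBundle, subject_dti: TensorVolume,
                     properties: Sequence[str] = ("fa",),
                     grid: Optional[np.ndarray] = None,
                     grid_step_mm: float = 1.0,
                     kernel_sigma_mm: Optional[float] = None,
                     label: str = "subject") -> SubjectProfile:
    """Gaussian-weighted along-tract profiles for one subject.

    Every fiber point contributes its trilinearly sampled property value to
    each grid bin with weight ``exp(-(s - s_bin)^2 / (2 sigma^2))``; a bin's
    value is the weighted mean and bins with negligible total weight are
    flagged missing. Scalar maps are computed on ``subject_dti`` directly.
    """
    for p in properties:
        if p.lower() not in SCALAR_PROPERTIES:
            raise ValueError(f"unknown property {p!r}; valid: "
                             f"{', '.join(SCALAR_PROPERTIES)}")
    if LOCATION_INDEX not in pb_subject.point_data:
        raise StructuralError("bundle is not parameterized")
    if grid is None:
        grid = profile_grid(pb_subject, grid_step_mm)
    sigma = kernel_sigma_mm if kernel_sigma_mm is not None else \
        float(np.median(np.diff(grid))) if len(grid) > 1 else grid_step_mm

    pts = pb_subject.all_points()
    arcs = np.concatenate(pb_subject.point_data[LOCATION_INDEX])
    idx = subject_dti.world_to_index(pts)
    w = np.exp(-(arcs[:, np.newaxis] - grid[np.newaxis, :]) ** 2
               / (2 * sigma ** 2))                       # (points, bins)
    mass = w.sum(axis=0)
    values = {}
    for p in properties:
        smap = scalar_map(subject_dti, p)
        v = sample_trilinear(smap.data, idx, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            prof = (w * v[:, np.newaxis]).sum(axis=0) / mass
        values[p.lower()] = prof
    return SubjectProfile(label=label, grid=grid.copy(), values=values,
                          weight_mass=mass)


def assemble_cohort_profiles(rows: Sequence[SubjectProfile],
                             covariates: pd.DataFrame,
                             atlas_row: Optional[SubjectProfile] = None
                             ) -> Dict[str, pd.DataFrame]:
    """Align per-subject profiles into per-property arclength-first tables.

    Every subject label must appear in the covariate table (an error lists
    unmatched labels); the atlas's own profile, when given, is appended as a
    reference column named ``atlas``.
    """
    if not rows:
        raise StructuralError("no subject profiles given")
    grid = rows[0].grid
    for r in rows[1:]:
        if len(r.grid) != len(grid) or not np.allclose(r.grid, grid):
            raise StructuralError("subject profiles use different grids")
    missing = [r.label for r in rows if r.label not in covariates.index]
    if missing:
        raise StructuralError(
            f"labels missing from covariate table: {missing}")
    properties = rows[0].values.keys()
    out = {}
    for p in properties:
        data = {"arclength": grid}
        for r in rows:
            vals = r.values[p].copy()
            vals[r.missing] = np.nan
            data[r.label] = vals
        if atlas_row is not None:
            data["atlas"] = atlas_row.values[p]
        out[p] = pd.DataFrame(data)
    return out
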