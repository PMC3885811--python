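"""Core data containers and spatial helpers shared by every pipeline stage.

World coordinates are RAS millimetres throughout. Voxel indexing is 0-based;
a voxel centre maps to world space via ``origin + direction @ (spacing * index)``.
Diffusion tensors are stored as the 6 unique components ``(xx, xy, xz, yy, yz, zz)``
in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GradientTable",
    "DWIVolume",
    "ScalarVolume",
    "LabelVolume",
    "TensorVolume",
    "DisplacementField",
    "AffineTransform",
    "FiberBundle",
    "tensor6_to_matrix",
    "matrix_to_tensor6",
    "eigensystem_field",
    "sample_trilinear",
]

BASELINE_NORM_TOL = 1e-8
UNIT_NORM_TOL = 1e-3


class FormatError(ValueError):
    """Raised when a file or header violates the expected dialect."""


class StructuralError(ValueError):
    """Raised when a container's internal consistency is violated."""


def _as_float_array(x, shape=None, name="array"):
    a = np.asarray(x, dtype=float)
    if shape is not None and a.shape != shape:
        raise StructuralError(f"{name}: expected shape {shape}, got {a.shape}")
    return a


# ---------------------------------------------------------------------------
# gradient table
# ---------------------------------------------------------------------------

@dataclass
class GradientTable:
    """Diffusion gradient scheme: directions, shared b-value, measurement frame.

    Directions are stored in the measurement frame exactly as read from the
    header; zero vectors mark baseline (b=0) acquisitions. ``measurement_frame``
    is the rotation taking gradient-frame vectors into the world (RAS) frame.
    """

    directions: np.ndarray          # (N, 3), unit norm or exactly zero
    b_value: float                  # s/mm^2
    measurement_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.directions = _as_float_array(self.directions, name="directions")
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise StructuralError("directions must be (N, 3)")
        self.measurement_frame = _as_float_array(
            self.measurement_frame, (3, 3), "measurement_frame")
        self.b_value = float(self.b_value)

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.directions, axis=1)

    @property
    def is_baseline(self) -> np.ndarray:
        """Boolean mask of b=0 (zero-vector) entries."""
        return self.norms < BASELINE_NORM_TOL

    @property
    def n_baselines(self) -> int:
        return int(self.is_baseline.sum())

    def normalized(self) -> "GradientTable":
        """Copy with non-baseline directions rescaled to exact unit norm."""
        d = self.directions.copy()
        nb = ~self.is_baseline
        d[nb] /= np.linalg.norm(d[nb], axis=1, keepdims=True)
        return GradientTable(d, self.b_value, self.measurement_frame.copy())

    def world_directions(self) -> np.ndarray:
        """Directions rotated into the world frame by the measurement frame."""
        return self.directions @ self.measurement_frame.T

    def validate(self) -> None:
        nb = ~self.is_baseline
        bad = np.abs(self.norms[nb] - 1.0) > UNIT_NORM_TOL
        if bad.any():
            idx = np.flatnonzero(nb)[bad]
            raise StructuralError(
                f"non-unit gradient direction(s) at index {idx.tolist()}")
        det = np.linalg.det(self.measurement_frame)
        if abs(abs(det) - 1.0) > 1e-6:
            raise StructuralError(
                f"measurement_frame determinant {det:.6g} is not +-1")

    def subset(self, keep: np.ndarray) -> "GradientTable":
        return GradientTable(self.directions[keep], self.b_value,
                             self.measurement_frame.copy())


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

class _Spatial:
    """Mixin providing index<->world mapping from (spacing, origin, direction)."""

    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def _init_spatial(self, spacing, origin, direction):
        self.spacing = _as_float_array(spacing, (3,), "spacing")
        if (self.spacing <= 0).any():
            raise StructuralError("spacing must be strictly positive")
        self.origin = _as_float_array(origin, (3,), "origin")
        self.direction = _as_float_array(direction, (3, 3), "direction")

    @property
    def index_to_world_matrix(self) -> np.ndarray:
        """3x3 matrix A with world = A @ index + origin."""
        return self.direction * self.spacing[np.newaxis, :]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.index_to_world_matrix.T + self.origin

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.index_to_world_matrix)
        return (world - self.origin) @ inv.T

    def spatial_kwargs(self) -> dict:
        return dict(spacing=self.spacing.copy(), origin=self.origin.copy(),
                    direction=self.direction.copy())

    def same_grid_as(self, other: "_Spatial", atol=1e-9) -> bool:
        return (np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.direction, other.direction, atol=atol))


class DWIVolume(_Spatial):
    """4D diffusion-weighted signal grid plus its gradient table."""

    def __init__(self, data, gradients: GradientTable,
                 spacing=(1, 1, 1), origin=(0, 0, 0), direction=np.eye(3)):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 4:
            raise StructuralError("DWI data must be 4D (x, y, z, gradient)")
        if (self.data < 0).any():
            raise StructuralError("DWI signal must be non-negative")
        if self.data.shape[3] != len(gradients):
            raise StructuralError(
                f"gradient axis length {self.data.shape[3]} != table length "
                f"{len(gradients)}")
        self.gradients = gradients
        self._init_spatial(spacing, origin, direction)
        self.metadata: dict = {}

    @property
    def shape(self):
        return self.data.shape

    def copy(self) -> "DWIVolume":
        return DWIVolume(self.data.copy(),
                         GradientTable(self.gradients.directions.copy(),
                                       self.gradients.b_value,
                                       self.gradients.measurement_frame.copy()),
                         **self.spatial_kwargs())


class ScalarVolume(_Spatial):
    """3D scalar image (e.g., an FA map)."""

    def __init__(self, data, spacing=(1, 1, 1), origin=(0, 0, 0),
                 direction=np.eye(3)):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 3:
            raise StructuralError("scalar data must be 3D")
        self._init_spatial(spacing, origin, direction)

    @property
    def shape(self):
        return self.data.shape

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), **self.spatial_kwargs())


class LabelVolume(_Spatial):
    """3D integer label map."""

    def __init__(self, data, spacing=(1, 1, 1), origin=(0, 0, 0),
                 direction=np.eye(3)):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise StructuralError("label values must be whole numbers")
            arr = np.round(arr).astype(np.int32)
        if (arr < 0).any():
            raise StructuralError("label values must be non-negative")
        self.data = arr
        if self.data.ndim != 3:
            raise StructuralError("label data must be 3D")
        self._init_spatial(spacing, origin, direction)

    @property
    def shape(self):
        return self.data.shape


class TensorVolume(_Spatial):
    """Per-voxel symmetric diffusion tensors, 6-component storage.

    ``tensors`` has shape (x, y, z, 6) ordered (xx, xy, xz, yy, yz, zz);
    ``mask`` marks voxels where the tensor is valid.
    """

    def __init__(self, tensors, spacing=(1, 1, 1), origin=(0, 0, 0),
                 direction=np.eye(3), mask: Optional[np.ndarray] = None):
        self.tensors = np.asarray(tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[3] != 6:
            raise StructuralError("tensors must be (x, y, z, 6)")
        self._init_spatial(spacing, origin, direction)
        if mask is None:
            mask = np.ones(self.tensors.shape[:3], dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.tensors.shape[:3]:
            raise StructuralError("mask shape mismatch")
        self.metadata: dict = {}

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        return tensor6_to_matrix(self.tensors)

    def copy(self) -> "TensorVolume":
        return TensorVolume(self.tensors.copy(), mask=self.mask.copy(),
                            **self.spatial_kwargs())


class DisplacementField(_Spatial):
    """Dense pull-back displacement field on the atlas grid.

    For an atlas voxel with world position x, the mapped subject-space
    position is ``x + field[idx]`` (field entries are millimetre offsets).
    """

    def __init__(self, field_mm, spacing=(1, 1, 1), origin=(0, 0, 0),
                 direction=np.eye(3)):
        self.field = np.asarray(field_mm, dtype=float)
        if self.field.ndim != 4 or self.field.shape[3] != 3:
            raise StructuralError("displacement field must be (x, y, z, 3)")
        if not np.isfinite(self.field).all():
            raise StructuralError("displacement field contains non-finite values")
        self._init_spatial(spacing, origin, direction)

    @property
    def shape(self):
        return self.field.shape[:3]

    @classmethod
    def identity_like(cls, vol: _Spatial, shape=None) -> "DisplacementField":
        shape = shape if shape is not None else vol.data.shape[:3] \
            if hasattr(vol, "data") else vol.shape
        return cls(np.zeros(tuple(shape) + (3,)), **vol.spatial_kwargs())

    def displacement_at(self, world_points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement (mm) at world points."""
        pts = np.atleast_2d(np.asarray(world_points, dtype=float))
        idx = self.world_to_index(pts)
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = map_coordinates(self.field[..., c], idx.T, order=1,
                                        mode="nearest")
        return out

    def map_points(self, world_points: np.ndarray) -> np.ndarray:
        """Map atlas-space world points into subject space."""
        pts = np.atleast_2d(np.asarray(world_points, dtype=float))
        return pts + self.displacement_at(pts)

    def jacobian_determinants(self) -> np.ndarray:
        """det of d(mapped)/d(index-space position) rescaled to world units."""
        A = self.index_to_world_matrix
        grads = np.stack(
            [np.stack(np.gradient(self.field[..., c]), axis=-1)
             for c in range(3)], axis=-2)          # (..., 3 comp, 3 d/dindex)
        # d(mapped)/d(world) = I + d(disp)/d(index) @ A^-1
        J = np.eye(3) + grads @ np.linalg.inv(A)
        return np.linalg.det(J)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.field.copy(), **self.spatial_kwargs())


@dataclass
class AffineTransform:
    """12-parameter affine, world mm, mapping subject coords -> atlas coords."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.linear = _as_float_array(self.linear, (3, 3), "linear")
        self.translation = _as_float_array(self.translation, (3,), "translation")
        if abs(np.linalg.det(self.linear)) <= 1e-8:
            raise StructuralError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform(self.linear @ other.linear,
                               self.linear @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# fiber bundles
# ---------------------------------------------------------------------------

class FiberBundle:
    """Ordered 3D polylines in world mm with named per-point scalar arrays."""

    def __init__(self, fibers: List[np.ndarray],
                 point_data: Optional[Dict[str, List[np.ndarray]]] = None,
                 metadata: Optional[dict] = None):
        self.fibers = [np.asarray(f, dtype=float) for f in fibers]
        for i, f in enumerate(self.fibers):
            if f.ndim != 2 or f.shape[1] != 3:
                raise StructuralError(f"fiber {i} is not an (n, 3) polyline")
            if len(f) < 2:
                raise StructuralError(f"fiber {i} has fewer than 2 points")
        self.point_data = {}
        if point_data:
            for name, arrays in point_data.items():
                self.set_point_data(name, arrays)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.fibers)

    @property
    def n_points(self) -> int:
        return sum(len(f) for f in self.fibers)

    def set_point_data(self, name: str, arrays: List[np.ndarray]) -> None:
        arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
        if len(arrays) != len(self.fibers):
            raise StructuralError(
                f"point_data '{name}': {len(arrays)} arrays for "
                f"{len(self.fibers)} fibers")
        for i, (a, f) in enumerate(zip(arrays, self.fibers)):
            if len(a) != len(f):
                raise StructuralError(
                    f"point_data '{name}': fiber {i} has {len(f)} points "
                    f"but {len(a)} values")
        self.point_data[name] = arrays

    def select(self, keep_indices) -> "FiberBundle":
        keep_indices = list(keep_indices)
        fibers = [self.fibers[i] for i in keep_indices]
        pd = {name: [arrays[i] for i in keep_indices]
              for name, arrays in self.point_data.items()}
        if not fibers:
            return _EmptyBundle(pd.keys(), self.metadata)
        return FiberBundle(fibers, pd, self.metadata)

    def fiber_lengths(self) -> np.ndarray:
        """Arclength (mm) of each fiber."""
        return np.array([segment_lengths(f).sum() for f in self.fibers])

    def all_points(self) -> np.ndarray:
        if not self.fibers:
            return np.zeros((0, 3))
        return np.concatenate(self.fibers, axis=0)

    def copy(self) -> "FiberBundle":
        return FiberBundle([f.copy() for f in self.fibers],
                           {k: [a.copy() for a in v]
                            for k, v in self.point_data.items()},
                           dict(self.metadata))


class _EmptyBundle(FiberBundle):
    """Zero-fiber bundle (legal result of filtering operations)."""

    def __init__(self, data_names=(), metadata=None):
        self.fibers = []
        self.point_data = {name: [] for name in data_names}
        self.metadata = dict(metadata or {})


def empty_bundle(like: Optional[FiberBundle] = None) -> FiberBundle:
    names = like.point_data.keys() if like is not None else ()
    meta = like.metadata if like is not None else None
    return _EmptyBundle(names, meta)


def segment_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


# ---------------------------------------------------------------------------
# tensor component packing and eigensystems
# ---------------------------------------------------------------------------

_T6_ROWS = np.array([0, 0, 0, 1, 1, 2])
_T6_COLS = np.array([0, 1, 2, 1, 2, 2])


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    """(..., 6) components (xx,xy,xz,yy,yz,zz) -> (..., 3, 3) symmetric."""
    t6 = np.asarray(t6, dtype=float)
    out = np.empty(t6.shape[:-1] + (3, 3))
    out[..., _T6_ROWS, _T6_COLS] = t6
    out[..., _T6_COLS, _T6_ROWS] = t6
    return out


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric -> (..., 6) components."""
    m = np.asarray(m, dtype=float)
    return m[..., _T6_ROWS, _T6_COLS]


def eigensystem_field(t6: np.ndarray):
    """Sorted, canonicalized eigensystem of a field of symmetric tensors.

    Returns (eigenvalues, eigenvectors): eigenvalues (..., 3) descending;
    eigenvectors (..., 3, 3) with vectors in ROWS (vecs[..., 0, :] is e1),
    sign-fixed so each vector's first component of magnitude > 1e-12 is
    positive, and the triple is right-handed (e3 = e1 x e2).
    """
    m = tensor6_to_matrix(t6) if t6.shape[-1] == 6 else np.asarray(t6)
    vals, vecs = np.linalg.eigh(m)                 # ascending, columns
    vals = vals[..., ::-1]
    vecs = vecs[..., :, ::-1]                      # columns reordered
    vecs = np.swapaxes(vecs, -1, -2)               # rows are eigenvectors
    vecs = _canonical_signs(vecs)
    e3 = np.cross(vecs[..., 0, :], vecs[..., 1, :])
    vecs = np.concatenate([vecs[..., :2, :], e3[..., np.newaxis, :]], axis=-2)
    return vals, vecs


def _canonical_signs(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each eigenvector so its first non-negligible component is > 0."""
    out = vecs.copy()
    for k in range(vecs.shape[-2]):
        v = out[..., k, :]
        sign = np.zeros(v.shape[:-1])
        for c in range(3):
            comp = v[..., c]
            undecided = sign == 0
            big = np.abs(comp) > tol
            sign = np.where(undecided & big, np.sign(comp), sign)
        sign = np.where(sign == 0, 1.0, sign)
        out[..., k, :] = v * sign[..., np.newaxis]
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_trilinear(data: np.ndarray, index_points: np.ndarray,
                     mode: str = "nearest", cval: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of a 3D (or 3D+channels) array at index-space points."""
    pts = np.atleast_2d(np.asarray(index_points, dtype=float))
    if data.ndim == 3:
        return map_coordinates(data, pts.T, order=1, mode=mode, cval=cval)
    out = np.empty((len(pts), data.shape[3]))
    for c in range(data.shape[3]):
        out[:, c] = map_coordinates(data[..., c], pts.T, order=1, mode=mode,
                                    cval=cval)
    return out
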