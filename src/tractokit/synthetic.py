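"""Synthetic phantoms, simulated DWI and multi-subject cohorts.

Everything the test battery consumes is generated here with explicit seeds:
analytic tensor-field phantoms (straight / arc / crossing bundles), the
monoexponential DWI signal with Rician noise, injected slice and
directional-bias artifacts with exact ground truth, and cohorts of warped
phantoms whose along-tract FA carries known covariate effects.

All generators are bit-reproducible given (spec, seed). Warps are smooth
Gaussian random displacement fields whose Jacobian determinant is verified
positive everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (DWIVolume, DisplacementField, GradientTable, StructuralError,
                   TensorVolume, matrix_to_tensor6)
from .tensor import le_resample

DEFAULT_EIGENVALUES_INSIDE = (1.7e-3, 0.3e-3, 0.3e-3)
DEFAULT_EIGENVALUES_BACKGROUND = (0.7e-3, 0.7e-3, 0.7e-3)


# ---------------------------------------------------------------------------
# gradient schemes
# ---------------------------------------------------------------------------

def default_gradient_table(n_directions: int = 6, b_value: float = 1000.0,
                           n_baselines: int = 1,
                           measurement_frame: Optional[np.ndarray] = None
                           ) -> GradientTable:
    """Baseline(s) followed by a well-spread direction scheme.

    For n=6 the classic icosahedral DTI scheme is used; larger schemes are
    spread by a deterministic Fibonacci hemisphere sampling.
    """
    if n_directions == 6:
        phi = (1 + np.sqrt(5)) / 2
        dirs = np.array([[1, phi, 0], [-1, phi, 0], [0, 1, phi],
                         [0, -1, phi], [phi, 0, 1], [-phi, 0, 1]], dtype=float)
    else:
        i = np.arange(n_directions) + 0.5
        theta = np.arccos(i / n_directions)          # hemisphere
        golden = np.pi * (3 - np.sqrt(5))
        az = golden * np.arange(n_directions)
        dirs = np.stack([np.sin(theta) * np.cos(az),
                         np.sin(theta) * np.sin(az),
                         np.cos(theta)], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    directions = np.vstack([np.zeros((n_baselines, 3)), dirs])
    mf = np.eye(3) if measurement_frame is None else measurement_frame
    return GradientTable(directions, b_value, mf)


# ---------------------------------------------------------------------------
# tensor phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and eigenvalues of an analytic tensor-field phantom."""

    shape: Tuple[int, int, int] = (32, 32, 32)
    bundle_geometry: str = "straight"            # straight | arc | crossing
    eigenvalues_inside: Tuple[float, float, float] = DEFAULT_EIGENVALUES_INSIDE
    eigenvalues_background: Tuple[float, float, float] = \
        DEFAULT_EIGENVALUES_BACKGROUND
    bundle_radius_vox: float = 3.0
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("eigenvalues_inside", "eigenvalues_background"):
            ev = np.asarray(getattr(self, name), dtype=float)
            if (ev <= 0).any():
                raise StructuralError(f"{name} must be positive")
            if not np.all(np.diff(ev) <= 0):
                raise StructuralError(f"{name} must be sorted descending")


def _tensor_from_tangent(tangent: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially symmetric tensor whose principal axis follows the tangent."""
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    # stable orthonormal complement
    helper = np.where(np.abs(t[..., [0]]) < 0.9,
                      np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
    n1 = np.cross(t, helper)
    n1 /= np.linalg.norm(n1, axis=-1, keepdims=True)
    n2 = np.cross(t, n1)
    l1, l2, l3 = eigenvalues
    mats = (l1 * t[..., :, np.newaxis] * t[..., np.newaxis, :]
            + l2 * n1[..., :, np.newaxis] * n1[..., np.newaxis, :]
            + l3 * n2[..., :, np.newaxis] * n2[..., np.newaxis, :])
    return matrix_to_tensor6(mats)


def arc_centerline(spec: PhantomSpec, n_samples: int = 200):
    """Analytic centerline and unit tangents of the arc phantom (world mm).

    The arc is a half circle in the x-y plane centred in the grid.
    """
    sx, sy, sz = spec.shape
    spacing = np.asarray(spec.spacing)
    center = np.array([sx / 2.0, sy * 0.25, sz / 2.0]) * spacing
    radius = min(sx, sy) * 0.3 * min(spacing[0], spacing[1])
    theta = np.linspace(np.pi * 0.15, np.pi * 0.85, n_samples)
    pts = center + radius * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    tangents = np.stack([-np.sin(theta), np.cos(theta),
                         np.zeros_like(theta)], axis=1)
    return pts, tangents


def make_tensor_phantom(spec: PhantomSpec) -> TensorVolume:
    """Analytic tensor phantom: bundle with tangent-aligned principal axis.

    Inside the bundle the principal eigenvector follows the bundle tangent;
    the background is isotropic with the background eigenvalues. Voxels of
    crossing-region ambiguity (crossing geometry) take the x-bundle tensor.
    """
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    if spec.bundle_geometry == "crossing" and min(shape) < 16:
        raise StructuralError("crossing geometry needs a grid of at least "
                              "16^3 voxels")
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    world = idx * spacing                       # axis-aligned grid, origin 0
    cx = (np.asarray(shape) / 2.0) * spacing

    tensors = np.zeros(shape + (6,))
    l_bg = spec.eigenvalues_background
    tensors[..., 0] = l_bg[0]
    tensors[..., 3] = l_bg[1]
    tensors[..., 5] = l_bg[2]
    r_mm = spec.bundle_radius_vox * spacing.min()

    if spec.bundle_geometry in ("straight", "crossing"):
        dy = world[..., 1] - cx[1]
        dz = world[..., 2] - cx[2]
        in_x = dy ** 2 + dz ** 2 <= r_mm ** 2
        tensors[in_x] = _tensor_from_tangent(np.array([1.0, 0, 0]),
                                             spec.eigenvalues_inside)
        if spec.bundle_geometry == "crossing":
            dx = world[..., 0] - cx[0]
            in_y = dx ** 2 + dz ** 2 <= r_mm ** 2
            only_y = in_y & ~in_x
            tensors[only_y] = _tensor_from_tangent(np.array([0, 1.0, 0]),
                                                   spec.eigenvalues_inside)
    elif spec.bundle_geometry == "arc":
        pts, tangents = arc_centerline(spec, n_samples=400)
        flat_world = world.reshape(-1, 3)
        d2 = ((flat_world[:, np.newaxis, :] - pts[np.newaxis, :, :]) ** 2
              ).sum(axis=2)
        nearest = d2.argmin(axis=1)
        # drop voxels nearest the arc ends: otherwise the tube grows straight
        # stubs beyond the arc (end tangents assigned radially outward)
        interior = (nearest > 2) & (nearest < len(pts) - 3)
        inside = (d2[np.arange(len(flat_world)), nearest] <= r_mm ** 2) \
            & interior
        t6 = _tensor_from_tangent(tangents[nearest[inside]],
                                  spec.eigenvalues_inside)
        flat = tensors.reshape(-1, 6)
        flat[inside] = t6
        tensors = flat.reshape(shape + (6,))
    else:
        raise ValueError(f"unknown bundle geometry {spec.bundle_geometry!r}")

    return TensorVolume(tensors, spacing=spacing, origin=np.zeros(3),
                        direction=np.eye(3))


def modulated_bundle_mask(shape, radius_vox: float, modulation: float = 0.3,
                          period_mm: float = 16.0,
                          spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """In-bundle mask of a straight bundle whose radius tapers and bulges.

    ``r(x) = radius * (1 + modulation * cos(2 pi (x - cx) / period))`` —
    fiber bundles are not uniform cylinders, and the varying outline anchors
    registration along the bundle axis.
    """
    shape = tuple(shape)
    spacing = np.asarray(spacing, dtype=float)
    cx = (np.asarray(shape) / 2.0) * spacing
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    world = idx * spacing
    x = world[..., 0] - cx[0]
    r = radius_vox * spacing.min() * (
        1.0 + modulation * np.cos(2 * np.pi * x / period_mm))
    dy = world[..., 1] - cx[1]
    dz = world[..., 2] - cx[2]
    return dy ** 2 + dz ** 2 <= r ** 2


def straight_bundle_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean in-bundle mask of the straight phantom (for oracles)."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    cx = (np.asarray(shape) / 2.0) * spacing
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    world = idx * spacing
    r_mm = spec.bundle_radius_vox * spacing.min()
    dy = world[..., 1] - cx[1]
    dz = world[..., 2] - cx[2]
    return dy ** 2 + dz ** 2 <= r_mm ** 2


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def textured_s0(shape, base: float = 1000.0, amplitude: float = 0.3,
                smooth_sigma_vox: float = 2.0, seed: int = 0) -> np.ndarray:
    """Smooth random proton-density texture (tissue has spatial structure).

    Returns a strictly positive S0 field ``base * (1 + amplitude * field)``
    with the field Gaussian-smoothed and scaled to unit peak magnitude.
    """
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.normal(0, 1, tuple(shape)), smooth_sigma_vox)
    peak = np.abs(raw).max()
    if peak > 0:
        raw /= peak
    return base * (1.0 + amplitude * raw)


def textured_scalar_volume(shape, seed: int = 0, smooth_sigma_vox: float = 2.0,
                           spacing=(1.0, 1.0, 1.0)):
    """Smooth random scalar image in [0, 1] with structure in every direction.

    Registration test target: unlike the straight-bundle phantom (whose FA is
    invariant to translations along the bundle axis) this image constrains
    all transform parameters.
    """
    from .core import ScalarVolume
    rng = np.random.default_rng(seed)
    data = gaussian_filter(rng.normal(0, 1, tuple(shape)), smooth_sigma_vox)
    data -= data.min()
    if data.max() > 0:
        data /= data.max()
    # soft spherical apodization keeps mass away from the boundary
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    r = np.linalg.norm((idx - c) / c, axis=-1)
    data *= np.clip((0.85 - r) / 0.25, 0, 1)      # exactly zero near boundary
    return ScalarVolume(data, spacing=spacing)


def simulate_dwi(tensors: TensorVolume, gradients: GradientTable,
                 s0=1000.0, noise_sd: float = 0.0,
                 seed: int = 0) -> DWIVolume:
    """Monoexponential DWI signal S = S0 exp(-b g^T D g), with Rician noise.

    ``s0`` may be a scalar or a per-voxel array (see :func:`textured_s0`).
    Rician noise adds two independent Gaussian channels of width ``noise_sd``
    and takes the magnitude; ``noise_sd = 0`` returns the exact model signal.
    """
    s0 = np.asarray(s0, dtype=float)
    if (s0 <= 0).any():
        raise StructuralError("s0 must be positive")
    gradients.validate()
    g = gradients.world_directions()
    b = gradients.b_value
    D = tensors.as_matrices()                         # (x,y,z,3,3)
    adc = np.einsum("gi,...ij,gj->...g", g, D, g)     # (x,y,z,G)
    s0v = s0 if s0.ndim == 0 else s0[..., np.newaxis]
    signal = s0v * np.exp(-b * adc)
    bl = gradients.is_baseline
    signal[..., bl] = (s0 * np.ones(tensors.shape))[..., np.newaxis]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0, noise_sd, signal.shape)
        n2 = rng.normal(0, noise_sd, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return DWIVolume(signal, gradients, **tensors.spatial_kwargs())


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifact(dwi: DWIVolume, kind: str, params: dict,
                    seed: int = 0) -> Tuple[DWIVolume, List[Tuple[int, int]]]:
    """Corrupt a DWI and return exact ground truth of (gradient, slice) pairs.

    kinds: ``zero_slice`` (params: gradient, slice), ``attenuated_slice``
    (params: gradient, slice, factor), ``direction_bias`` (params: axis,
    strength) which multiplies the signal of axis-aligned gradients so the
    estimated principal-direction field skews toward the axis.
    """
    out = dwi.copy()
    n_slices = out.data.shape[2]
    truth: List[Tuple[int, int]] = []
    if kind in ("zero_slice", "attenuated_slice"):
        grads = np.atleast_1d(params["gradient"])
        slices = np.atleast_1d(params["slice"])
        factor = 0.0 if kind == "zero_slice" else float(params["factor"])
        for gi in grads:
            for sl in slices:
                if not (0 <= sl < n_slices):
                    raise IndexError(f"slice {sl} out of range 0..{n_slices-1}")
                out.data[:, :, sl, gi] *= factor
                truth.append((int(gi), int(sl)))
    elif kind == "direction_bias":
        axis = np.asarray(params["axis"], dtype=float)
        axis /= np.linalg.norm(axis)
        strength = float(params.get("strength", 0.5))
        g = out.gradients.world_directions()
        align = (g @ axis) ** 2
        nb = ~out.gradients.is_baseline
        scale = np.where(nb, 1.0 - strength * align, 1.0)
        out.data *= scale[np.newaxis, np.newaxis, np.newaxis, :]
        biased = np.flatnonzero(nb & (align > 0.5))
        truth = [(int(gi), sl) for gi in biased for sl in range(n_slices)]
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return out, truth


# ---------------------------------------------------------------------------
# random smooth warps
# ---------------------------------------------------------------------------

def random_smooth_field(shape, magnitude_mm: float, seed: int,
                        smooth_sigma_vox: float = 4.0,
                        spacing=(1.0, 1.0, 1.0),
                        origin=(0.0, 0.0, 0.0)) -> DisplacementField:
    """Gaussian-smoothed random displacement field scaled to a peak magnitude.

    Raises if the resulting mapping's Jacobian determinant is not strictly
    positive everywhere (non-diffeomorphic request).
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(0, 1, tuple(shape) + (3,))
    for c in range(3):
        raw[..., c] = gaussian_filter(raw[..., c], smooth_sigma_vox)
    peak = np.linalg.norm(raw, axis=-1).max()
    if peak > 0:
        raw *= magnitude_mm / peak
    fld = DisplacementField(raw, spacing=spacing, origin=origin)
    jmin = fld.jacobian_determinants().min()
    if jmin <= 0:
        raise StructuralError(
            f"warp magnitude {magnitude_mm} mm is not diffeomorphic on this "
            f"grid (min Jacobian {jmin:.4f})")
    return fld


def invert_displacement_field(fld: DisplacementField,
                              n_iter: int = 20) -> DisplacementField:
    """Fixed-point inverse: psi(x) = -phi(x + psi(x)), iterated on the grid."""
    shape = fld.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = fld.index_to_world(idx)
    psi = np.zeros_like(world)
    for _ in range(n_iter):
        psi = -fld.displacement_at(world + psi)
    return DisplacementField(psi.reshape(tuple(shape) + (3,)),
                             **fld.spatial_kwargs())


# ---------------------------------------------------------------------------
# cohorts with known effects
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort of warped bundle phantoms.

    Defaults mirror a small infant DTI study: eight subjects with age in
    weeks spread over 11.8-14.5, mild FA profile noise and ~2 mm anatomical
    variability.
    """

    n_subjects: int = 8
    covariates: Optional[pd.DataFrame] = None     # default: 'age' in weeks
    beta_functions: Optional[Dict[str, Callable[[np.ndarray], np.ndarray]]] = None
    noise_sd: float = 0.02                        # FA units per arclength bin
    warp_magnitude: float = 2.0                   # mm
    shape: Tuple[int, int, int] = (40, 24, 24)
    bundle_radius_vox: float = 3.0
    md: float = 0.9e-3                            # mean diffusivity, mm^2/s
    n_landmarks: int = 6                          # anisotropic anchor blobs
    radius_modulation: float = 0.3                # bundle taper/bulge amplitude
    radius_period_mm: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise StructuralError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise StructuralError("noise_sd must be >= 0")


@dataclass
class Cohort:
    """Generated cohort: subject volumes, true warps and analytic profiles."""

    phantom: TensorVolume                 # atlas-space base phantom
    subjects: List[TensorVolume]          # subject-space tensor volumes
    fields: List[DisplacementField]       # atlas -> subject pull-back fields
    covariates: pd.DataFrame              # indexed by subject label
    arclength: np.ndarray                 # profile grid, mm, 0 at bundle centre
    baseline_profile: np.ndarray          # FA(s) common baseline
    beta_profiles: Dict[str, np.ndarray]  # per-covariate effect curves
    true_profiles: np.ndarray             # (n_subjects, n_s) noise-free FA
    noisy_profiles: np.ndarray            # (n_subjects, n_s) with profile noise
    bundle_mask: np.ndarray               # in-bundle voxels of the phantom
    clipped_fraction: float = 0.0         # profile mass lost to the FA ceiling


def default_baseline_profile(s: np.ndarray) -> np.ndarray:
    """Smooth FA baseline: mid-tract peak falling off toward the ends."""
    return 0.45 + 0.2 * np.exp(-(s / 12.0) ** 2)


def eigenvalues_for_fa(fa: np.ndarray, md: float) -> np.ndarray:
    """Axially symmetric eigenvalue triples (a, b, b) with given FA and MD."""
    fa = np.clip(np.asarray(fa, dtype=float), 0.0, 0.99)
    x = fa / np.sqrt(3.0 - 2.0 * fa ** 2)
    a = md * (1 + 2 * x)
    b = md * (1 - x)
    return np.stack([a, b, b], axis=-1)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Build a cohort of warped straight-bundle phantoms with known effects.

    Subject s's true FA profile is ``baseline(s_arc) + sum_k covariate_k(s) *
    beta_k(s_arc)``; its tensor volume is the base phantom with that profile
    baked in along the bundle, resampled through a smooth random warp. The
    returned field per subject is the exact atlas-to-subject mapping used.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    pspec = PhantomSpec(shape=shape, bundle_geometry="straight",
                        bundle_radius_vox=spec.bundle_radius_vox)
    bundle_mask = modulated_bundle_mask(shape, spec.bundle_radius_vox,
                                        spec.radius_modulation,
                                        spec.radius_period_mm)

    if spec.covariates is None:
        labels = [f"s{i + 1:02d}" for i in range(spec.n_subjects)]
        cov = pd.DataFrame(
            {"age": np.round(rng.uniform(11.8, 14.5, spec.n_subjects), 2)},
            index=pd.Index(labels, name="label"))
    else:
        cov = spec.covariates.copy()
        if len(cov) != spec.n_subjects:
            raise StructuralError("covariate table length != n_subjects")

    # fixed anisotropic landmark blobs shared by all subjects: white-matter
    # structures away from the bundle that anchor registration in every
    # direction (a bare straight bundle is translation-degenerate along its
    # own axis)
    landmark_rng = np.random.default_rng(spec.seed + 104729)
    landmarks = []
    r_land = 2.5
    for _ in range(spec.n_landmarks):
        center = landmark_rng.uniform([4, 3, 3],
                                      np.asarray(shape) - [4, 3, 3])
        axis = landmark_rng.normal(0, 1, 3)
        axis /= np.linalg.norm(axis)
        if np.linalg.norm(center[1:] -
                          np.asarray(shape)[1:] / 2.0) < spec.bundle_radius_vox + r_land:
            continue                       # keep clear of the bundle
        landmarks.append((center, axis))
    land_t6 = _tensor_from_tangent(
        np.array([a for _, a in landmarks]) if landmarks else np.zeros((0, 3)),
        eigenvalues_for_fa(0.6, spec.md)[..., :]) if landmarks else None

    x_pos = np.arange(shape[0], dtype=float)       # spacing 1 mm
    s = x_pos - shape[0] / 2.0
    baseline = default_baseline_profile(s)
    betas = {}
    effect = np.zeros((spec.n_subjects, len(s)))
    for name, fn in (spec.beta_functions or {}).items():
        curve = np.asarray(fn(s), dtype=float)
        betas[name] = curve
        effect += cov[name].to_numpy()[:, np.newaxis] * curve[np.newaxis, :]
    unclipped = baseline[np.newaxis, :] + effect
    true_profiles = np.clip(unclipped, 0.05, 0.95)
    clipped_fraction = float((unclipped != true_profiles).mean())
    noise = rng.normal(0, spec.noise_sd, true_profiles.shape) \
        if spec.noise_sd > 0 else np.zeros_like(true_profiles)
    noisy_profiles = np.clip(true_profiles + noise, 0.02, 0.98)

    grid_idx = np.stack(np.meshgrid(*[np.arange(sdim) for sdim in shape],
                                    indexing="ij"), axis=-1)

    def base_volume(profile: np.ndarray) -> TensorVolume:
        """Atlas-space volume with the given FA(x) profile on the bundle."""
        tensors = np.zeros(shape + (6,))
        tensors[..., 0] = DEFAULT_EIGENVALUES_BACKGROUND[0]
        tensors[..., 3] = DEFAULT_EIGENVALUES_BACKGROUND[1]
        tensors[..., 5] = DEFAULT_EIGENVALUES_BACKGROUND[2]
        evs = eigenvalues_for_fa(profile, spec.md)              # (nx, 3)
        for xi in range(shape[0]):
            sl = bundle_mask[xi]
            if sl.any():
                a, b, _ = evs[xi]
                tensors[xi, sl] = [a, 0, 0, b, 0, b]            # e1 along +x
        for (center, _axis), t6 in zip(landmarks, land_t6
                                       if land_t6 is not None else []):
            d2 = ((grid_idx - center) ** 2).sum(axis=-1)
            tensors[(d2 <= r_land ** 2) & ~bundle_mask] = t6
        return TensorVolume(tensors, spacing=pspec.spacing,
                            origin=np.zeros(3), direction=np.eye(3),
                            mask=np.ones(shape, dtype=bool))

    subjects, fields = [], []
    for i in range(spec.n_subjects):
        base = base_volume(noisy_profiles[i])
        if spec.warp_magnitude > 0:
            phi = random_smooth_field(shape, spec.warp_magnitude,
                                      seed=int(rng.integers(0, 2 ** 31 - 1)),
                                      spacing=pspec.spacing)
            psi = invert_displacement_field(phi)
            subj = le_resample(base, psi, reorient=True)
        else:
            phi = DisplacementField(np.zeros(shape + (3,)),
                                    spacing=pspec.spacing)
            subj = base
        subjects.append(subj)
        fields.append(phi)

    phantom = base_volume(baseline)
    return Cohort(phantom=phantom, subjects=subjects, fields=fields,
                  covariates=cov, arclength=s, baseline_profile=baseline,
                  beta_profiles=betas, true_profiles=true_profiles,
                  noisy_profiles=noisy_profiles, bundle_mask=bundle_mask,
                  clipped_fraction=clipped_fraction)


def simulate_profile_cohort(spec: CohortSpec, grid: Optional[np.ndarray] = None):
    """Fast profile-only cohort: (profiles DataFrame, covariates, betas).

    Returns the same statistical generative model as :func:`make_cohort`
    without building volumes — the input format of the stats module.
    """
    rng = np.random.default_rng(spec.seed)
    if grid is None:
        grid = np.arange(-20.0, 20.0 + 1e-9, 1.0)
    if spec.covariates is None:
        labels = [f"s{i + 1:02d}" for i in range(spec.n_subjects)]
        cov = pd.DataFrame(
            {"age": np.round(rng.uniform(11.8, 14.5, spec.n_subjects), 2)},
            index=pd.Index(labels, name="label"))
    else:
        cov = spec.covariates.copy()
    baseline = default_baseline_profile(grid)
    betas = {}
    y = np.tile(baseline, (spec.n_subjects, 1))
    for name, fn in (spec.beta_functions or {}).items():
        curve = np.asarray(fn(grid), dtype=float)
        betas[name] = curve
        y = y + cov[name].to_numpy()[:, np.newaxis] * curve[np.newaxis, :]
    y = y + rng.normal(0, spec.noise_sd, y.shape)
    data = {"arclength": grid}
    for i, label in enumerate(cov.index):
        data[str(label)] = y[i]
    return pd.DataFrame(data), cov, betas
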