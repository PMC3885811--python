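"""Unbiased DTI atlas construction.

Staged pipeline: FA normalization -> affine loop to an initial reference
(template or first subject) -> second affine loop to the affine atlas ->
greedy diffeomorphic averaging -> two-pass demons refinement -> composition
of per-subject Global Displacement Fields (atlas coords -> subject coords)
-> final Log-Euclidean DTI atlas. All registrations run on FA scalar images;
all DTI averaging and resampling is Log-Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import (AffineTransform, DisplacementField, ScalarVolume,
                   StructuralError, TensorVolume)
from .registration import (DemonsParams, affine_register, affine_to_field,
                           compose_fields, greedy_diffeo_register, warp_scalar)
from .tensor import (filter_negative_eigenvalues, le_mean_volumes, le_resample,
                     scalar_map)


# ---------------------------------------------------------------------------
# FA intensity normalization
# ---------------------------------------------------------------------------

def normalize_fa(fa: ScalarVolume, reference: ScalarVolume,
                 n_landmarks: int = 64,
                 foreground_min: float = 0.05) -> ScalarVolume:
    """Histogram quantile normalization of an FA image onto a reference.

    Piecewise-linear mapping between matched foreground quantiles (landmarks
    spread over [0, 1] probability), output clipped to [0, 1]. The foreground
    is FA above a small floor so interpolation halos cannot skew the
    landmark quantiles. A constant input maps to the reference's median.
    """
    fg = fa.data > foreground_min
    ref_fg = reference.data > foreground_min
    if not fg.any():
        fg = fa.data > 0
    if not ref_fg.any():
        ref_fg = reference.data > 0
    if not fg.any() or not ref_fg.any():
        raise StructuralError("normalize_fa: empty foreground mask")
    q = np.linspace(0, 1, n_landmarks)
    src = np.quantile(fa.data[fg], q)
    dst = np.quantile(reference.data[ref_fg], q)
    if src[-1] - src[0] < 1e-12:
        mapped = np.where(fg, np.median(reference.data[ref_fg]), 0.0)
        return ScalarVolume(np.clip(mapped, 0, 1), **fa.spatial_kwargs())
    out = np.interp(fa.data, src, dst)
    out = np.where(fa.data > foreground_min, out, fa.data)
    return ScalarVolume(np.clip(out, 0, 1), **fa.spatial_kwargs())


def fa_sharpness(fa: ScalarVolume) -> float:
    """Mean gradient magnitude of FA over the foreground (atlas crispness)."""
    grads = np.gradient(fa.data, *fa.spacing)
    mag = np.sqrt(sum(g ** 2 for g in grads))
    fg = fa.data > 0.05
    return float(mag[fg].mean()) if fg.any() else 0.0


# ---------------------------------------------------------------------------
# parameters and result containers
# ---------------------------------------------------------------------------

@dataclass
class AtlasParams:
    """Schedules for the staged atlas build."""

    affine_levels: tuple = (4, 2, 1)
    affine_maxiter: int = 40
    greedy: DemonsParams = dc_field(default_factory=lambda: DemonsParams(
        iterations=(20, 10, 5), levels=(4, 2, 1),
        sigma_fluid_vox=1.0, sigma_field_vox=1.0))
    refine: DemonsParams = dc_field(default_factory=lambda: DemonsParams(
        iterations=(15, 10, 10), levels=(4, 2, 1),
        sigma_fluid_vox=1.0, sigma_field_vox=0.7))
    n_greedy_outer: int = 3
    n_landmarks: int = 64


@dataclass
class AtlasResult:
    """All stage outputs of the atlas build."""

    affine_atlas: TensorVolume
    greedy_atlas: TensorVolume
    final_atlas: TensorVolume
    affine_1a: List[AffineTransform]
    affine_1b: List[AffineTransform]
    greedy_fields: List[DisplacementField]
    refine_fields: List[DisplacementField]
    global_fields: List[DisplacementField]
    fa_snapshots: Dict[str, ScalarVolume]

    def sharpness_progression(self) -> Dict[str, float]:
        return {stage: fa_sharpness(self.fa_snapshots[stage])
                for stage in ("affine", "greedy", "final")}


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def compose(field_a: DisplacementField, field_b: DisplacementField
            ) -> DisplacementField:
    """compose(f, g)(x) = g(f(x)) on f's grid (trilinear field interpolation)."""
    return compose_fields(field_a, field_b)


def compose_field_then_affine(fld: DisplacementField,
                              affine_pullback: AffineTransform
                              ) -> DisplacementField:
    """Field mapping x -> affine_pullback(x + fld(x)), on the field's grid."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in fld.shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = fld.index_to_world(idx)
    mapped = affine_pullback.apply(fld.map_points(world))
    disp = (mapped - world).reshape(tuple(fld.shape) + (3,))
    return DisplacementField(disp, **fld.spatial_kwargs())


def apply_global_field(tv: TensorVolume, fld: DisplacementField
                       ) -> TensorVolume:
    """Resample a subject DTI through its global field (Log-Euclidean,
    finite-strain reorientation); out-of-FOV voxels become zero tensors and
    are counted in ``metadata['n_outside']``."""
    return le_resample(tv, fld, reorient=True)


# ---------------------------------------------------------------------------
# staged atlas build
# ---------------------------------------------------------------------------

def _center_affines(transforms: List[AffineTransform]) -> List[AffineTransform]:
    """Compose each subject->atlas affine with the inverse mean transform.

    Keeps the atlas frame the barycentre of the cohort rather than anchored
    to the initial reference (the unbiasedness step of affine atlas loops).
    """
    mean = AffineTransform(np.mean([t.linear for t in transforms], axis=0),
                           np.mean([t.translation for t in transforms],
                                   axis=0))
    inv = mean.inverse()
    return [inv.compose(t) for t in transforms]


def _center_fields(fields: List[DisplacementField]) -> List[DisplacementField]:
    """Subtract the voxelwise mean displacement (unbiased greedy constraint)."""
    mean = np.mean([f.field for f in fields], axis=0)
    return [DisplacementField(f.field - mean, **f.spatial_kwargs())
            for f in fields]


def _stage(stage: str, subject: Optional[int] = None):
    where = f"stage '{stage}'" + (f", subject {subject}" if subject is not None
                                  else "")
    return where


def build_atlas(subjects: Sequence[TensorVolume],
                template_fa: Optional[ScalarVolume] = None,
                params: Optional[AtlasParams] = None) -> AtlasResult:
    """Build an unbiased DTI atlas from filtered subject tensor volumes.

    Stages: (1A) affine to the template (or first subject), average ->
    affine atlas; (1B) affine re-registration to that atlas; (2) greedy
    diffeomorphic averaging of the affinely co-registered FAs; (3, 4) demons
    refinement against the evolving atlas, run twice; finally per-subject
    Global Displacement Fields (atlas -> subject) are composed and the Final
    DTI Atlas is the Log-Euclidean mean of the subjects resampled through
    them.
    """
    if len(subjects) < 2:
        raise StructuralError("atlas building needs >= 2 subjects")
    params = params or AtlasParams()
    subjects = [filter_negative_eigenvalues(tv) for tv in subjects]
    fas = [scalar_map(tv, "fa") for tv in subjects]
    reference = template_fa if template_fa is not None else fas[0]
    norm_fas = [normalize_fa(fa, reference, params.n_landmarks) for fa in fas]
    snapshots: Dict[str, ScalarVolume] = {}

    def _affine_loop(target_fa, stage_name):
        out = []
        for i, nfa in enumerate(norm_fas):
            try:
                out.append(affine_register(nfa, target_fa,
                                           levels=params.affine_levels,
                                           maxiter=params.affine_maxiter))
            except Exception as exc:
                raise RuntimeError(f"{_stage(stage_name, i)} failed: {exc}"
                                   ) from exc
        return out

    # ---- stage 1A: affine to initial reference -----------------------------
    affine_1a = _center_affines(_affine_loop(reference, "affine 1A"))
    warped = [le_resample(subjects[i],
                          affine_to_field(affine_1a[i].inverse().apply,
                                          reference))
              for i in range(len(subjects))]
    atlas_1a = le_mean_volumes(warped)
    fa_1a = scalar_map(atlas_1a, "fa")

    # ---- stage 1B: affine to the affine atlas ------------------------------
    affine_1b = _center_affines(_affine_loop(fa_1a, "affine 1B"))
    affine_fields = [affine_to_field(affine_1b[i].inverse().apply, reference)
                     for i in range(len(subjects))]
    affine_dtis = [le_resample(subjects[i], affine_fields[i])
                   for i in range(len(subjects))]
    affine_atlas = le_mean_volumes(affine_dtis)
    snapshots["affine"] = scalar_map(affine_atlas, "fa")

    # ---- stage 2: greedy diffeomorphic averaging ---------------------------
    affine_fas = [warp_scalar(norm_fas[i], affine_fields[i])
                  for i in range(len(subjects))]
    mean_fa = ScalarVolume(np.mean([f.data for f in affine_fas], axis=0),
                           **reference.spatial_kwargs())
    greedy_fields = [None] * len(subjects)
    for outer in range(params.n_greedy_outer):
        warped_fas = []
        for i, afa in enumerate(affine_fas):
            try:
                greedy_fields[i] = greedy_diffeo_register(afa, mean_fa,
                                                          params.greedy)
            except Exception as exc:
                raise RuntimeError(
                    f"{_stage(f'greedy (outer {outer})', i)} failed: {exc}"
                ) from exc
        greedy_fields = _center_fields(greedy_fields)
        for i, afa in enumerate(affine_fas):
            warped_fas.append(warp_scalar(afa, greedy_fields[i]))
        mean_fa = ScalarVolume(np.mean([f.data for f in warped_fas], axis=0),
                               **reference.spatial_kwargs())
    # one interpolation from the originals: compose greedy field with the
    # affine pull-back before resampling
    greedy_dtis = [
        le_resample(subjects[i],
                    compose_field_then_affine(greedy_fields[i],
                                              affine_1b[i].inverse()))
        for i in range(len(subjects))]
    greedy_atlas = le_mean_volumes(greedy_dtis)
    snapshots["greedy"] = scalar_map(greedy_atlas, "fa")

    # ---- stages 3-4: refinement loops to the evolving final atlas ----------
    greedy_fa = snapshots["greedy"]
    refine_fields = [None] * len(subjects)
    target = greedy_fa
    for pass_name in ("refine A", "refine B"):
        refined_dtis = []
        for i in range(len(subjects)):
            nfa = normalize_fa(affine_fas[i], target, params.n_landmarks)
            try:
                refine_fields[i] = greedy_diffeo_register(nfa, target,
                                                          params.refine)
            except Exception as exc:
                raise RuntimeError(f"{_stage(pass_name, i)} failed: {exc}"
                                   ) from exc
            refined_dtis.append(
                le_resample(subjects[i],
                            compose_field_then_affine(refine_fields[i],
                                                      affine_1b[i].inverse())))
        atlas_pass = le_mean_volumes(refined_dtis)
        target = scalar_map(atlas_pass, "fa")

    # ---- global fields and final atlas -------------------------------------
    global_fields = []
    for i in range(len(subjects)):
        # atlas -> affine space via the refinement field, then affine space
        # -> subject via the inverse of affine 1B
        gfield = compose_field_then_affine(refine_fields[i],
                                           affine_1b[i].inverse())
        global_fields.append(gfield)
    final_dtis = [le_resample(subjects[i], global_fields[i])
                  for i in range(len(subjects))]
    final_atlas = le_mean_volumes(final_dtis)
    snapshots["final"] = scalar_map(final_atlas, "fa")

    return AtlasResult(affine_atlas=affine_atlas, greedy_atlas=greedy_atlas,
                       final_atlas=final_atlas, affine_1a=affine_1a,
                       affine_1b=affine_1b, greedy_fields=greedy_fields,
                       refine_fields=refine_fields,
                       global_fields=global_fields, fa_snapshots=snapshots)
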