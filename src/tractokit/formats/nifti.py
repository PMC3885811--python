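"""NIfTI-1 scalar/label volume IO via nibabel (affine carries the RAS frame)."""

from __future__ import annotations

import nibabel as nib
import numpy as np

from ..core import LabelVolume, ScalarVolume, StructuralError


def _spatial_from_affine(affine):
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if (spacing <= 0).any():
        raise StructuralError("degenerate NIfTI affine")
    direction = linear / spacing[np.newaxis, :]
    return spacing, affine[:3, 3].copy(), direction


def _affine_from(vol):
    aff = np.eye(4)
    aff[:3, :3] = vol.direction * vol.spacing[np.newaxis, :]
    aff[:3, 3] = vol.origin
    return aff


def read_nifti_scalar(path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise StructuralError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    spacing, origin, direction = _spatial_from_affine(img.affine)
    return ScalarVolume(data, spacing=spacing, origin=origin,
                        direction=direction)


def write_nifti_scalar(vol: ScalarVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), _affine_from(vol)),
             str(path))


def read_nifti_label(path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise StructuralError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    spacing, origin, direction = _spatial_from_affine(img.affine)
    return LabelVolume(np.round(data).astype(np.int32), spacing=spacing,
                       origin=origin, direction=direction)


def write_nifti_label(vol: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.int32), _affine_from(vol)),
             str(path))
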