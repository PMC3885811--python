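"""Automatic DWI quality control.

Header checking, slice-wise artifact detection with gradient exclusion,
baseline averaging and the entropy-based dominant-direction (vibration)
artifact check. Detection works by normalized cross-correlation of adjacent
slices per gradient; per-slice-position scores are standardized across
gradients with a robust z (median/MAD) so a single gross artifact cannot
mask itself. Thresholds are package defaults, tunable per study through
:class:`QCProtocol`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DWIVolume, GradientTable, StructuralError, TensorVolume
from .tensor import eigensystem_field, scalar_map

_MAD_SCALE = 1.4826


@dataclass
class QCProtocol:
    """All tunable parameters of the automatic QC."""

    slice_corr_z_threshold: float = 3.5
    baseline_slice_corr_z_threshold: float = 3.0
    min_corr_drop: float = 0.5          # absolute NCC drop required to exclude
    min_intensity_drop: float = 0.4     # relative slice-mean drop required
    entropy_low: float = 3.5
    entropy_high: float = 4.2
    low_fa_max: float = 0.25
    min_remaining_gradients: int = 6
    azimuth_bins: int = 16
    elevation_bins: int = 8
    expected_spacing: Optional[Tuple[float, float, float]] = None
    expected_shape: Optional[Tuple[int, int, int]] = None

    def __post_init__(self):
        if self.slice_corr_z_threshold <= 0 or \
                self.baseline_slice_corr_z_threshold <= 0:
            raise StructuralError("thresholds must be positive")
        if not (0 < self.low_fa_max < 1):
            raise StructuralError("low_fa_max must lie in (0, 1)")
        if self.entropy_low >= self.entropy_high:
            raise StructuralError("entropy_low must be < entropy_high")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QCProtocol":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class QCReport:
    """Per-gradient slice-check outcome plus overall and entropy verdicts."""

    excluded: List[int]                       # gradient indices
    z_scores: np.ndarray                      # (n_gradients, n_slice_pairs)
    correlations: np.ndarray                  # (n_gradients, n_slice_pairs)
    verdict: str = "pass"
    dominant_direction_verdict: str = "not run"
    entropy: Optional[float] = None
    findings: List[str] = field(default_factory=list)

    @property
    def passed(self) -> List[int]:
        return [g for g in range(self.z_scores.shape[0])
                if g not in self.excluded]

    def to_dataframe(self) -> pd.DataFrame:
        n_grad, n_pairs = self.z_scores.shape
        rows = []
        for g in range(n_grad):
            rows.append({"gradient": g,
                         "status": "excluded" if g in self.excluded else "pass",
                         "min_z": float(self.z_scores[g].min())
                         if n_pairs else np.nan,
                         "min_correlation": float(self.correlations[g].min())
                         if n_pairs else np.nan})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"overall verdict: {self.verdict}",
                 f"dominant direction: {self.dominant_direction_verdict}"
                 + (f" (entropy {self.entropy:.3f})"
                    if self.entropy is not None else ""),
                 f"excluded gradients: {self.excluded or 'none'}"]
        lines += [f"finding: {f}" for f in self.findings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# header check
# ---------------------------------------------------------------------------

def check_header(dwi: DWIVolume, protocol: QCProtocol) -> List[str]:
    """Image-information findings: bad gradient norms, missing baseline,
    spacing/size mismatches against protocol expectations."""
    findings = []
    table = dwi.gradients
    norms = table.norms
    nb = ~table.is_baseline
    bad = np.flatnonzero(nb & (np.abs(norms - 1.0) > 1e-3))
    for g in bad:
        findings.append(f"gradient {g} has non-unit norm {norms[g]:.4f}")
    if table.n_baselines == 0:
        findings.append("no b=0 volume")
    det = np.linalg.det(table.measurement_frame)
    if abs(abs(det) - 1.0) > 1e-6:
        findings.append(f"measurement frame determinant {det:.4g} not +-1")
    if protocol.expected_spacing is not None and not np.allclose(
            dwi.spacing, protocol.expected_spacing, atol=1e-6):
        findings.append(
            f"spacing {tuple(dwi.spacing)} != expected "
            f"{tuple(protocol.expected_spacing)}")
    if protocol.expected_shape is not None and \
            tuple(dwi.data.shape[:3]) != tuple(protocol.expected_shape):
        findings.append(
            f"volume shape {dwi.data.shape[:3]} != expected "
            f"{tuple(protocol.expected_shape)}")
    return findings


# ---------------------------------------------------------------------------
# slice-wise artifact detection
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb_ = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb_ < 1e-12:
        return 1.0 if na < 1e-12 and nb_ < 1e-12 else 0.0
    return float(a @ b / (na * nb_))


def slicewise_check(dwi: DWIVolume, protocol: QCProtocol) -> QCReport:
    """Detect slice artifacts by adjacent-slice correlation, robust-z scored.

    For each gradient, the normalized cross-correlation of every adjacent
    axial slice pair is computed; each slice-pair position is standardized
    across gradients (median/MAD) and a gradient is excluded when any of its
    robust z-scores falls below the (negative) threshold. Baselines are
    scored against the baseline threshold.
    """
    n_slices = dwi.data.shape[2]
    if n_slices < 3:
        raise StructuralError("slice-wise check needs >= 3 slices")
    n_grad = dwi.data.shape[3]
    n_pairs = n_slices - 1
    corr = np.empty((n_grad, n_pairs))
    inten = np.empty((n_grad, n_slices))
    for g in range(n_grad):
        vol = dwi.data[..., g]
        inten[g] = vol.mean(axis=(0, 1))
        for k in range(n_pairs):
            corr[g, k] = _ncc(vol[:, :, k], vol[:, :, k + 1])

    # correlation standardized ACROSS gradients per slice position; slice
    # intensity standardized WITHIN each gradient across slices (per-direction
    # mean intensity varies legitimately)
    corr_med = np.median(corr, axis=0)
    corr_mad = np.median(np.abs(corr - corr_med[np.newaxis, :]), axis=0)
    z = (corr - corr_med[np.newaxis, :]) \
        / (_MAD_SCALE * corr_mad[np.newaxis, :] + 1e-12)
    in_med = np.median(inten, axis=1)
    in_mad = np.median(np.abs(inten - in_med[:, np.newaxis]), axis=1)
    zi = (inten - in_med[:, np.newaxis]) \
        / (_MAD_SCALE * in_mad[:, np.newaxis] + 1e-12)

    baseline = dwi.gradients.is_baseline
    thr = np.where(baseline, protocol.baseline_slice_corr_z_threshold,
                   protocol.slice_corr_z_threshold)
    # an exclusion needs both a robust-z outlier and a material absolute drop
    # (NCC alone is scale-invariant, so slice intensity is scored as well)
    corr_drop = corr_med[np.newaxis, :] - corr
    with np.errstate(invalid="ignore", divide="ignore"):
        inten_drop = (in_med[:, np.newaxis] - inten) \
            / np.where(in_med > 1e-12, in_med, 1)[:, np.newaxis]
    bad_corr = (z < -thr[:, np.newaxis]) & (corr_drop > protocol.min_corr_drop)
    bad_inten = (zi < -thr[:, np.newaxis]) & \
        (inten_drop > protocol.min_intensity_drop)
    excluded = [g for g in range(n_grad)
                if bad_corr[g].any() or bad_inten[g].any()]

    report = QCReport(excluded=excluded, z_scores=z, correlations=corr)
    remaining = (~baseline).sum() - sum(1 for g in excluded if not baseline[g])
    if remaining < protocol.min_remaining_gradients:
        report.verdict = "reject dataset"
    elif excluded:
        report.verdict = "pass with exclusions"
    return report


def apply_exclusions(dwi: DWIVolume, report: QCReport) -> DWIVolume:
    """Drop excluded gradient volumes and table entries, preserving order."""
    if report.z_scores.shape[0] != dwi.data.shape[3]:
        raise StructuralError("report does not match this DWI")
    keep = np.array([g not in report.excluded
                     for g in range(dwi.data.shape[3])])
    table = dwi.gradients
    remaining_dirs = (~table.is_baseline[keep]).sum()
    if remaining_dirs < 6:
        raise StructuralError(
            f"exclusion would leave only {remaining_dirs} gradient "
            "directions (minimum 6)")
    out = DWIVolume(dwi.data[..., keep], table.subset(keep),
                    **dwi.spatial_kwargs())
    return out


def average_baselines(dwi: DWIVolume) -> DWIVolume:
    """Replace all b=0 volumes by their voxelwise mean, placed first."""
    table = dwi.gradients
    bl = table.is_baseline
    if not bl.any():
        raise StructuralError("no baseline volume to average")
    mean_b0 = dwi.data[..., bl].mean(axis=3)
    rest = dwi.data[..., ~bl]
    data = np.concatenate([mean_b0[..., np.newaxis], rest], axis=3)
    dirs = np.vstack([np.zeros(3), table.directions[~bl]])
    out_table = GradientTable(dirs, table.b_value,
                              table.measurement_frame.copy())
    return DWIVolume(data, out_table, **dwi.spatial_kwargs())


# ---------------------------------------------------------------------------
# dominant-direction (vibration) artifact check
# ---------------------------------------------------------------------------

def direction_histogram_entropy(e1: np.ndarray, azimuth_bins: int = 16,
                                elevation_bins: int = 8) -> float:
    """Shannon entropy (nats) of principal directions on an equal-area
    hemisphere histogram with antipodal identification."""
    v = np.asarray(e1, dtype=float)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    flip = (v[:, 2] < 0) | ((v[:, 2] == 0) & (v[:, 1] < 0)) | \
        ((v[:, 2] == 0) & (v[:, 1] == 0) & (v[:, 0] < 0))
    v = np.where(flip[:, np.newaxis], -v, v)
    az = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * np.pi)
    az_idx = np.minimum((az / (2 * np.pi) * azimuth_bins).astype(int),
                        azimuth_bins - 1)
    # equal-area elevation bins: cos(el) uniform in [0, 1]
    z = np.clip(v[:, 2], 0.0, 1.0)
    el_idx = np.minimum(((1.0 - z) * elevation_bins).astype(int),
                        elevation_bins - 1)
    hist = np.zeros(azimuth_bins * elevation_bins)
    np.add.at(hist, az_idx * elevation_bins + el_idx, 1.0)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def dominant_direction_check(tensors: TensorVolume, protocol: QCProtocol
                             ) -> Tuple[str, Optional[float]]:
    """Entropy-of-directions verdict on low-FA voxels.

    Returns (verdict, entropy); verdict is one of ``pass``, ``suspicious``,
    ``dominant direction artifact`` or ``insufficient data``.
    """
    fa = scalar_map(tensors, "fa").data
    low = tensors.mask & (fa < protocol.low_fa_max)
    if low.sum() < 100:
        return "insufficient data", None
    _, vecs = eigensystem_field(tensors.tensors[low])
    entropy = direction_histogram_entropy(
        vecs[:, 0, :], protocol.azimuth_bins, protocol.elevation_bins)
    if entropy < protocol.entropy_low:
        return "dominant direction artifact", entropy
    if entropy <= protocol.entropy_high:
        return "suspicious", entropy
    return "pass", entropy


def run_qc(dwi: DWIVolume, protocol: Optional[QCProtocol] = None
           ) -> Tuple[DWIVolume, QCReport]:
    """Full automatic QC: header findings, slice check, exclusion, baseline
    averaging. Returns the cleaned DWI and the report."""
    protocol = protocol or QCProtocol()
    report = slicewise_check(dwi, protocol)
    report.findings = check_header(dwi, protocol)
    if report.verdict == "reject dataset":
        return dwi, report
    cleaned = apply_exclusions(dwi, report)
    cleaned = average_baselines(cleaned)
    return cleaned, report


# ---------------------------------------------------------------------------
# brain-mask plumbing
# ---------------------------------------------------------------------------

def baseline_brain_mask(dwi: DWIVolume, threshold_fraction: float = 0.25
                        ) -> np.ndarray:
    """Simple baseline-threshold + morphology foreground mask.

    Threshold at a fraction of the robust maximum of the mean baseline, close
    small gaps, fill holes and keep the largest connected component.
    """
    bl = dwi.gradients.is_baseline
    if not bl.any():
        raise StructuralError("brain mask needs a baseline volume")
    b0 = dwi.data[..., bl].mean(axis=3)
    level = threshold_fraction * np.percentile(b0, 99)
    mask = b0 > level
    mask = ndimage.binary_closing(mask, iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(mask, labels,
                                               range(1, n + 1))) + 1
        mask = labels == largest
    return mask
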