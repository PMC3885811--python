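"""Tensor estimation, scalar maps and Log-Euclidean algebra."""

import numpy as np
import pytest

import tractokit as tk
from tractokit.core import StructuralError, matrix_to_tensor6, tensor6_to_matrix
from tractokit.tensor import (color_fa, estimate_tensors, eigensystem,
                              exp_map, filter_negative_eigenvalues, le_mean,
                              le_resample, log_map, scalar_map,
                              scalars_from_eigenvalues)


def _diag6(a, b, c):
    return np.array([a, 0, 0, b, 0, c], dtype=float)


class TestEstimation:
    @pytest.mark.parametrize("method", ["lls", "wls"])
    def test_noise_free_recovery(self, method, gradient_table):
        spec = tk.PhantomSpec(shape=(8, 8, 8))
        tv = tk.make_tensor_phantom(spec)
        dwi = tk.simulate_dwi(tv, gradient_table, s0=1000.0, noise_sd=0.0)
        est = estimate_tensors(dwi, method=method)
        err = np.abs(est.tensors - tv.tensors)[est.mask].max()
        assert err < 1e-9

    def test_all_signals_equal_baseline_gives_zero_tensor(self, gradient_table):
        data = np.full((4, 4, 4, len(gradient_table)), 500.0)
        dwi = tk.DWIVolume(data, gradient_table)
        est = estimate_tensors(dwi)
        assert np.abs(est.tensors).max() < 1e-12

    def test_measurement_frame_consistency(self):
        """Same world tensor recovered when simulation and estimation share
        a rotated measurement frame."""
        theta = np.radians(90)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        table_id = tk.default_gradient_table(n_directions=12)
        # same world directions expressed in a rotated frame
        dirs_rot = table_id.directions @ R  # R^T applied row-wise
        table_rot = tk.GradientTable(dirs_rot, 1000.0, R)
        assert np.allclose(table_rot.world_directions(),
                           table_id.world_directions(), atol=1e-12)
        spec = tk.PhantomSpec(shape=(6, 6, 6))
        tv = tk.make_tensor_phantom(spec)
        d1 = tk.simulate_dwi(tv, table_id, 1000.0)
        d2 = tk.simulate_dwi(tv, table_rot, 1000.0)
        e1 = estimate_tensors(d1)
        e2 = estimate_tensors(d2)
        assert np.allclose(e1.tensors, e2.tensors, atol=1e-10)

    def test_collinear_gradients_rejected(self):
        dirs = np.vstack([np.zeros(3)] + [[1, 0, 0]] * 6)
        table = tk.GradientTable(dirs, 1000.0)
        dwi = tk.DWIVolume(np.full((3, 3, 3, 7), 100.0), table)
        with pytest.raises(StructuralError, match="condition number"):
            estimate_tensors(dwi)

    def test_rotation_equivariance(self):
        """Rotating phantom and gradients together rotates the estimate."""
        theta = np.radians(40)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3)) * 1e-3
        D = A @ A.T + 1e-4 * np.eye(3)
        table = tk.default_gradient_table(n_directions=12)
        rot_dirs = np.where(table.is_baseline[:, None], 0.0,
                            table.directions @ R.T)
        table_rot = tk.GradientTable(rot_dirs, 1000.0)

        def fit(d6, tab):
            tvol = tk.TensorVolume(np.tile(d6, (2, 2, 2, 1)))
            dwi = tk.simulate_dwi(tvol, tab, 1000.0)
            return tensor6_to_matrix(estimate_tensors(dwi).tensors[0, 0, 0])

        base = fit(matrix_to_tensor6(D), table)
        rotated = fit(matrix_to_tensor6(R @ D @ R.T), table_rot)
        assert np.allclose(rotated, R @ base @ R.T,
                           atol=1e-6 * np.abs(D).max())


class TestEigenAndScalars:
    def test_negative_eigenvalue_clamp(self):
        vecs = np.eye(3)
        vals = np.array([2e-3, -1e-3, -1e-3])
        d6 = matrix_to_tensor6(vecs @ np.diag(vals) @ vecs.T)
        tv = tk.TensorVolume(np.tile(d6, (2, 2, 2, 1)))
        out = filter_negative_eigenvalues(tv)
        es = eigensystem(out.tensors[0, 0, 0])
        assert np.allclose(es.eigenvalues, [2e-3, 0, 0], atol=1e-15)

    def test_spd_tensor_unchanged_and_reconstructs(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        D = A @ A.T + 3 * np.eye(3)
        d6 = matrix_to_tensor6(D)
        tv = tk.TensorVolume(np.tile(d6, (1, 1, 1, 1)))
        out = filter_negative_eigenvalues(tv)
        assert np.allclose(out.tensors[0, 0, 0], d6, atol=1e-10)
        es = eigensystem(d6)
        rec = es.eigenvectors.T @ np.diag(es.eigenvalues) @ es.eigenvectors
        assert np.allclose(rec, D, atol=1e-10)
        # right-handed, orthonormal
        assert np.allclose(es.eigenvectors @ es.eigenvectors.T, np.eye(3),
                           atol=1e-9)
        assert np.linalg.det(es.eigenvectors) > 0

    @pytest.mark.parametrize("lam,which,expected", [
        ((1.0, 1.0, 1.0), "fa", 0.0),
        ((1.0, 1.0, 1.0), "md", 1.0),
        ((1.0, 1.0, 1.0), "rd", 1.0),
        ((1.0, 1.0, 1.0), "ad", 1.0),
        ((1.0, 0.0, 0.0), "fa", 1.0),
        ((1.7e-3, 0.3e-3, 0.3e-3), "md", 2.3e-3 / 3),
        ((1.7e-3, 0.3e-3, 0.3e-3), "ad", 1.7e-3),
        ((1.7e-3, 0.3e-3, 0.3e-3), "rd", 0.3e-3),
    ])
    def test_closed_forms(self, lam, which, expected):
        got = scalars_from_eigenvalues(np.array(lam), which)
        assert np.isclose(got, expected, atol=1e-12)

    def test_fa_closed_form_anisotropic(self):
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        mean = lam.mean()
        expected = np.sqrt(1.5) * np.linalg.norm(lam - mean) \
            / np.linalg.norm(lam)
        assert np.isclose(scalars_from_eigenvalues(lam, "fa"), expected,
                          atol=1e-15)

    def test_fa_in_unit_interval_after_filtering(self):
        rng = np.random.default_rng(123)
        n = 10_000
        m = rng.normal(size=(n, 3, 3)) * 1e-3
        sym6 = matrix_to_tensor6((m + np.swapaxes(m, 1, 2)) / 2)
        tv = tk.TensorVolume(sym6.reshape(n, 1, 1, 6))
        fa = scalar_map(filter_negative_eigenvalues(tv), "fa").data
        assert np.all(fa >= 0) and np.all(fa <= 1 + 1e-12)

    def test_color_fa_axis_conventions(self):
        lam = (1.7e-3, 0.3e-3, 0.3e-3)
        along_x = tk.TensorVolume(np.tile(_diag6(*lam), (1, 1, 1, 1)))
        rgb = color_fa(along_x)[0, 0, 0]
        fa = scalars_from_eigenvalues(np.array(lam), "fa")
        assert np.allclose(rgb, [fa, 0, 0], atol=1e-12)   # R-L is red
        along_z = tk.TensorVolume(
            np.tile(_diag6(lam[1], lam[1], lam[0]), (1, 1, 1, 1)))
        rgb = color_fa(along_z)[0, 0, 0]
        assert np.allclose(rgb, [0, 0, fa], atol=1e-12)   # I-S is blue
        iso = tk.TensorVolume(np.tile(_diag6(1e-3, 1e-3, 1e-3), (1, 1, 1, 1)))
        assert np.allclose(color_fa(iso)[0, 0, 0], 0.0, atol=1e-12)


class TestLogEuclidean:
    def test_exp_log_inverse_pair(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(5, 3, 3))
        spd = A @ np.swapaxes(A, 1, 2) + 2 * np.eye(3)
        d6 = matrix_to_tensor6(spd)
        assert np.allclose(exp_map(log_map(d6)), d6, atol=1e-10)

    def test_le_mean_identity_and_geometric_mean(self):
        d = _diag6(1.7e-3, 0.3e-3, 0.3e-3)
        assert np.allclose(le_mean([d, d, d]), d, atol=1e-12)
        a = _diag6(1e-3, 2e-3, 4e-3)
        b = _diag6(4e-3, 2e-3, 1e-3)
        got = le_mean([a, b])
        expected = _diag6(2e-3, 2e-3, 2e-3)
        assert np.allclose(got, expected, atol=1e-12)

    def test_le_mean_permutation_invariant(self):
        rng = np.random.default_rng(9)
        ts = [matrix_to_tensor6(m @ m.T + 1e-3 * np.eye(3))
              for m in rng.normal(size=(4, 3, 3)) * 1e-2]
        a = le_mean(ts)
        b = le_mean(ts[::-1])
        assert np.allclose(a, b, atol=1e-12)

    def test_le_mean_bad_weights_rejected(self):
        d = _diag6(1e-3, 1e-3, 1e-3)
        with pytest.raises(StructuralError):
            le_mean([d, d], weights=[0.6, 0.6])

    def test_translation_resample_keeps_tensor_orientation(self):
        spec = tk.PhantomSpec(shape=(12, 10, 10))
        tv = filter_negative_eigenvalues(tk.make_tensor_phantom(spec))
        fld = tk.DisplacementField(
            np.full(tv.shape + (3,), [2.0, 0.0, 0.0]), **tv.spatial_kwargs())
        out = le_resample(tv, fld, reorient=True)
        # integer translation: tensors shifted, unrotated
        assert np.allclose(out.tensors[:9], tv.tensors[2:11], atol=1e-9)
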