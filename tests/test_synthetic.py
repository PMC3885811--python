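"""Phantoms, DWI simulation, artifacts and cohort generators."""

import numpy as np
import pytest

import tractokit as tk
from tractokit.core import StructuralError
from tractokit.synthetic import (arc_centerline, eigenvalues_for_fa,
                                 invert_displacement_field,
                                 modulated_bundle_mask, random_smooth_field,
                                 simulate_profile_cohort,
                                 straight_bundle_mask)
from tractokit.tensor import eigensystem, scalar_map, scalars_from_eigenvalues


class TestPhantoms:
    def test_straight_bundle_axis_and_fa(self):
        spec = tk.PhantomSpec(shape=(16, 16, 16))
        tv = tk.make_tensor_phantom(spec)
        mask = straight_bundle_mask(spec)
        fa = scalar_map(tv, "fa").data
        fa_expected = scalars_from_eigenvalues(
            np.array(spec.eigenvalues_inside), "fa")
        assert np.allclose(fa[mask], fa_expected, atol=1e-12)
        assert np.allclose(fa[~mask], 0.0, atol=1e-12)
        es = eigensystem(tv.tensors[8, 8, 8])
        assert np.allclose(np.abs(es.eigenvectors[0]), [1, 0, 0], atol=1e-12)

    def test_arc_tangent_alignment(self):
        spec = tk.PhantomSpec(shape=(32, 32, 16), bundle_geometry="arc")
        tv = tk.make_tensor_phantom(spec)
        pts, tans = arc_centerline(spec, n_samples=400)
        # probe mid-arc voxel: e1 along the analytic tangent of the nearest
        # centerline sample (the voxel centre is up to half a voxel off-arc)
        mid = pts[len(pts) // 2]
        idx = np.round(tv.world_to_index(mid)).astype(int).ravel()
        center_world = tv.index_to_world(idx.astype(float))
        nearest = np.argmin(np.linalg.norm(pts - center_world, axis=1))
        es = eigensystem(tv.tensors[tuple(idx)])
        assert abs(abs(es.eigenvectors[0] @ tans[nearest]) - 1) < 1e-6

    def test_crossing_requires_large_grid(self):
        with pytest.raises(StructuralError, match="16"):
            tk.make_tensor_phantom(tk.PhantomSpec(shape=(8, 8, 8),
                                                  bundle_geometry="crossing"))

    def test_eigenvalue_ordering_validated(self):
        with pytest.raises(StructuralError):
            tk.PhantomSpec(eigenvalues_inside=(0.3e-3, 1.7e-3, 0.3e-3))

    def test_eigenvalues_for_fa_round_trip(self):
        for target in (0.1, 0.4, 0.7, 0.9):
            lam = eigenvalues_for_fa(target, 0.9e-3)
            assert np.isclose(scalars_from_eigenvalues(lam, "fa"), target,
                              atol=1e-12)
            assert np.isclose(lam.mean(), 0.9e-3, atol=1e-18)


class TestSimulateDwi:
    def test_exact_model_signal(self, gradient_table):
        d6 = np.array([1.7e-3, 0, 0, 0.3e-3, 0, 0.3e-3])
        tv = tk.TensorVolume(np.tile(d6, (2, 2, 2, 1)))
        gx = tk.GradientTable(np.array([[0, 0, 0], [1.0, 0, 0],
                                        [0, 1.0, 0], [0, 0, 1.0],
                                        [0.707106781186547, 0.707106781186547, 0],
                                        [0.707106781186547, 0, 0.707106781186547],
                                        [0, 0.707106781186547, 0.707106781186547]]),
                              1000.0)
        dwi = tk.simulate_dwi(tv, gx, s0=1000.0, noise_sd=0.0)
        assert np.isclose(dwi.data[0, 0, 0, 0], 1000.0)
        assert np.isclose(dwi.data[0, 0, 0, 1], 1000.0 * np.exp(-1.7))

    def test_isotropic_signal_direction_independent(self, gradient_table):
        d6 = np.array([1e-3, 0, 0, 1e-3, 0, 1e-3])
        tv = tk.TensorVolume(np.tile(d6, (2, 2, 2, 1)))
        dwi = tk.simulate_dwi(tv, gradient_table, s0=500.0)
        nb = ~gradient_table.is_baseline
        vals = dwi.data[0, 0, 0, nb]
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_rician_noise_reproducible(self, gradient_table):
        spec = tk.PhantomSpec(shape=(6, 6, 6))
        tv = tk.make_tensor_phantom(spec)
        a = tk.simulate_dwi(tv, gradient_table, 1000.0, noise_sd=20.0, seed=5)
        b = tk.simulate_dwi(tv, gradient_table, 1000.0, noise_sd=20.0, seed=5)
        c = tk.simulate_dwi(tv, gradient_table, 1000.0, noise_sd=20.0, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        assert (a.data >= 0).all()


class TestArtifacts:
    def test_zero_slice_exact_ground_truth(self, textured_dwi):
        bad, truth = tk.inject_artifact(textured_dwi, "zero_slice",
                                        {"gradient": 3, "slice": 10})
        assert truth == [(3, 10)]
        assert np.all(bad.data[:, :, 10, 3] == 0)
        keep = np.ones(bad.data.shape, dtype=bool)
        keep[:, :, 10, 3] = False
        assert np.array_equal(bad.data[keep], textured_dwi.data[keep])

    def test_attenuated_slice_halves_mean(self, textured_dwi):
        bad, _ = tk.inject_artifact(textured_dwi, "attenuated_slice",
                                    {"gradient": 2, "slice": 8, "factor": 0.5})
        assert np.isclose(bad.data[:, :, 8, 2].mean(),
                          textured_dwi.data[:, :, 8, 2].mean() * 0.5)

    def test_slice_out_of_range(self, textured_dwi):
        with pytest.raises(IndexError):
            tk.inject_artifact(textured_dwi, "zero_slice",
                               {"gradient": 1, "slice": 99})

    def test_direction_bias_skews_principal_directions(self, gradient_table):
        """On an isotropic phantom the bias axis dominates estimated e1."""
        iso6 = np.array([0.7e-3, 0, 0, 0.7e-3, 0, 0.7e-3])
        tv = tk.TensorVolume(np.tile(iso6, (10, 10, 10, 1)))
        dwi = tk.simulate_dwi(tv, gradient_table, 1000.0, noise_sd=5.0, seed=2)
        bad, truth = tk.inject_artifact(dwi, "direction_bias",
                                        {"axis": [0, 0, 1], "strength": 0.2})
        assert len(truth) > 0
        est = tk.estimate_tensors(bad)
        from tractokit.core import eigensystem_field
        _, vecs = eigensystem_field(est.tensors)
        align = np.abs(vecs[..., 0, :] @ np.array([0, 0, 1.0]))
        assert np.median(align) > 0.9


class TestWarps:
    def test_field_reproducible_and_diffeomorphic(self):
        f1 = random_smooth_field((16, 16, 16), 2.0, seed=3)
        f2 = random_smooth_field((16, 16, 16), 2.0, seed=3)
        assert np.array_equal(f1.field, f2.field)
        assert f1.jacobian_determinants().min() > 0

    def test_excessive_magnitude_rejected_with_jacobian(self):
        with pytest.raises(StructuralError, match="Jacobian"):
            random_smooth_field((16, 16, 16), 50.0, seed=3,
                                smooth_sigma_vox=1.0)

    def test_inverse_field_composes_to_identity(self):
        fld = random_smooth_field((16, 16, 16), 2.0, seed=8)
        inv = invert_displacement_field(fld)
        from tractokit.registration import compose_fields
        comp = compose_fields(fld, inv)
        assert np.linalg.norm(comp.field, axis=-1).mean() < 0.05


class TestCohort:
    def test_zero_beta_zero_noise_identical_profiles(self):
        spec = tk.CohortSpec(n_subjects=3, noise_sd=0.0, warp_magnitude=0.0,
                             seed=2)
        coh = tk.make_cohort(spec)
        assert np.allclose(coh.true_profiles[0], coh.true_profiles[1])
        assert np.array_equal(coh.subjects[0].tensors,
                              coh.subjects[1].tensors)

    def test_constant_beta_linearity(self):
        c = 0.01
        spec = tk.CohortSpec(n_subjects=4, noise_sd=0.0, warp_magnitude=0.0,
                             beta_functions={"age": lambda s: np.full_like(s, c)},
                             seed=3)
        coh = tk.make_cohort(spec)
        ages = coh.covariates["age"].to_numpy()
        diff = coh.true_profiles[1] - coh.true_profiles[0]
        assert np.allclose(diff, c * (ages[1] - ages[0]), atol=1e-12)

    def test_cohort_reproducible(self):
        a = tk.make_cohort(tk.CohortSpec(n_subjects=2, seed=7))
        b = tk.make_cohort(tk.CohortSpec(n_subjects=2, seed=7))
        assert np.array_equal(a.subjects[0].tensors, b.subjects[0].tensors)
        assert np.array_equal(a.fields[1].field, b.fields[1].field)

    def test_warp_jacobians_positive(self):
        coh = tk.make_cohort(tk.CohortSpec(n_subjects=2, warp_magnitude=2.0,
                                           seed=5))
        for fld in coh.fields:
            assert fld.jacobian_determinants().min() > 0

    def test_modulated_mask_radius(self):
        m = modulated_bundle_mask((40, 24, 24), 3.0, 0.3, 16.0)
        widths = m.sum(axis=(1, 2))
        assert widths.max() > widths.min() > 0

    def test_profile_cohort_matches_model(self):
        beta = lambda s: 0.01 * np.ones_like(s)
        spec = tk.CohortSpec(n_subjects=5, noise_sd=0.0,
                             beta_functions={"age": beta}, seed=4)
        prof, cov, betas = simulate_profile_cohort(spec)
        from tractokit.synthetic import default_baseline_profile
        grid = prof["arclength"].to_numpy()
        for label in cov.index:
            expected = default_baseline_profile(grid) \
                + cov.loc[label, "age"] * 0.01
            assert np.allclose(prof[label], expected, atol=1e-12)
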