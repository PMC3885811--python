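"""Origin planes, arclength parameterization and profile extraction."""

import numpy as np
import pandas as pd
import pytest

import tractokit as tk
from tractokit.core import StructuralError, segment_lengths
from tractokit.profiles import (LOCATION_INDEX, OriginPlane,
                                assemble_cohort_profiles, auto_origin_plane,
                                deform_fibers_to_subject, extract_profiles,
                                parameterize, profile_grid)
from tractokit.synthetic import eigenvalues_for_fa, modulated_bundle_mask


def _straight_fiber(x0=0.0, x1=30.0, y=0.0, z=0.0, n=31):
    xs = np.linspace(x0, x1, n)
    return np.stack([xs, np.full_like(xs, y), np.full_like(xs, z)], axis=1)


class TestOriginPlane:
    def test_straight_bundle_plane_perpendicular_and_central(
            self, tracked_bundle):
        plane = auto_origin_plane(tracked_bundle)
        assert abs(abs(plane.normal[0]) - 1) < 1e-6
        xs = tracked_bundle.all_points()[:, 0]
        assert abs(plane.point[0] - xs.mean()) < 1.0

    def test_arc_plane_normal_near_mid_tangent(self, arc_phantom):
        from tractokit.synthetic import arc_centerline
        from tractokit.tractography import TrackingParams, track
        spec, tv = arc_phantom
        pts, tans = arc_centerline(spec)
        bundle = track(tv, pts[len(pts) // 2][np.newaxis, :],
                       TrackingParams())
        plane = auto_origin_plane(bundle)
        mid_t = tans[len(tans) // 2]
        angle = np.degrees(np.arccos(min(1.0, abs(plane.normal @ mid_t))))
        assert angle < 5.0

    def test_single_fiber_plane_at_midpoint(self):
        b = tk.FiberBundle([_straight_fiber()])
        plane = auto_origin_plane(b)
        assert abs(plane.point[0] - 15.0) < 1e-6

    def test_empty_bundle_rejected(self):
        from tractokit.core import empty_bundle
        with pytest.raises(StructuralError):
            auto_origin_plane(empty_bundle())


class TestParameterize:
    def test_midpoint_plane_symmetric_arclengths(self):
        b = tk.FiberBundle([_straight_fiber(0, 30)])
        plane = OriginPlane([15.0, 0, 0], [1.0, 0, 0])
        pb = parameterize(b, plane)
        s = pb.point_data[LOCATION_INDEX][0]
        assert abs(abs(s[0]) - 15.0) < 1e-9
        assert abs(abs(s[-1]) - 15.0) < 1e-9
        # zero exactly at the crossing
        assert np.min(np.abs(s)) < 1e-9

    def test_quarter_plane_arclengths(self):
        b = tk.FiberBundle([_straight_fiber(0, 40, n=41)])
        plane = OriginPlane([10.0, 0, 0], [1.0, 0, 0])
        pb = parameterize(b, plane)
        s = pb.point_data[LOCATION_INDEX][0]
        assert {round(float(s[0]), 6), round(float(s[-1]), 6)} == \
            {-10.0, 30.0}

    def test_monotone_along_each_fiber(self, tracked_bundle):
        plane = auto_origin_plane(tracked_bundle)
        pb = parameterize(tracked_bundle, plane)
        for s in pb.point_data[LOCATION_INDEX]:
            d = np.diff(s)
            assert np.all(d > 0) or np.all(d < 0)

    def test_fiber_in_plane_excluded_and_reported(self):
        in_plane = _straight_fiber(y=5.0)        # lies in x-z plane y=5
        crossing = np.stack([np.full(11, 10.0), np.linspace(0, 10, 11),
                             np.zeros(11)], axis=1)
        b = tk.FiberBundle([in_plane, crossing])
        plane = OriginPlane([0.0, 5.0, 0.0], [0, 1.0, 0])
        pb = parameterize(b, plane)
        assert len(pb) == 1
        assert pb.metadata["excluded_fibers"] == [0]

    def test_no_crossing_fiber_is_excluded(self):
        crossing = _straight_fiber(0, 30)
        off_side = _straight_fiber(20, 30, y=2.0)
        plane = OriginPlane([15.0, 0, 0], [1.0, 0, 0])
        pb = parameterize(tk.FiberBundle([crossing, off_side,
                                          crossing + [0, 1, 0]]), plane)
        assert len(pb) == 2
        assert pb.metadata["excluded_fibers"] == [1]


class TestDeform:
    def test_identity_field_keeps_points(self, tracked_bundle):
        pb = parameterize(tracked_bundle, auto_origin_plane(tracked_bundle))
        fld = tk.DisplacementField(np.zeros((32, 24, 24, 3)))
        out = deform_fibers_to_subject(pb, fld)
        for a, b in zip(pb.fibers, out.fibers):
            assert np.allclose(a, b, atol=1e-12)

    def test_translation_shifts_points_keeps_arclengths(self, tracked_bundle):
        pb = parameterize(tracked_bundle, auto_origin_plane(tracked_bundle))
        fld = tk.DisplacementField(
            np.full((32, 24, 24, 3), [1.0, -2.0, 0.5]))
        out = deform_fibers_to_subject(pb, fld)
        for a, b in zip(pb.fibers, out.fibers):
            assert np.allclose(b - a, [1.0, -2.0, 0.5], atol=1e-9)
        for sa, sb in zip(pb.point_data[LOCATION_INDEX],
                          out.point_data[LOCATION_INDEX]):
            assert np.array_equal(sa, sb)


class TestExtraction:
    def test_constant_fa_gives_flat_profile(self, straight_phantom,
                                            tracked_bundle):
        _, tv, _ = straight_phantom
        pb = parameterize(tracked_bundle, auto_origin_plane(tracked_bundle))
        prof = extract_profiles(pb, tv, ["fa"], grid_step_mm=1.0)
        vals = prof.values["fa"][~prof.missing]
        assert vals.std() < 1e-12

    def test_linear_fa_ramp_slope_recovered(self):
        shape = (40, 24, 24)
        mask = modulated_bundle_mask(shape, 3.0, 0.0)
        tensors = np.zeros(shape + (6,))
        tensors[..., [0, 3, 5]] = 0.7e-3
        slope_true = 0.01
        fa_t = 0.3 + slope_true * (np.arange(40) - 20.0)
        evs = eigenvalues_for_fa(fa_t, 0.9e-3)
        for x in range(40):
            a, b, _ = evs[x]
            tensors[x, mask[x]] = [a, 0, 0, b, 0, b]
        tv = tk.TensorVolume(tensors)
        fa = tk.scalar_map(tv, "fa")
        labels = np.zeros(shape, dtype=np.int32)
        labels[20, 10:14, 10:14] = 1
        lab = tk.LabelVolume(labels, **tv.spatial_kwargs())
        params = tk.TrackingParams()
        seeds = tk.seeds_from_labelmap(lab, 1, fa, params)
        bundle = tk.track(tv, seeds, params)
        pb = parameterize(bundle, auto_origin_plane(bundle))
        prof = extract_profiles(pb, tv, ["fa"], grid_step_mm=1.0)
        g = prof.grid[~prof.missing]
        v = prof.values["fa"][~prof.missing]
        slope = abs(np.polyfit(g[2:-2], v[2:-2], 1)[0])
        assert abs(slope - slope_true) / slope_true < 0.05

    def test_reversal_invariance(self, straight_phantom, tracked_bundle):
        _, tv, _ = straight_phantom
        plane = auto_origin_plane(tracked_bundle)
        pb = parameterize(tracked_bundle, plane)
        reversed_bundle = tk.FiberBundle([f[::-1].copy()
                                          for f in tracked_bundle.fibers])
        pb_rev = parameterize(reversed_bundle, plane)
        grid = profile_grid(pb, 1.0)
        a = extract_profiles(pb, tv, ["fa"], grid=grid)
        b = extract_profiles(pb_rev, tv, ["fa"], grid=grid)
        assert np.allclose(a.values["fa"], b.values["fa"], equal_nan=True)

    def test_grid_refinement_consistency(self, straight_phantom,
                                         tracked_bundle):
        """Profiles at two grid steps agree within the kernel bias."""
        _, tv, _ = straight_phantom
        pb = parameterize(tracked_bundle, auto_origin_plane(tracked_bundle))
        coarse = extract_profiles(pb, tv, ["fa"], grid_step_mm=2.0,
                                  kernel_sigma_mm=1.0)
        fine = extract_profiles(pb, tv, ["fa"], grid_step_mm=1.0,
                                kernel_sigma_mm=1.0)
        interp = np.interp(coarse.grid, fine.grid, fine.values["fa"])
        ok = ~coarse.missing
        assert np.abs(coarse.values["fa"][ok] - interp[ok]).max() < 0.02

    def test_unknown_property_lists_valid_names(self, straight_phantom,
                                                tracked_bundle):
        _, tv, _ = straight_phantom
        pb = parameterize(tracked_bundle, auto_origin_plane(tracked_bundle))
        with pytest.raises(ValueError, match="fa"):
            extract_profiles(pb, tv, ["bogus"])


class TestAssemble:
    def _rows(self, labels, grid):
        rows = []
        for i, lab in enumerate(labels):
            rows.append(tk.SubjectProfile(
                label=lab, grid=grid,
                values={"fa": np.full(len(grid), 0.5 + 0.01 * i)},
                weight_mass=np.ones(len(grid))))
        return rows

    def test_cohort_assembly_with_atlas_column(self):
        grid = np.arange(-5.0, 6.0)
        labels = [f"s{i:02d}" for i in range(8)]
        cov = pd.DataFrame({"age": np.arange(8.0)},
                           index=pd.Index(labels, name="label"))
        atlas_row = tk.SubjectProfile("atlas", grid,
                                      {"fa": np.full(len(grid), 0.55)},
                                      np.ones(len(grid)))
        out = assemble_cohort_profiles(self._rows(labels, grid), cov,
                                       atlas_row)
        df = out["fa"]
        assert list(df.columns) == ["arclength"] + labels + ["atlas"]
        assert df.shape == (11, 10)

    def test_single_subject_valid(self):
        grid = np.arange(3.0)
        cov = pd.DataFrame({"age": [1.0]}, index=pd.Index(["s01"]))
        out = assemble_cohort_profiles(self._rows(["s01"], grid), cov)
        assert out["fa"].shape == (3, 2)

    def test_missing_covariate_label_named(self):
        grid = np.arange(3.0)
        cov = pd.DataFrame({"age": [1.0]}, index=pd.Index(["other"]))
        with pytest.raises(StructuralError, match="s01"):
            assemble_cohort_profiles(self._rows(["s01"], grid), cov)
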