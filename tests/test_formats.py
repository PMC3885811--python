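"""IO round trips and dialect handling for NRRD, VTK polydata, NIfTI, CSV."""

import numpy as np
import pandas as pd
import pytest

import tractokit as tk
from tractokit.core import FormatError, StructuralError
from tractokit.formats import (read_nifti_scalar, read_nrrd_dwi,
                               read_nrrd_label, read_nrrd_scalar,
                               read_nrrd_tensor, read_profile_csv,
                               read_vtk_fibers, write_nifti_scalar,
                               write_nrrd_dwi, write_nrrd_label,
                               write_nrrd_scalar, write_nrrd_tensor,
                               write_profile_csv, write_vtk_fibers)


def _dwi(n_grad=7, b=1000.0, mf=None, seed=0):
    rng = np.random.default_rng(seed)
    table = tk.default_gradient_table(n_directions=n_grad - 1, b_value=b,
                                      measurement_frame=mf)
    data = rng.uniform(10, 1000, (4, 4, 4, n_grad))
    return tk.DWIVolume(data, table, spacing=(1.5, 2.0, 2.5),
                        origin=(-3, 4, 5))


class TestNrrdDwi:
    def test_round_trip_bitwise(self, tmp_path):
        vol = _dwi()
        path = tmp_path / "dwi.nrrd"
        write_nrrd_dwi(vol, path)
        back = read_nrrd_dwi(path)
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.gradients.directions,
                           vol.gradients.directions, atol=1e-15)
        assert back.gradients.b_value == 1000.0
        assert np.array_equal(back.spacing, vol.spacing)
        assert np.array_equal(back.origin, vol.origin)

    def test_measurement_frame_round_trip(self, tmp_path):
        theta = np.radians(30)
        mf = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        vol = _dwi(mf=mf)
        path = tmp_path / "dwi.nrrd"
        write_nrrd_dwi(vol, path)
        back = read_nrrd_dwi(path)
        assert np.allclose(back.gradients.measurement_frame, mf, atol=1e-12)

    def test_lps_space_converted_to_ras(self, tmp_path):
        vol = _dwi()
        path = tmp_path / "dwi.nrrd"
        write_nrrd_dwi(vol, path)
        # rewrite the header claiming LPS with the sign-flipped geometry:
        # reading it back must restore the RAS quantities exactly
        raw = path.read_bytes()
        head, _, payload = raw.partition(b"\n\n")
        lines = head.decode().split("\n")
        flip = np.array([-1.0, -1.0, 1.0])
        out = []
        for line in lines:
            if line.startswith("space:"):
                out.append("space: left-posterior-superior")
            elif line.startswith("space directions:"):
                vecs = [np.array([float(x) for x in
                                  tok.strip("()").split(",")])
                        for tok in line.split(": ", 1)[1].split(") ")
                        if tok.strip() != "none"]
                toks = ["(" + ",".join(repr(float(v)) for v in (vec * flip)) + ")"
                        for vec in vecs] + ["none"]
                out.append("space directions: " + " ".join(toks))
            elif line.startswith("space origin:"):
                vec = np.array([float(x) for x in
                                line.split(": ", 1)[1].strip("()").split(",")])
                out.append("space origin: (" + ",".join(
                    repr(float(v)) for v in (vec * flip)) + ")")
            elif line.startswith("measurement frame:"):
                vecs = [np.array([float(x) for x in tok.strip("()").split(",")])
                        for tok in line.split(": ", 1)[1].split(") ")]
                out.append("measurement frame: " + " ".join(
                    "(" + ",".join(repr(float(v)) for v in (vec * flip)) + ")"
                    for vec in vecs))
            else:
                out.append(line)
        lps = tmp_path / "lps.nrrd"
        lps.write_bytes("\n".join(out).encode() + b"\n\n" + payload)
        back = read_nrrd_dwi(lps)
        vol_ras = read_nrrd_dwi(path)
        assert np.allclose(back.direction, vol_ras.direction, atol=1e-12)
        assert np.allclose(back.origin, vol_ras.origin, atol=1e-12)
        assert np.allclose(back.gradients.measurement_frame,
                           vol_ras.gradients.measurement_frame, atol=1e-12)

    def test_missing_gradient_key_names_it(self, tmp_path):
        vol = _dwi()
        path = tmp_path / "dwi.nrrd"
        write_nrrd_dwi(vol, path)
        raw = path.read_bytes().replace(b"DWMRI_gradient_0003", b"ignored_key")
        bad = tmp_path / "bad.nrrd"
        bad.write_bytes(raw)
        with pytest.raises(FormatError, match="DWMRI_gradient_0003"):
            read_nrrd_dwi(bad)

    def test_missing_measurement_frame_names_it(self, tmp_path):
        vol = _dwi()
        path = tmp_path / "dwi.nrrd"
        write_nrrd_dwi(vol, path)
        lines = [ln for ln in path.read_bytes().split(b"\n")
                 if not ln.startswith(b"measurement frame")]
        bad = tmp_path / "bad.nrrd"
        bad.write_bytes(b"\n".join(lines))
        with pytest.raises(FormatError, match="measurement frame"):
            read_nrrd_dwi(bad)

    def test_zero_gradient_volume_refused(self, tmp_path):
        vol = _dwi()
        vol.data = vol.data[..., :0]
        vol.gradients = vol.gradients.subset(np.zeros(7, dtype=bool))
        with pytest.raises(StructuralError):
            write_nrrd_dwi(vol, tmp_path / "empty.nrrd")

    def test_simpleitk_reads_our_nrrd(self, tmp_path):
        """Independent reader oracle: geometry and voxels must agree."""
        sitk = pytest.importorskip("SimpleITK")
        sv = tk.ScalarVolume(np.arange(24.0).reshape(2, 3, 4),
                             spacing=(1, 2, 3), origin=(5, 6, 7))
        path = tmp_path / "sv.nrrd"
        write_nrrd_scalar(sv, path)
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        assert np.array_equal(arr, sv.data)
        assert img.GetSpacing() == (1.0, 2.0, 3.0)
        # ITK reports LPS; our RAS origin appears with flipped x/y
        assert img.GetOrigin() == (-5.0, -6.0, 7.0)


class TestNrrdOtherKinds:
    def test_scalar_label_tensor_field_round_trips(self, tmp_path):
        rng = np.random.default_rng(3)
        sv = tk.ScalarVolume(rng.normal(size=(5, 4, 3)), spacing=(1, 2, 3),
                             origin=(1, 2, 3))
        write_nrrd_scalar(sv, tmp_path / "s.nrrd")
        assert np.array_equal(read_nrrd_scalar(tmp_path / "s.nrrd").data,
                              sv.data)

        lv = tk.LabelVolume(rng.integers(0, 5, (5, 4, 3)).astype(np.int32))
        write_nrrd_label(lv, tmp_path / "l.nrrd")
        assert np.array_equal(read_nrrd_label(tmp_path / "l.nrrd").data,
                              lv.data)

        tv = tk.TensorVolume(rng.normal(size=(4, 4, 4, 6)))
        write_nrrd_tensor(tv, tmp_path / "t.nrrd")
        back = read_nrrd_tensor(tmp_path / "t.nrrd")
        assert np.array_equal(back.tensors, tv.tensors)

        fld = tk.DisplacementField(rng.normal(size=(4, 4, 4, 3)))
        tk.formats.write_nrrd_field(fld, tmp_path / "f.nrrd")
        assert np.array_equal(
            tk.formats.read_nrrd_field(tmp_path / "f.nrrd").field, fld.field)


class TestVtkPolydata:
    def test_ascii_round_trip(self, tmp_path, two_fiber_bundle):
        path = tmp_path / "b.vtk"
        write_vtk_fibers(two_fiber_bundle, path)
        back = read_vtk_fibers(path)
        assert len(back) == 2
        for a, b in zip(two_fiber_bundle.fibers, back.fibers):
            assert np.array_equal(a, b)
        for a, b in zip(two_fiber_bundle.point_data["FA"],
                        back.point_data["FA"]):
            assert np.array_equal(a, b)

    def test_binary_round_trip(self, tmp_path, two_fiber_bundle):
        path = tmp_path / "b.vtk"
        write_vtk_fibers(two_fiber_bundle, path, binary=True)
        back = read_vtk_fibers(path)
        for a, b in zip(two_fiber_bundle.fibers, back.fibers):
            assert np.allclose(a, b)

    def test_random_bundles_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        for trial in range(5):
            fibers = [rng.normal(size=(int(rng.integers(2, 12)), 3)) * 30
                      for _ in range(int(rng.integers(1, 6)))]
            pd_ = {"A": [rng.normal(size=len(f)) for f in fibers],
                   "B": [rng.uniform(size=len(f)) for f in fibers]}
            b = tk.FiberBundle(fibers, pd_)
            path = tmp_path / f"r{trial}.vtk"
            write_vtk_fibers(b, path)
            back = read_vtk_fibers(path)
            for a, c in zip(b.fibers, back.fibers):
                assert np.array_equal(a, c)
            for name in pd_:
                for a, c in zip(b.point_data[name], back.point_data[name]):
                    assert np.array_equal(a, c)

    def test_polygons_only_is_rejected(self, tmp_path):
        path = tmp_path / "poly.vtk"
        path.write_text("# vtk DataFile Version 4.0\nt\nASCII\n"
                        "DATASET POLYDATA\nPOINTS 3 float\n"
                        "0 0 0\n1 0 0\n0 1 0\nPOLYGONS 1 4\n3 0 1 2\n")
        with pytest.raises(FormatError, match="no fiber lines"):
            read_vtk_fibers(path)


class TestNifti:
    def test_scalar_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        sv = tk.ScalarVolume(rng.normal(size=(6, 5, 4)), spacing=(1, 1.5, 2),
                             origin=(-4, 3, 9))
        path = tmp_path / "s.nii"
        write_nifti_scalar(sv, path)
        back = read_nifti_scalar(path)
        assert np.allclose(back.data, sv.data)
        # NIfTI-1 headers store the affine in float32
        assert np.allclose(back.spacing, sv.spacing, atol=1e-5)
        assert np.allclose(back.origin, sv.origin, atol=1e-5)


class TestProfileCsv:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"arclength": [-1.0, 0.0, 1.0],
                           "s01": [0.5, 0.6, 0.55],
                           "s02": [0.4, 0.45, 0.5]})
        path = tmp_path / "p.csv"
        write_profile_csv(df, path)
        back = read_profile_csv(path)
        assert list(back.columns) == ["arclength", "s01", "s02"]
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_non_monotone_arclength_rejected(self, tmp_path):
        df = pd.DataFrame({"arclength": [0.0, 0.0, 1.0], "s": [1, 2, 3]})
        with pytest.raises(StructuralError, match="increasing"):
            write_profile_csv(df, tmp_path / "bad.csv")
        good = pd.DataFrame({"arclength": [0.0, 1.0], "s": [1, 2]})
        path = tmp_path / "g.csv"
        write_profile_csv(good, path)
        text = path.read_text().replace("1.0,2", "0.0,2")
        bad = tmp_path / "b.csv"
        bad.write_text(text)
        with pytest.raises(StructuralError, match="increasing"):
            read_profile_csv(bad)
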