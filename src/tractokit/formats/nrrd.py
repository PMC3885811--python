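"""NRRD reader/writer for the DWI dialect plus scalar/label/tensor/field volumes.

Supports attached-header NRRD with ``raw``, ``gzip`` and ``ascii`` encodings.
Gradient directions are carried as ``DWMRI_gradient_NNNN`` key/value pairs
(4-digit zero padding on write), the shared b-value as ``DWMRI_b-value`` and
the measurement frame as the standard ``measurement frame`` field. Files in
left-posterior-superior (LPS) space are converted to RAS on read by negating
the first two rows of the space-directions matrix, the first two components
of the origin and the first two rows of the measurement frame; RAS is always
written.
"""

from __future__ import annotations

import gzip
import re
from typing import Tuple

import numpy as np

from ..core import (DWIVolume, FormatError, GradientTable, LabelVolume,
                    ScalarVolume, StructuralError, TensorVolume,
                    DisplacementField)

_MAGIC_RE = re.compile(r"^NRRD000\d")

_SPACE_FLIPS = {
    "right-anterior-superior": np.array([1.0, 1.0, 1.0]),
    "ras": np.array([1.0, 1.0, 1.0]),
    "left-posterior-superior": np.array([-1.0, -1.0, 1.0]),
    "lps": np.array([-1.0, -1.0, 1.0]),
    "left-anterior-superior": np.array([-1.0, 1.0, 1.0]),
    "las": np.array([-1.0, 1.0, 1.0]),
}

_DTYPES = {
    "float": np.float32, "double": np.float64,
    "short": np.int16, "unsigned short": np.uint16,
    "int": np.int32, "unsigned int": np.uint32,
    "uchar": np.uint8, "unsigned char": np.uint8, "signed char": np.int8,
    "long long": np.int64, "unsigned long long": np.uint64,
}


def _parse_vector(text: str) -> np.ndarray:
    return np.array([float(x) for x in
                     text.strip().lstrip("(").rstrip(")").split(",")])


def _parse_vector_list(text: str):
    out = []
    for token in re.findall(r"none|\([^)]*\)", text, flags=re.IGNORECASE):
        out.append(None if token.lower() == "none" else _parse_vector(token))
    return out


def _format_vector(v) -> str:
    return "(" + ",".join(repr(float(x)) for x in v) + ")"


def read_header(path) -> Tuple[dict, dict, int]:
    """Parse an attached NRRD header: (fields, key_values, data_offset)."""
    fields, keyvals = {}, {}
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").rstrip("\r\n")
        if not _MAGIC_RE.match(magic):
            raise FormatError(f"{path}: not an NRRD file (magic {magic!r})")
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                offset = fh.tell()
                break
            text = line.decode("utf-8").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                key, val = text.split(":=", 1)
                keyvals[key.strip()] = val.strip()
            elif ": " in text or text.endswith(":"):
                key, _, val = text.partition(":")
                fields[key.strip().lower()] = val.strip()
            else:
                raise FormatError(f"{path}: unparsable header line {text!r}")
    return fields, keyvals, offset


def _read_payload(path, offset, dtype, count, encoding, endian):
    with open(path, "rb") as fh:
        fh.seek(offset)
        blob = fh.read()
    enc = encoding.lower()
    if enc in ("gzip", "gz"):
        blob = gzip.decompress(blob)
        enc = "raw"
    if enc == "raw":
        dt = np.dtype(dtype)
        if dt.itemsize > 1:
            dt = dt.newbyteorder("<" if endian == "little" else ">")
        arr = np.frombuffer(blob, dtype=dt, count=count)
    elif enc in ("ascii", "text", "txt"):
        arr = np.array(blob.split(), dtype=dtype)
    else:
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if arr.size != count:
        raise StructuralError(
            f"{path}: payload holds {arr.size} values, header implies {count}")
    return arr


def _read_common(path):
    fields, keyvals, offset = read_header(path)
    if "sizes" not in fields or "type" not in fields:
        raise FormatError(f"{path}: NRRD header missing 'sizes' or 'type'")
    sizes = [int(s) for s in fields["sizes"].split()]
    dtype = _DTYPES.get(fields["type"].lower())
    if dtype is None:
        raise FormatError(f"{path}: unsupported NRRD type {fields['type']!r}")
    encoding = fields.get("encoding", "raw")
    endian = fields.get("endian", "little")
    data = _read_payload(path, offset, dtype, int(np.prod(sizes)),
                         encoding, endian)
    data = data.reshape(sizes, order="F")
    return fields, keyvals, data


def _spatial_from_fields(path, fields, n_domain_axes=3):
    space = fields.get("space", "right-anterior-superior").lower()
    flip = _SPACE_FLIPS.get(space)
    if flip is None:
        raise FormatError(f"{path}: unsupported NRRD space {space!r}")
    if "space directions" not in fields:
        raise FormatError(f"{path}: header missing 'space directions'")
    vecs = [v for v in _parse_vector_list(fields["space directions"])
            if v is not None]
    if len(vecs) != n_domain_axes:
        raise StructuralError(
            f"{path}: expected {n_domain_axes} spatial axes, found {len(vecs)}")
    axes = np.stack(vecs, axis=1) * flip[:, np.newaxis]   # columns = axes, RAS
    spacing = np.linalg.norm(axes, axis=0)
    if (spacing <= 0).any():
        raise StructuralError(f"{path}: degenerate space direction")
    direction = axes / spacing[np.newaxis, :]
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = _parse_vector(fields["space origin"]) * flip
    return spacing, origin, direction, flip


def read_nrrd_dwi(path) -> DWIVolume:
    """Read a DWI NRRD with per-gradient keys, b-value and measurement frame."""
    fields, keyvals, data = _read_common(path)
    if data.ndim != 4:
        raise StructuralError(f"{path}: DWI NRRD must be 4D, got {data.ndim}D")
    kinds = fields.get("kinds", "domain domain domain list").split()
    try:
        grad_axis = next(i for i, k in enumerate(kinds)
                         if k.lower() in ("list", "vector", "none"))
    except StopIteration:
        grad_axis = 3
    data = np.moveaxis(data, grad_axis, 3)
    n_grad = data.shape[3]

    if "DWMRI_b-value" not in keyvals:
        raise FormatError(f"{path}: missing 'DWMRI_b-value' key")
    b_value = float(keyvals["DWMRI_b-value"])
    directions = []
    for i in range(n_grad):
        key = f"DWMRI_gradient_{i:04d}"
        if key not in keyvals:
            raise FormatError(f"{path}: missing gradient key {key!r}")
        directions.append([float(x) for x in keyvals[key].split()])
    extra = [k for k in keyvals
             if k.startswith("DWMRI_gradient_") and int(k[-4:]) >= n_grad]
    if extra:
        raise StructuralError(
            f"{path}: gradient keys {extra} exceed 4th-axis length {n_grad}")

    spacing, origin, direction, flip = _spatial_from_fields(path, fields)
    if "measurement frame" not in fields:
        raise FormatError(f"{path}: header missing 'measurement frame' field")
    mf_cols = [v for v in _parse_vector_list(fields["measurement frame"])]
    mf = np.stack(mf_cols, axis=1) * flip[:, np.newaxis]

    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    nb = norms > 1e-8
    recorded = norms.copy()
    directions[nb] /= norms[nb, np.newaxis]
    table = GradientTable(directions, b_value, mf)
    vol = DWIVolume(np.ascontiguousarray(data, dtype=float), table,
                    spacing=spacing, origin=origin, direction=direction)
    vol.metadata = {"gradient_norms": recorded,
                    "space": fields.get("space", "right-anterior-superior")}
    return vol


def _write_header(fh, sizes, kinds, spacing, origin, direction, dtype_name,
                  keyvals=None, measurement_frame=None, n_domain=3):
    lines = ["NRRD0005",
             "# produced by tractokit",
             f"type: {dtype_name}",
             f"dimension: {len(sizes)}",
             "space: right-anterior-superior",
             "sizes: " + " ".join(str(s) for s in sizes)]
    axes = direction * np.asarray(spacing)[np.newaxis, :]
    dirtokens = []
    domain_seen = 0
    for k in kinds:
        if k == "domain":
            dirtokens.append(_format_vector(axes[:, domain_seen]))
            domain_seen += 1
        else:
            dirtokens.append("none")
    lines.append("space directions: " + " ".join(dirtokens))
    lines.append("kinds: " + " ".join(kinds))
    lines.append("endian: little")
    lines.append("encoding: raw")
    lines.append("space origin: " + _format_vector(origin))
    if measurement_frame is not None:
        lines.append("measurement frame: " + " ".join(
            _format_vector(measurement_frame[:, j]) for j in range(3)))
    for key, val in (keyvals or {}).items():
        lines.append(f"{key}:={val}")
    fh.write(("\n".join(lines) + "\n\n").encode("utf-8"))


def write_nrrd_dwi(vol: DWIVolume, path) -> None:
    """Write a DWIVolume as a RAS NRRD with the DWI key/value dialect."""
    if len(vol.gradients) == 0:
        raise StructuralError("refusing to write DWI with 0 gradients")
    keyvals = {"modality": "DWMRI",
               "DWMRI_b-value": repr(float(vol.gradients.b_value))}
    for i, g in enumerate(vol.gradients.directions):
        keyvals[f"DWMRI_gradient_{i:04d}"] = "   ".join(repr(float(x))
                                                        for x in g)
    with open(path, "wb") as fh:
        _write_header(fh, vol.data.shape,
                      ["domain", "domain", "domain", "list"],
                      vol.spacing, vol.origin, vol.direction, "double",
                      keyvals=keyvals,
                      measurement_frame=vol.gradients.measurement_frame)
        fh.write(np.asarray(vol.data, dtype="<f8").ravel(order="F").tobytes())


def read_nrrd_scalar(path) -> ScalarVolume:
    fields, _, data = _read_common(path)
    if data.ndim != 3:
        raise StructuralError(f"{path}: expected 3D scalar NRRD")
    spacing, origin, direction, _ = _spatial_from_fields(path, fields)
    return ScalarVolume(np.ascontiguousarray(data, dtype=float),
                        spacing=spacing, origin=origin, direction=direction)


def write_nrrd_scalar(vol: ScalarVolume, path) -> None:
    with open(path, "wb") as fh:
        _write_header(fh, vol.data.shape, ["domain"] * 3,
                      vol.spacing, vol.origin, vol.direction, "double")
        fh.write(np.asarray(vol.data, dtype="<f8").ravel(order="F").tobytes())


def read_nrrd_label(path) -> LabelVolume:
    fields, _, data = _read_common(path)
    if data.ndim != 3:
        raise StructuralError(f"{path}: expected 3D label NRRD")
    spacing, origin, direction, _ = _spatial_from_fields(path, fields)
    return LabelVolume(np.ascontiguousarray(np.round(data).astype(np.int32)),
                       spacing=spacing, origin=origin, direction=direction)


def write_nrrd_label(vol: LabelVolume, path) -> None:
    with open(path, "wb") as fh:
        _write_header(fh, vol.data.shape, ["domain"] * 3,
                      vol.spacing, vol.origin, vol.direction, "int")
        fh.write(np.asarray(vol.data, dtype="<i4").ravel(order="F").tobytes())


def read_nrrd_tensor(path) -> TensorVolume:
    """Read a 6-component symmetric-matrix tensor NRRD (component axis first)."""
    fields, _, data = _read_common(path)
    if data.ndim != 4:
        raise StructuralError(f"{path}: tensor NRRD must be 4D")
    kinds = fields.get("kinds", "3D-symmetric-matrix domain domain domain").split()
    comp_axis = next((i for i, k in enumerate(kinds)
                      if k.lower() != "domain"), 0)
    data = np.moveaxis(data, comp_axis, 3)
    if data.shape[3] != 6:
        raise StructuralError(f"{path}: expected 6 tensor components, got "
                              f"{data.shape[3]}")
    spacing, origin, direction, _ = _spatial_from_fields(path, fields)
    return TensorVolume(np.ascontiguousarray(data, dtype=float),
                        spacing=spacing, origin=origin, direction=direction)


def write_nrrd_tensor(tv: TensorVolume, path) -> None:
    data = np.moveaxis(tv.tensors, 3, 0)
    with open(path, "wb") as fh:
        _write_header(fh, data.shape,
                      ["3D-symmetric-matrix", "domain", "domain", "domain"],
                      tv.spacing, tv.origin, tv.direction, "double")
        fh.write(np.asarray(data, dtype="<f8").ravel(order="F").tobytes())


def read_nrrd_field(path) -> DisplacementField:
    """Read a displacement field NRRD (3-vector axis first)."""
    fields, _, data = _read_common(path)
    if data.ndim != 4:
        raise StructuralError(f"{path}: field NRRD must be 4D")
    kinds = fields.get("kinds", "vector domain domain domain").split()
    comp_axis = next((i for i, k in enumerate(kinds)
                      if k.lower() != "domain"), 0)
    data = np.moveaxis(data, comp_axis, 3)
    spacing, origin, direction, _ = _spatial_from_fields(path, fields)
    return DisplacementField(np.ascontiguousarray(data, dtype=float),
                             spacing=spacing, origin=origin,
                             direction=direction)


def write_nrrd_field(df: DisplacementField, path) -> None:
    data = np.moveaxis(df.field, 3, 0)
    with open(path, "wb") as fh:
        _write_header(fh, data.shape, ["vector", "domain", "domain", "domain"],
                      df.spacing, df.origin, df.direction, "double")
        fh.write(np.asarray(data, dtype="<f8").ravel(order="F").tobytes())
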