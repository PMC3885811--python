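"""Legacy VTK polydata reader/writer for fiber bundles.

Handles the classic (pre-5.0) ``DATASET POLYDATA`` layout with LINES cells
and per-point SCALARS arrays, in both ASCII and big-endian BINARY dialects
on read; ASCII is written by default. The 5.x OFFSETS/CONNECTIVITY LINES
layout is also accepted on read.
"""

from __future__ import annotations

import numpy as np

from ..core import FiberBundle, FormatError, StructuralError

_BIN_DTYPES = {
    "float": ">f4", "double": ">f8", "int": ">i4", "long": ">i4",
    "unsigned_int": ">u4", "vtktypeint64": ">i8", "vtktypeuint64": ">u8",
    "short": ">i2", "char": ">i1", "unsigned_char": ">u1",
}
_TXT_DTYPES = {k: v.replace(">", "") for k, v in _BIN_DTYPES.items()}


class _Cursor:
    """Sequential token/blob reader over the raw file bytes."""

    def __init__(self, blob: bytes, binary: bool):
        self.blob = blob
        self.pos = 0
        self.binary = binary

    def readline(self) -> str:
        end = self.blob.find(b"\n", self.pos)
        if end == -1:
            line, self.pos = self.blob[self.pos:], len(self.blob)
        else:
            line, self.pos = self.blob[self.pos:end], end + 1
        return line.decode("ascii", "replace").strip()

    def next_section_line(self) -> str:
        while self.pos < len(self.blob):
            line = self.readline()
            if line:
                return line
        return ""

    def read_values(self, count: int, vtk_type: str) -> np.ndarray:
        if self.binary:
            dt = np.dtype(_BIN_DTYPES[vtk_type])
            nbytes = count * dt.itemsize
            arr = np.frombuffer(self.blob[self.pos:self.pos + nbytes], dtype=dt)
            if arr.size != count:
                raise StructuralError("binary VTK payload truncated")
            self.pos += nbytes
            return arr.astype(float if dt.kind == "f" else np.int64)
        vals = []
        while len(vals) < count:
            line = self.readline()
            if line == "" and self.pos >= len(self.blob):
                raise StructuralError("ASCII VTK payload truncated")
            vals.extend(line.split())
        if len(vals) != count:
            # tolerate trailing tokens only if they belong to the next section
            vals = vals[:count]
        dt = _TXT_DTYPES[vtk_type]
        return np.array(vals, dtype=dt).astype(
            float if dt.startswith("f") else np.int64)


def read_vtk_fibers(path) -> FiberBundle:
    """Read a legacy VTK polydata file with LINES cells into a FiberBundle."""
    with open(path, "rb") as fh:
        blob = fh.read()
    header_end = blob.find(b"\n")
    if header_end == -1 or not blob[:header_end].startswith(b"# vtk DataFile"):
        raise FormatError(f"{path}: not a legacy VTK file")
    cur = _Cursor(blob, binary=False)
    cur.readline()                       # magic
    cur.readline()                       # title
    fmt = cur.next_section_line().upper()
    if fmt not in ("ASCII", "BINARY"):
        raise FormatError(f"{path}: unknown VTK format {fmt!r}")
    cur.binary = fmt == "BINARY"
    dataset = cur.next_section_line().upper().split()
    if len(dataset) < 2 or dataset[1] != "POLYDATA":
        raise FormatError(f"{path}: not a POLYDATA dataset")

    points = None
    lines_ids = None
    point_arrays = {}
    n_points = 0
    while True:
        line = cur.next_section_line()
        if not line:
            break
        tokens = line.split()
        kw = tokens[0].upper()
        if kw == "POINTS":
            n_points = int(tokens[1])
            vtk_type = tokens[2].lower()
            points = cur.read_values(3 * n_points, vtk_type).reshape(-1, 3)
        elif kw == "LINES":
            n_lines, total = int(tokens[1]), int(tokens[2])
            if cur.binary:
                flat = cur.read_values(total, "int")
                lines_ids = _split_classic_lines(flat, n_lines)
            else:
                mark = cur.pos
                nxt = cur.next_section_line()
                if nxt.upper().startswith("OFFSETS"):
                    # VTK 5.x layout: per-line offsets then connectivity
                    offsets = cur.read_values(n_lines, nxt.split()[1].lower())
                    conn_line = cur.next_section_line().split()
                    conn = cur.read_values(int(offsets[-1]),
                                           conn_line[1].lower())
                    lines_ids = [conn[int(offsets[i]):int(offsets[i + 1])]
                                 for i in range(n_lines - 1)]
                else:
                    cur.pos = mark
                    flat = cur.read_values(total, "int")
                    lines_ids = _split_classic_lines(flat, n_lines)
        elif kw in ("POLYGONS", "VERTICES", "TRIANGLE_STRIPS"):
            cur.read_values(int(tokens[2]), "int")
        elif kw == "POINT_DATA":
            n_pd = int(tokens[1])
            if n_pd != n_points:
                raise StructuralError(
                    f"{path}: POINT_DATA count {n_pd} != POINTS {n_points}")
            _read_point_data(cur, n_pd, point_arrays, path)
        elif kw == "CELL_DATA" or kw == "FIELD":
            break
        # classic binary LINES come through read_values above
    if points is None:
        raise FormatError(f"{path}: no POINTS section")
    if lines_ids is None:
        raise FormatError(f"{path}: no fiber lines (LINES section missing)")

    fibers = [points[np.asarray(ids, dtype=int)] for ids in lines_ids]
    pd = {name: [arr[np.asarray(ids, dtype=int)] for ids in lines_ids]
          for name, arr in point_arrays.items()}
    return FiberBundle(fibers, pd)


def _split_classic_lines(flat: np.ndarray, n_lines: int):
    out, pos = [], 0
    for _ in range(n_lines):
        count = int(flat[pos])
        out.append(flat[pos + 1: pos + 1 + count])
        pos += 1 + count
    if pos != len(flat):
        raise StructuralError("LINES connectivity length mismatch")
    return out


def _read_point_data(cur: _Cursor, n: int, arrays: dict, path) -> None:
    while cur.pos < len(cur.blob):
        mark = cur.pos
        line = cur.next_section_line()
        if not line:
            return
        tokens = line.split()
        kw = tokens[0].upper()
        if kw == "SCALARS":
            name, vtk_type = tokens[1], tokens[2].lower()
            ncomp = int(tokens[3]) if len(tokens) > 3 else 1
            lut = cur.next_section_line()
            if not lut.upper().startswith("LOOKUP_TABLE"):
                cur.pos = mark  # malformed; bail out
                raise FormatError(f"{path}: SCALARS without LOOKUP_TABLE")
            vals = cur.read_values(n * ncomp, vtk_type)
            arrays[name] = vals.reshape(n, ncomp)[:, 0] if ncomp > 1 else vals
        elif kw == "FIELD":
            n_arr = int(tokens[2])
            for _ in range(n_arr):
                fa = cur.next_section_line().split()
                name, ncomp, tup, vtk_type = fa[0], int(fa[1]), int(fa[2]), \
                    fa[3].lower()
                vals = cur.read_values(ncomp * tup, vtk_type)
                if tup == n and ncomp == 1:
                    arrays[name] = vals
        else:
            cur.pos = mark
            return


def write_vtk_fibers(bundle: FiberBundle, path, binary: bool = False) -> None:
    """Write a FiberBundle as legacy VTK 4.x polydata (ASCII by default)."""
    points = bundle.all_points()
    counts = [len(f) for f in bundle.fibers]
    offsets = np.cumsum([0] + counts)
    with open(path, "wb") as fh:
        fh.write(b"# vtk DataFile Version 4.0\n")
        fh.write(b"tractokit fiber bundle\n")
        fh.write(b"BINARY\n" if binary else b"ASCII\n")
        fh.write(b"DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n".encode())
        _write_values(fh, points.ravel(), ">f8", binary, per_line=3)
        total = sum(c + 1 for c in counts)
        fh.write(f"LINES {len(counts)} {total}\n".encode())
        conn = []
        for i, c in enumerate(counts):
            conn.append(c)
            conn.extend(range(offsets[i], offsets[i] + c))
        _write_values(fh, np.array(conn, dtype=np.int64), ">i4", binary,
                      per_line=None, groups=counts)
        if bundle.point_data:
            fh.write(f"POINT_DATA {len(points)}\n".encode())
            for name, arrays in bundle.point_data.items():
                fh.write(f"SCALARS {name} double 1\n".encode())
                fh.write(b"LOOKUP_TABLE default\n")
                flat = np.concatenate(arrays) if arrays else np.zeros(0)
                _write_values(fh, flat, ">f8", binary, per_line=9)


def _write_values(fh, values, dtype, binary, per_line=9, groups=None):
    if binary:
        fh.write(np.asarray(values).astype(dtype).tobytes())
        fh.write(b"\n")
        return
    vals = np.asarray(values)
    fmt = (lambda x: repr(float(x))) if dtype.endswith("f8") \
        else (lambda x: str(int(x)))
    if groups is not None:
        pos = 0
        for c in groups:
            row = vals[pos:pos + c + 1]
            fh.write((" ".join(fmt(x) for x in row) + "\n").encode())
            pos += c + 1
    else:
        for start in range(0, len(vals), per_line):
            row = vals[start:start + per_line]
            fh.write((" ".join(fmt(x) for x in row) + "\n").encode())
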