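"""Minimal Wavefront OBJ and PLY mesh input/output.

Only the subset used by this package: triangulated geometry in OBJ, and
PLY (ascii or binary little-endian) with one per-face float scalar
property in addition to the vertex index list.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np


def write_obj(path, coords: np.ndarray, facets: np.ndarray) -> None:
    """Write vertices and triangular faces; indices exported 1-based."""
    coords = np.asarray(coords, dtype=float)
    facets = np.asarray(facets, dtype=int)
    with open(path, "w") as fh:
        for v in coords:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in facets:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path) -> tuple[np.ndarray, np.ndarray]:
    """Read vertices and triangular faces; returns 0-based facet indices."""
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise ValueError("only triangular faces are supported")
            faces.append(idx)
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


def write_ply(
    path,
    coords: np.ndarray,
    facets: np.ndarray,
    face_scalar: np.ndarray | None = None,
    scalar_name: str = "area_change_pct",
    binary: bool = False,
) -> None:
    """Write a triangulated mesh with an optional per-face float scalar."""
    coords = np.asarray(coords, dtype=float)
    facets = np.asarray(facets, dtype=int)
    if face_scalar is not None:
        face_scalar = np.asarray(face_scalar, dtype=float)
        if len(face_scalar) != len(facets):
            raise ValueError("face_scalar length must equal facet count")
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {len(coords)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(facets)}",
        "property list uchar int vertex_indices",
    ]
    if face_scalar is not None:
        header.append(f"property double {scalar_name}")
    header.append("end_header")

    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(coords.astype("<f8").tobytes())
            for i, f in enumerate(facets):
                fh.write(struct.pack("<B3i", 3, *f))
                if face_scalar is not None:
                    fh.write(struct.pack("<d", face_scalar[i]))
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for v in coords:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for i, f in enumerate(facets):
                line = f"3 {f[0]} {f[1]} {f[2]}"
                if face_scalar is not None:
                    line += f" {float(face_scalar[i])!r}"
                fh.write(line + "\n")


def read_ply(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read a PLY written by :func:`write_ply`.

    Returns (coords, facets, face_scalar or None). Supports only the
    element/property layout this package writes.
    """
    raw = Path(path).read_bytes()
    end = raw.index(b"end_header\n") + len(b"end_header\n")
    header = raw[:end].decode("ascii").splitlines()
    body = raw[end:]

    fmt = next(l.split()[1] for l in header if l.startswith("format"))
    n_vert = int(next(l.split()[2] for l in header if l.startswith("element vertex")))
    n_face = int(next(l.split()[2] for l in header if l.startswith("element face")))
    face_props = []
    in_face = False
    for l in header:
        if l.startswith("element"):
            in_face = l.startswith("element face")
        elif l.startswith("property") and in_face:
            face_props.append(l.split()[-1])
    has_scalar = len(face_props) > 1
    scalar = np.empty(n_face) if has_scalar else None
    faces = np.empty((n_face, 3), dtype=int)

    if fmt == "ascii":
        lines = body.decode("ascii").splitlines()
        coords = np.array([[float(x) for x in l.split()] for l in lines[:n_vert]])
        for i, l in enumerate(lines[n_vert : n_vert + n_face]):
            parts = l.split()
            faces[i] = [int(p) for p in parts[1:4]]
            if has_scalar:
                scalar[i] = float(parts[4])
    elif fmt == "binary_little_endian":
        nbytes = n_vert * 3 * 8
        coords = np.frombuffer(body[:nbytes], dtype="<f8").reshape(n_vert, 3).copy()
        off = nbytes
        rec = struct.Struct("<B3i" + ("d" if has_scalar else ""))
        for i in range(n_face):
            vals = rec.unpack_from(body, off)
            off += rec.size
            faces[i] = vals[1:4]
            if has_scalar:
                scalar[i] = vals[4]
    else:
        raise ValueError(f"unsupported PLY format {fmt!r}")
    return coords, faces, scalar
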