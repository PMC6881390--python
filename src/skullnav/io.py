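"""Readers and writers for triangle meshes (STL, OBJ) and landmark files.

Landmark files come in two dialects:

* plain CSV with header ``label,x,y,z[,frame]``
* Slicer-style markup control-point files (``.fcsv``), whose RAS
  coordinates are converted to the internal LPS convention by flipping
  the sign of x and y (controlled by ``convert_ras``).
"""

from __future__ import annotations

import csv
import struct
from pathlib import Path

import numpy as np

from .geometry import LandmarkSet, TriangleMesh, ValidationError

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "merge_vertices",
]

#: vertices closer than this (mm) are merged when reading facet soups
MERGE_TOL = 1e-6


def merge_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL):
    """Merge vertices closer than ``tol`` and remap faces.

    Quantizes coordinates onto a ``tol`` grid; first occurrence wins so the
    result is deterministic for a given input order.
    """
    keys = np.round(np.asarray(vertices, float) / tol).astype(np.int64)
    _, first_idx, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    # preserve original order of first occurrences
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = np.asarray(vertices, float)[first_idx[order]]
    new_faces = rank[inverse][np.asarray(faces, np.int64)]
    return new_vertices, new_faces


# ---------------------------------------------------------------------------
# STL

def _is_binary_stl(data: bytes) -> bool:
    if len(data) < 84:
        return False
    (n_tri,) = struct.unpack("<I", data[80:84])
    if len(data) == 84 + 50 * n_tri:
        return True
    # ASCII files start with "solid" and contain "facet"
    head = data[:512].lstrip()
    return not (head.startswith(b"solid") and b"facet" in data[:2048])


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    data = path.read_bytes()
    if _is_binary_stl(data):
        (n_tri,) = struct.unpack("<I", data[80:84])
        rec = np.frombuffer(data[84 : 84 + 50 * n_tri], dtype=np.uint8)
        rec = rec.reshape(n_tri, 50)
        floats = rec[:, :48].copy().view("<f4").reshape(n_tri, 12)
        tri = floats[:, 3:12].astype(float).reshape(-1, 3)
    else:
        verts = []
        for line in data.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if len(parts) == 4 and parts[0] == "vertex":
                verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if len(verts) % 3 != 0:
            raise ValidationError(f"{path}: ASCII STL vertex count not divisible by 3")
        tri = np.asarray(verts, float)
    if tri.size == 0:
        raise ValidationError(f"{path}: empty STL")
    faces = np.arange(tri.shape[0]).reshape(-1, 3)
    return merge_vertices(tri, faces)


def _write_stl(mesh: TriangleMesh, path: Path, ascii_: bool = False) -> None:
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    if ascii_:
        with open(path, "w") as fh:
            fh.write("solid skullnav\n")
            for nv, t in zip(n, tri):
                fh.write(f"  facet normal {nv[0]:.9e} {nv[1]:.9e} {nv[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid skullnav\n")
        return
    with open(path, "wb") as fh:
        fh.write(b"skullnav binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", mesh.n_faces))
        rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
        floats = np.concatenate([n, tri.reshape(-1, 9)], axis=1).astype("<f4")
        rec[:, :48] = floats.view(np.uint8).reshape(mesh.n_faces, 48)
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# OBJ

def _read_obj(path: Path, strict: bool = False) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
            elif parts[0] == "f":
                idx = []
                for token in parts[1:]:
                    i = int(token.split("/")[0])
                    idx.append(i - 1 if i > 0 else len(verts) + i)
                if len(idx) < 3:
                    raise ValidationError(f"{path}:{lineno}: face with <3 vertices")
                if len(idx) > 3 and strict:
                    raise ValidationError(
                        f"{path}:{lineno}: non-triangular face in strict mode"
                    )
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # vt / vn / mtllib / usemtl / o / g / s are tolerated and ignored
    if not verts or not faces:
        raise ValidationError(f"{path}: OBJ contains no geometry")
    return np.asarray(verts, float), np.asarray(faces, np.int64)


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("stl", "obj"):
        return suffix
    raise ValidationError(f"cannot infer mesh format from {path.name!r}")


def read_mesh(path, format: str = "auto", strict: bool = False) -> TriangleMesh:
    """Read an STL (ASCII or binary) or OBJ mesh.

    STL facet soups are welded: vertices within ``MERGE_TOL`` mm are merged
    so edge topology exists. Non-triangular OBJ faces are fan-triangulated
    unless ``strict`` is set.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    fmt = _detect_format(path, format)
    if fmt == "stl":
        v, f = _read_stl(path)
    elif fmt == "obj":
        v, f = _read_obj(path, strict=strict)
    else:
        raise ValidationError(f"unknown mesh format {fmt!r}")
    return TriangleMesh(v, f)


def write_mesh(mesh: TriangleMesh, path, format: str = "auto", ascii_stl: bool = False) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "stl":
        _write_stl(mesh, path, ascii_=ascii_stl)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        raise ValidationError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# Landmarks

def _detect_landmark_dialect(path: Path, dialect: str) -> str:
    if dialect != "auto":
        return dialect
    if path.suffix.lower() == ".fcsv":
        return "slicer-markup"
    return "csv"


def read_landmarks(path, dialect: str = "auto", convert_ras: bool = True) -> LandmarkSet:
    """Read a landmark file as a :class:`LandmarkSet`.

    The plain-CSV dialect expects header ``label,x,y,z`` with an optional
    ``frame`` column. The Slicer dialect parses markup control-point rows;
    when the file declares (or defaults to) RAS coordinates and
    ``convert_ras`` is true, x and y signs are flipped to the internal LPS
    convention.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"landmark file not found: {path}")
    dialect = _detect_landmark_dialect(path, dialect)
    if dialect == "csv":
        return _read_landmarks_csv(path)
    if dialect == "slicer-markup":
        return _read_landmarks_slicer(path, convert_ras=convert_ras)
    raise ValidationError(f"unknown landmark dialect {dialect!r}")


def _read_landmarks_csv(path: Path) -> LandmarkSet:
    labels, pts, frames = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: expected header label,x,y,z[,frame]")
        for row in reader:
            for c in ("x", "y", "z"):
                if row[c] is None or row[c].strip() == "":
                    raise ValidationError(f"{path}: missing coordinate for {row['label']!r}")
            labels.append(row["label"])
            pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            frames.append(row.get("frame") or "image")
    if not labels:
        raise ValidationError(f"{path}: no landmark rows")
    if len(set(frames)) > 1:
        raise ValidationError(f"{path}: mixed frames {sorted(set(frames))}")
    return LandmarkSet(labels, np.asarray(pts), frame=frames[0])


def _read_landmarks_slicer(path: Path, convert_ras: bool) -> LandmarkSet:
    coord_system = "RAS"
    labels, pts = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lower()
                if "coordinatesystem" in low:
                    coord_system = "LPS" if "lps" in low.split("=")[-1].lower() else "RAS"
                continue
            cols = line.split(",")
            if len(cols) < 4:
                raise ValidationError(f"{path}: malformed control-point row {line!r}")
            x, y, z = (float(cols[1]), float(cols[2]), float(cols[3]))
            label = cols[11] if len(cols) > 11 and cols[11] else cols[0]
            labels.append(label)
            pts.append([x, y, z])
    if not labels:
        raise ValidationError(f"{path}: no control points")
    points = np.asarray(pts, float)
    if coord_system == "RAS" and convert_ras:
        points = points * np.array([-1.0, -1.0, 1.0])
    return LandmarkSet(labels, points, frame="image")


def write_landmarks(landmarks: LandmarkSet, path, dialect: str = "auto",
                    convert_ras: bool = True) -> None:
    path = Path(path)
    dialect = _detect_landmark_dialect(path, dialect)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y", "z", "frame"])
            for label, p in zip(landmarks.labels, landmarks.points):
                writer.writerow(
                    [label, repr(float(p[0])), repr(float(p[1])), repr(float(p[2])),
                     landmarks.frame]
                )
        return
    if dialect == "slicer-markup":
        pts = landmarks.points
        if convert_ras:
            pts = pts * np.array([-1.0, -1.0, 1.0])
        with open(path, "w") as fh:
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = RAS\n")
            fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
            for i, (label, p) in enumerate(zip(landmarks.labels, pts), 1):
                fh.write(
                    f"vtkMRMLMarkupsFiducialNode_{i},"
                    f"{float(p[0])!r},{float(p[1])!r},{float(p[2])!r},"
                    f"0,0,0,1,1,1,0,{label},,\n"
                )
        return
    raise ValidationError(f"unknown landmark dialect {dialect!r}")
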