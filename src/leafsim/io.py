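"""Readers and writers for the package's on-disk formats.

Meshes go to Wavefront OBJ (text) or binary little-endian PLY; both store
float64 coordinates and uv so a write/read cycle reproduces vertices,
texture coordinates, and triangles bit-exactly.  Masks are 8-bit
single-channel PNG; color images are collapsed by integer ITU-R 601 luma.
Key points travel as JSON ``{"points": [[x, y], ...]}`` or two-column text.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
from PIL import Image

from .deformation import MaskMap
from .errors import InvalidInputError
from .meshing import TriMesh

__all__ = [
    "read_key_points",
    "write_key_points",
    "write_mesh",
    "read_mesh",
    "read_mask",
    "write_mask",
]


# ---------------------------------------------------------------------------
# key points
# ---------------------------------------------------------------------------

def read_key_points(path) -> np.ndarray:
    """Read (n, 2) points from JSON {"points": ...} or whitespace text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        pts = np.asarray(json.loads(text)["points"], dtype=float)
    else:
        pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError(f"{path}: expected two columns of coordinates")
    return pts


def write_key_points(points: np.ndarray, path) -> Path:
    path = Path(path)
    pts = np.asarray(points, dtype=float)
    path.write_text(json.dumps({"points": pts.tolist()}))
    return path


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, ".17g")


def _infer_format(path: Path, format: str | None) -> str:
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("obj", "ply"):
        raise InvalidInputError(f"unsupported mesh format {format!r}")
    return format


def write_mesh(mesh: TriMesh, path, format: str | None = None) -> Path:
    """Write a mesh as OBJ (v/vt/f, 1-based indices) or binary PLY."""
    path = Path(path)
    format = _infer_format(path, format)
    V = mesh.vertices3
    if format == "obj":
        lines = []
        for x, y, z in V:
            lines.append(f"v {_fmt(x)} {_fmt(y)} {_fmt(z)}")
        for u, v in mesh.uv:
            lines.append(f"vt {_fmt(u)} {_fmt(v)}")
        for a, b, c in mesh.triangles + 1:
            lines.append(f"f {a}/{a} {b}/{b} {c}/{c}")
        path.write_text("\n".join(lines) + "\n")
    else:
        header = (
            "ply\n"
            "format binary_little_endian 1.0\n"
            f"element vertex {len(V)}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "property double u\nproperty double v\n"
            f"element face {len(mesh.triangles)}\n"
            "property list uchar int vertex_indices\n"
            "end_header\n"
        )
        vdata = np.hstack([V, mesh.uv]).astype("<f8")
        fdtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
        fdata = np.empty(len(mesh.triangles), dtype=fdtype)
        fdata["n"] = 3
        fdata["idx"] = mesh.triangles
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(vdata.tobytes())
            fh.write(fdata.tobytes())
    return path


def read_mesh(path, format: str | None = None) -> TriMesh:
    """Read an OBJ or binary PLY written by :func:`write_mesh`.

    Boundary flags are recomputed from edge multiplicity (an edge used by a
    single triangle is a boundary edge).
    """
    path = Path(path)
    format = _infer_format(path, format)
    if format == "obj":
        verts, uvs, faces = [], [], []
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "vt":
                uvs.append([float(p) for p in parts[1:3]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
        V = np.asarray(verts, dtype=float)
        uv = np.asarray(uvs, dtype=float) if uvs else np.zeros((len(V), 2))
        T = np.asarray(faces, dtype=np.int64)
    else:
        raw = path.read_bytes()
        end = raw.index(b"end_header\n") + len(b"end_header\n")
        header = raw[:end].decode("ascii").splitlines()
        nv = nf = 0
        for line in header:
            parts = line.split()
            if parts[:2] == ["element", "vertex"]:
                nv = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                nf = int(parts[2])
        body = raw[end:]
        vbytes = nv * 5 * 8
        vdata = np.frombuffer(body[:vbytes], dtype="<f8").reshape(nv, 5)
        fdtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
        fdata = np.frombuffer(body[vbytes:vbytes + nf * fdtype.itemsize], dtype=fdtype)
        V = vdata[:, :3].copy()
        uv = vdata[:, 3:].copy()
        T = fdata["idx"].astype(np.int64)
    if len(V) == 0 or len(T) == 0:
        raise InvalidInputError(f"{path}: empty mesh")
    edges = np.vstack([T[:, [0, 1]], T[:, [1, 2]], T[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = np.zeros(len(V), dtype=bool)
    boundary[np.unique(uniq[counts == 1])] = True
    return TriMesh(vertices=V, triangles=T, boundary=boundary, uv=uv)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path) -> MaskMap:
    """Read an image as an 8-bit grayscale mask.

    Multi-channel images collapse by integer luma
    round(0.299 R + 0.587 G + 0.114 B); alpha is ignored.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # noqa: BLE001 - map to the package's IO error
        raise OSError(f"cannot read mask image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        rgb = arr[:, :, :3].astype(float)
        gray = np.rint(
            0.299 * rgb[:, :, 0] + 0.587 * rgb[:, :, 1] + 0.114 * rgb[:, :, 2]
        ).astype(np.uint8)
    else:
        raise OSError(f"{path}: unsupported image layout {arr.shape}")
    return MaskMap(gray)


def write_mask(mask: MaskMap, path) -> Path:
    path = Path(path)
    Image.fromarray(mask.pixels, mode="L").save(path, format="PNG")
    return path
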