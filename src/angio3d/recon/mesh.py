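"""Frenet-frame tube meshing and ASCII STL / Wavefront OBJ export."""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import numpy as np


@dataclass
class TubeMesh:
    """Triangle mesh: (V, 3) float vertices, (F, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces reference invalid vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def build_tube(centerline3d, radii, N, B, subdivisions: int = 16,
               cap_ends: bool = True) -> TubeMesh:
    """Sweep circular rings along the centreline and stitch them.

    Ring vertices are ``X + r * (N cos(theta) + B sin(theta))`` at
    ``subdivisions`` equally spaced angles with spacing ``2*pi/s`` over
    ``[0, 2*pi)`` (no duplicated seam vertex); consecutive rings are joined by
    ``2*s`` triangles.  Optional triangle-fan end caps close the tube.
    """
    s = int(subdivisions)
    if s < 3:
        raise ValueError("need at least 3 subdivisions")
    X = np.asarray(centerline3d, dtype=float)
    r = np.asarray(radii, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    n = len(X)
    theta = 2 * np.pi * np.arange(s) / s
    ct, st = np.cos(theta), np.sin(theta)
    rings = (X[:, None, :]
             + r[:, None, None] * (np.asarray(N)[:, None, :] * ct[None, :, None]
                                   + np.asarray(B)[:, None, :] * st[None, :, None]))
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        a0 = i * s
        b0 = (i + 1) * s
        for k in range(s):
            k1 = (k + 1) % s
            faces.append((a0 + k, b0 + k, b0 + k1))
            faces.append((a0 + k, b0 + k1, a0 + k1))
    if cap_ends:
        c_start = len(verts)
        verts = np.vstack([verts, X[0], X[-1]])
        c_end = c_start + 1
        last = (n - 1) * s
        for k in range(s):
            k1 = (k + 1) % s
            faces.append((c_start, k1, k))           # start cap faces backwards
            faces.append((c_end, last + k, last + k1))
    return TubeMesh(verts, np.array(faces))


def export_mesh(mesh: TubeMesh, path, fmt: str | None = None) -> str:
    """Write a mesh as ASCII STL or Wavefront OBJ; format inferred from suffix."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to export an empty mesh")
    path = os.fspath(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt == "stl":
        _write_stl(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}; use 'stl' or 'obj'")
    return path


def _write_stl(mesh: TubeMesh, path: str) -> None:
    v = mesh.vertices
    with open(path, "w") as fh:
        fh.write("solid vessel\n")
        for f in mesh.faces:
            a, b, c = v[f[0]], v[f[1]], v[f[2]]
            nrm = np.cross(b - a, c - a)
            nn = np.linalg.norm(nrm)
            nrm = nrm / nn if nn > 0 else nrm
            fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
            fh.write("    outer loop\n")
            for p in (a, b, c):
                fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid vessel\n")


def _write_obj(mesh: TubeMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# angio3d tube mesh\n")
        for p in mesh.vertices:
            fh.write(f"v {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_mesh(path) -> TubeMesh:
    """Read back an ASCII STL (vertices deduplicated) or OBJ mesh."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    if ext == "obj":
        verts, faces = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "v":
                    verts.append([float(x) for x in parts[1:4]])
                elif parts[0] == "f":
                    faces.append([int(tok.split("/")[0]) - 1 for tok in parts[1:4]])
        return TubeMesh(np.array(verts), np.array(faces))
    if ext == "stl":
        tri_verts = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if parts and parts[0] == "vertex":
                    tri_verts.append([float(x) for x in parts[1:4]])
        tri_verts = np.array(tri_verts).reshape(-1, 3, 3)
        uniq, inverse = np.unique(tri_verts.reshape(-1, 3), axis=0, return_inverse=True)
        return TubeMesh(uniq, inverse.reshape(-1, 3))
    raise ValueError(f"unknown mesh format {ext!r}")


def _edge_face_counts(mesh: TubeMesh) -> Counter:
    counts: Counter = Counter()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            counts[(min(a, b), max(a, b))] += 1
    return counts


def is_edge_manifold(mesh: TubeMesh) -> bool:
    """True when every undirected edge is shared by at most two faces."""
    return all(c <= 2 for c in _edge_face_counts(mesh).values())


def is_watertight(mesh: TubeMesh) -> bool:
    """True when every undirected edge is shared by exactly two faces."""
    counts = _edge_face_counts(mesh)
    return bool(counts) and all(c == 2 for c in counts.values())
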