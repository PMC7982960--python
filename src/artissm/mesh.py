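"""Triangle-mesh containers, rigid/similarity transforms and mesh file I/O.

Vertex order is the correspondence carrier throughout the package: readers
and writers never deduplicate, reorder or re-index vertices (verified by
round-trip tests).  Units are millimetres everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh


class MeshFormatError(ValueError):
    """Raised when a mesh file violates the indexed-triangle-mesh contract."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface mesh for one anatomical component.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.  Ordering is semantically meaningful
        (dense correspondence), so it is preserved by every operation.
    faces : (F, 3) int array
        Triangles as vertex-index triples.
    name : str
        Component label (e.g. ``"MC3"``, ``"capsule"``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (F, 3) array of triangles")
        if len(self.vertices) <= 3:
            raise MeshFormatError("a surface mesh needs more than 3 vertices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError("face indices out of range")
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degen.any():
            raise MeshFormatError(f"degenerate triangle at face {int(np.flatnonzero(degen)[0])}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(np.asarray(vertices, float), self.faces.copy(), self.name)

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted face-normal average)."""
        vn = np.asarray(self.as_trimesh().vertex_normals, float)
        return vn / np.linalg.norm(vn, axis=1, keepdims=True)

    def signed_volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive for
        outward-oriented closed surfaces."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass
class RigidTransform:
    """A 4x4 homogeneous transform: rotation + translation, optionally with
    a uniform scale factor (similarity transform) when ``allow_scale``.

    The last row is always (0, 0, 0, 1); the linear block is ``s * R`` with
    R orthogonal.
    """

    matrix: np.ndarray
    allow_scale: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        A = self.matrix[:3, :3]
        s = np.cbrt(abs(np.linalg.det(A)))
        if not self.allow_scale and abs(s - 1.0) > 1e-6:
            raise ValueError("non-unit determinant in a transform declared rigid")
        R = A / s if s > 0 else A
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation block is not orthogonal")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_parts(cls, rotation: np.ndarray, translation: np.ndarray,
                   scale: float = 1.0) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = scale * np.asarray(rotation, float)
        m[:3, 3] = np.asarray(translation, float)
        return cls(m, allow_scale=(abs(scale - 1.0) > 1e-12))

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls.from_parts(np.eye(3), t)

    @classmethod
    def rotation_z(cls, theta: float) -> "RigidTransform":
        c, s = np.cos(theta), np.sin(theta)
        return cls.from_parts(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]), np.zeros(3))

    # -- accessors ----------------------------------------------------
    @property
    def scale(self) -> float:
        return float(np.cbrt(abs(np.linalg.det(self.matrix[:3, :3]))))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3] / self.scale

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra ------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix,
                              allow_scale=self.allow_scale or other.allow_scale)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix), allow_scale=self.allow_scale)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Directions: rotation only (scale and translation dropped)."""
        return np.asarray(vectors, float) @ self.rotation.T


def concatenate_meshes(meshes) -> TriangleMesh:
    """Stack meshes into one (faces re-indexed; vertex order preserved
    block-wise)."""
    meshes = list(meshes)
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.vstack(verts), np.vstack(faces), "concatenated")


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Map every vertex through the homogeneous transform; topology unchanged."""
    return mesh.with_vertices(t.apply_points(mesh.vertices))


def mirror_mesh(mesh: TriangleMesh, plane_normal) -> TriangleMesh:
    """Reflect through the plane through the origin with unit normal
    ``plane_normal``, reversing face winding so outward orientation is kept."""
    n = np.asarray(plane_normal, float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("plane normal must be a unit vector")
    v = mesh.vertices - 2.0 * np.outer(mesh.vertices @ n, n)
    f = mesh.faces[:, [0, 2, 1]].copy()
    return TriangleMesh(v, f, mesh.name)


# ----------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------

_FORMATS = ("ply", "obj", "stl", "vtk")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (supported: {_FORMATS})")
    return fmt


def _scan_ascii_polygons(path: str, fmt: str) -> None:
    # trimesh silently triangulates polygons; the correspondence contract
    # requires rejecting them instead, so pre-scan text formats.
    if fmt == "obj":
        with open(path, "r", errors="replace") as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("f "):
                    if len(line.split()) - 1 != 3:
                        raise MeshFormatError(f"non-triangular face at line {ln} of {path}")
    elif fmt == "ply":
        with open(path, "rb") as fh:
            header = fh.readline()
            if not header.startswith(b"ply"):
                raise MeshFormatError(f"{path} is not a PLY file")
            fmt_line = fh.readline()
            if b"ascii" not in fmt_line:
                return  # binary: face arity checked post-load
            n_vert = n_face = 0
            current = None
            for raw in fh:
                tok = raw.split()
                if tok[:1] == [b"element"]:
                    current = tok[1]
                    if current == b"vertex":
                        n_vert = int(tok[2])
                    elif current == b"face":
                        n_face = int(tok[2])
                elif tok[:1] == [b"end_header"]:
                    break
            for _ in range(n_vert):
                fh.readline()
            for k in range(n_face):
                tok = fh.readline().split()
                if tok and int(tok[0]) != 3:
                    raise MeshFormatError(f"non-triangular face {k} in {path}")


def read_mesh(path: str, fmt: str | None = None, name: str | None = None) -> TriangleMesh:
    """Read an indexed triangle mesh (PLY ascii/binary, OBJ, STL, legacy VTK).

    Vertex order is preserved exactly as stored in the file.  Note STL has no
    vertex indexing at all (a triangle soup), so it cannot carry
    correspondence; prefer PLY/OBJ/VTK for pipeline data.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    if fmt == "vtk":
        v, f = _read_vtk_polydata(path)
        return TriangleMesh(v, f, name)
    _scan_ascii_polygons(path, fmt)
    try:
        tm = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise IOError(f"could not read mesh file {path}: {exc}") from exc
    faces = np.asarray(tm.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshFormatError(f"{path} contains non-triangular faces")
    return TriangleMesh(np.asarray(tm.vertices, float), faces, name)


def write_mesh(mesh: TriangleMesh, path: str, fmt: str | None = None) -> None:
    """Write a mesh, preserving vertex order (PLY written as ascii)."""
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        _write_vtk_polydata(mesh, path)
        return
    tm = mesh.as_trimesh()
    if fmt == "ply":
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        tm.export(path, file_type=fmt)


def _read_vtk_polydata(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal legacy-VTK (ascii, POLYDATA with POINTS/POLYGONS) reader."""
    with open(path, "r", errors="replace") as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))
    upper = [t.upper() for t in tokens]
    try:
        pi = upper.index("POINTS")
        n_pts = int(tokens[pi + 1])
        coords = np.array(tokens[pi + 3: pi + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
        fi = upper.index("POLYGONS")
        n_poly = int(tokens[fi + 1])
        faces = []
        k = fi + 3
        for _ in range(n_poly):
            arity = int(tokens[k])
            if arity != 3:
                raise MeshFormatError(f"non-triangular polygon (arity {arity}) in {path}")
            faces.append([int(tokens[k + 1]), int(tokens[k + 2]), int(tokens[k + 3])])
            k += arity + 1
        return coords, np.asarray(faces, dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"could not parse legacy VTK polydata in {path}: {exc}") from exc


def _write_vtk_polydata(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.name or 'mesh'}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
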