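"""Surface-mesh container, STL I/O, and closed-surface area/volume.

Vascular surface models travel as STL in clinical shape-analysis work,
so this module reads and writes both STL dialects (binary and ASCII),
welds the per-facet duplicated vertices, and provides the area/volume
primitives every downstream morphometric needs.

Conventions
-----------
* Coordinates are millimetres; computation is float64 even though STL
  stores float32 (round-trips therefore tolerate float32 quantisation).
* Vertex welding is by exact coordinate match after float32
  quantisation — deterministic and tolerance-free.
* ``mesh_volume`` refuses open meshes rather than capping silently:
  a surface-area/volume ratio must be explicit about which surface it
  measures.  Use :func:`cap_open_boundaries` first.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MeshFormatError, MeshGeometryError

__all__ = [
    "SurfaceMesh",
    "read_stl",
    "write_stl",
    "mesh_surface_area",
    "mesh_volume",
    "boundary_edges",
    "cap_open_boundaries",
]

_BINARY_HEADER = 80
_FACET_BYTES = 50  # normal (12) + 3 vertices (36) + attribute count (2)


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (V, 3) mm and ``faces`` (F, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshGeometryError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshGeometryError(f"faces must be (F, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshGeometryError("face indices out of range")
        if f.size and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise MeshGeometryError("degenerate face (repeated vertex index)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def scaled(self, factor: float) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices * float(factor), self.faces)


def _weld(triangles: np.ndarray) -> SurfaceMesh:
    """Merge exactly-equal vertices of an (F, 3, 3) triangle soup."""
    flat = np.ascontiguousarray(triangles.reshape(-1, 3), dtype=np.float64)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    # np.unique sorts lexicographically; remap to first-appearance order so
    # reading is deterministic and independent of coordinate magnitudes.
    first = np.full(len(uniq), len(flat), dtype=np.int64)
    np.minimum.at(first, inverse, np.arange(len(flat)))
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return SurfaceMesh(uniq[order], rank[inverse].reshape(-1, 3))


def read_stl(path: str | Path) -> SurfaceMesh:
    """Read an ASCII or binary STL file, welding duplicated vertices.

    The dialect is detected from the file: a body whose length matches the
    declared binary facet count is binary; otherwise a leading ``solid``
    keyword selects the ASCII parser.  Malformed files raise
    :class:`MeshFormatError` naming the failing byte offset.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) >= _BINARY_HEADER + 4:
        (count,) = struct.unpack_from("<I", data, _BINARY_HEADER)
        if len(data) == _BINARY_HEADER + 4 + count * _FACET_BYTES:
            return _read_binary(data, count)
    if data[:5].lower() == b"solid":
        return _read_ascii(data.decode("ascii", errors="replace"))
    if len(data) >= _BINARY_HEADER + 4:
        (count,) = struct.unpack_from("<I", data, _BINARY_HEADER)
        raise MeshFormatError(
            f"binary STL truncated: header declares {count} facets "
            f"({_BINARY_HEADER + 4 + count * _FACET_BYTES} bytes) but file has "
            f"{len(data)} bytes (mismatch from byte offset {_BINARY_HEADER + 4})"
        )
    raise MeshFormatError(
        f"not an STL file: {len(data)} bytes, no binary header or 'solid' keyword"
    )


def _read_binary(data: bytes, count: int) -> SurfaceMesh:
    rec = np.dtype(
        [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
    )
    facets = np.frombuffer(data, dtype=rec, count=count, offset=_BINARY_HEADER + 4)
    return _weld(facets["verts"].astype(np.float64))


def _read_ascii(text: str) -> SurfaceMesh:
    triangles: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if tokens[0] == "vertex":
            if len(tokens) != 4:
                raise MeshFormatError(f"ASCII STL line {lineno}: bad vertex record")
            current.append([float(t) for t in tokens[1:4]])
        elif tokens[0] == "endfacet":
            if len(current) != 3:
                raise MeshFormatError(
                    f"ASCII STL line {lineno}: facet with {len(current)} vertices"
                )
            triangles.append(current)
            current = []
    if current:
        raise MeshFormatError("ASCII STL ended inside an open facet")
    if not triangles:
        raise MeshFormatError("ASCII STL contains no facets")
    return _weld(np.asarray(triangles, dtype=np.float64))


def write_stl(mesh: SurfaceMesh, path: str | Path, *, ascii: bool = False) -> None:
    """Write binary (default, little-endian) or ASCII STL."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    if ascii:
        lines = ["solid aorta_ssm"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid aorta_ssm")
        path.write_text("\n".join(lines) + "\n")
        return
    rec = np.dtype(
        [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
    )
    out = np.zeros(len(tri), dtype=rec)
    out["normal"] = normals.astype(np.float32)
    out["verts"] = tri.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(b"aorta_ssm binary STL".ljust(_BINARY_HEADER, b" "))
        fh.write(struct.pack("<I", len(tri)))
        fh.write(out.tobytes())


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area in mm² (sum of triangle areas)."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def boundary_edges(mesh: SurfaceMesh) -> np.ndarray:
    """Directed edges whose reverse is absent — (B, 2) array, empty if closed."""
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edge_set = set(map(tuple, directed))
    bound = [e for e in edge_set if (e[1], e[0]) not in edge_set]
    return np.asarray(bound, dtype=np.int64).reshape(-1, 2)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mm³ by the divergence-theorem tetrahedron sum.

    Requires a closed, consistently oriented mesh; the absolute value is
    returned so either orientation convention works.
    """
    nb = len(boundary_edges(mesh))
    if nb:
        raise MeshGeometryError(
            f"mesh_volume requires a closed surface; found {nb} boundary edges "
            "(cap_open_boundaries first)"
        )
    tri = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    return abs(float(signed.sum() / 6.0))


def _boundary_loops(mesh: SurfaceMesh) -> list[list[int]]:
    edges = boundary_edges(mesh)
    succ: dict[int, int] = {}
    for a, b in edges:
        if a in succ:
            raise MeshGeometryError(
                f"non-simple boundary: vertex {a} has multiple boundary successors"
            )
        succ[int(a)] = int(b)
    loops: list[list[int]] = []
    remaining = dict(succ)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        node = remaining.pop(start)
        while node != start:
            loop.append(node)
            if node not in remaining:
                raise MeshGeometryError("boundary loop is not closed")
            node = remaining.pop(node)
        loops.append(loop)
    return loops


def cap_open_boundaries(mesh: SurfaceMesh) -> SurfaceMesh:
    """Close every boundary loop with a triangle fan to the loop centroid.

    A closed mesh is returned unchanged.  The fan orientation reverses the
    boundary edges, so a consistently oriented input stays consistently
    oriented and :func:`mesh_volume` is well defined afterwards.
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    verts = [mesh.vertices]
    faces = [mesh.faces]
    next_idx = mesh.n_vertices
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None, :])
        ring = np.asarray(loop, dtype=np.int64)
        # boundary directed edge (a, b): cap triangle (b, a, centroid)
        fan = np.stack(
            [np.roll(ring, -1), ring, np.full(len(ring), next_idx, dtype=np.int64)],
            axis=1,
        )
        faces.append(fan)
        next_idx += 1
    return SurfaceMesh(np.concatenate(verts), np.concatenate(faces))
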