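"""Surface-mesh container, file I/O and synthetic organ-like mesh generation.

The deformable-organ pipeline operates on a closed triangulated surface mesh
(the high-resolution render model).  This module provides:

* :class:`SurfaceMesh` — the in-memory container (vertices, per-vertex unit
  normals, triangles);
* :func:`read_mesh` / :func:`write_mesh` — OBJ / PLY / STL file I/O (via
  trimesh, with vertex order preserved for the indexed formats);
* :func:`make_synthetic_organ` — watertight icosphere / ellipsoid / blob
  meshes at a controllable vertex count, standing in for CT-derived organ
  meshes when no real anatomy is at hand.

Vertex indices are 0-based everywhere internally; OBJ's 1-based indices are
converted at the file boundary by the loader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "make_synthetic_organ",
    "compute_vertex_normals",
    "geodesic_sphere",
]

_FORMATS = ("obj", "ply", "stl")


class MeshFormatError(ValueError):
    """A mesh file could not be parsed or violates basic consistency."""


def compute_vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex normals.

    Each triangle contributes its (unnormalized) cross-product normal — whose
    magnitude is twice the triangle area — to its three corners; the
    accumulated vectors are then normalized.  Vertices with no incident area
    (isolated or fully degenerate) get an arbitrary unit normal.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.int64)
    normals = np.zeros_like(vertices)
    if len(triangles):
        tri = vertices[triangles]  # (m, 3, 3)
        face_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        for k in range(3):
            np.add.at(normals, triangles[:, k], face_n)
    norms = np.linalg.norm(normals, axis=1)
    bad = norms < 1e-300
    normals[bad] = (0.0, 0.0, 1.0)
    norms[bad] = 1.0
    return normals / norms[:, None]


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-vertex unit normals.

    Attributes
    ----------
    vertices : (n_v, 3) float array, model units, world frame.
    normals : (n_v, 3) float array of unit vectors.
    triangles : (m, 3) int array of vertex indices (0-based).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.normals is None:
            self.normals = compute_vertex_normals(self.vertices, self.triangles)
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64).reshape(-1, 3)

    # -- basic queries -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy(), self.normals.copy())

    def validate(self) -> None:
        """Raise :class:`MeshFormatError` on violated invariants."""
        if self.n_vertices == 0:
            raise MeshFormatError("mesh has no vertices")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            bad = int(np.flatnonzero(
                (self.triangles < 0).any(axis=1)
                | (self.triangles >= self.n_vertices).any(axis=1)
            )[0])
            raise MeshFormatError(
                f"triangle {bad} references vertex {int(self.triangles[bad].max())} "
                f"of a mesh with {self.n_vertices} vertices"
            )
        if self.normals.shape != self.vertices.shape:
            raise MeshFormatError("normals array incongruent with vertices")
        n = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(n, 1.0, atol=1e-9):
            raise MeshFormatError("per-vertex normals are not unit length")

    def edge_use_counts(self) -> dict[tuple[int, int], int]:
        """Multiplicity of each undirected edge over all triangles."""
        counts: dict[tuple[int, int], int] = {}
        for a, b, c in self.triangles:
            for u, v in ((a, b), (b, c), (c, a)):
                key = (int(u), int(v)) if u < v else (int(v), int(u))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two triangles."""
        counts = self.edge_use_counts()
        return bool(counts) and all(c == 2 for c in counts.values())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles,
            vertex_normals=self.normals, process=False,
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {f!r}; expected one of {_FORMATS}")
    return f


def _weld_exact_duplicates(vertices: np.ndarray, triangles: np.ndarray):
    """Merge bitwise-identical vertices, first-appearance order (STL soup)."""
    seen: dict[bytes, int] = {}
    remap = np.empty(len(vertices), dtype=np.int64)
    kept = []
    for i, v in enumerate(vertices):
        key = v.tobytes()
        j = seen.get(key)
        if j is None:
            j = len(kept)
            seen[key] = j
            kept.append(v)
        remap[i] = j
    return np.array(kept, dtype=np.float64), remap[triangles]


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read an OBJ, PLY or STL surface mesh.

    Vertex order and indexing are preserved for OBJ and PLY.  STL is a
    triangle soup: exact duplicate corner positions are welded back into
    shared vertices in order of first appearance.  Normals are recomputed
    from geometry (area-weighted) — the pipeline only uses them as
    interpolation input.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load_mesh(str(path), file_type=f, process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise MeshFormatError(f"could not parse {path} as {f}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no mesh geometry")
        loaded = geoms[0]
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    triangles = np.asarray(loaded.faces, dtype=np.int64)
    if vertices.size == 0 or triangles.size == 0:
        raise MeshFormatError(f"{path}: empty or non-triangulated mesh")
    if f == "stl":
        vertices, triangles = _weld_exact_duplicates(vertices, triangles)
    mesh = SurfaceMesh(vertices, triangles)
    mesh.validate()
    return mesh


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Write ``mesh`` to OBJ, PLY (ascii) or STL (binary), preserving vertex order."""
    path = Path(path)
    f = _infer_format(path, fmt)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        if f == "ply":
            data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
            path.write_bytes(data)
        else:
            tm.export(str(path), file_type=f)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# synthetic organ-like meshes
# ---------------------------------------------------------------------------

def geodesic_sphere(frequency: int, radius: float = 1.0) -> SurfaceMesh:
    """Unit geodesic sphere from an icosahedron at integer *frequency* f.

    Each of the 20 icosahedral faces is subdivided into f² triangles on a
    barycentric grid and the grid points are projected onto the sphere,
    giving exactly 10 f² + 2 vertices and 20 f² triangles.  Shared edge
    points are generated once per undirected edge, so the mesh is watertight
    by construction (every edge used by exactly 2 triangles).
    """
    if frequency < 1:
        raise ValueError("frequency must be >= 1")
    ico = trimesh.creation.icosahedron()
    base_v = np.asarray(ico.vertices, dtype=np.float64)
    base_v /= np.linalg.norm(base_v, axis=1)[:, None]
    base_f = np.asarray(ico.faces, dtype=np.int64)

    f = frequency
    verts: list[np.ndarray] = [v for v in base_v]
    edge_points: dict[tuple[int, int], list[int]] = {}

    def edge_ids(a: int, b: int) -> list[int]:
        # points strictly between corners a and b, ordered from a to b
        key = (a, b) if a < b else (b, a)
        ids = edge_points.get(key)
        if ids is None:
            ids = []
            for i in range(1, f):
                p = ((f - i) * base_v[key[0]] + i * base_v[key[1]]) / f
                verts.append(p)
                ids.append(len(verts) - 1)
            edge_points[key] = ids
        return ids if (a, b) == key else ids[::-1]

    faces: list[tuple[int, int, int]] = []
    for a, b, c in base_f:
        a, b, c = int(a), int(b), int(c)
        ab, ac = edge_ids(a, b), edge_ids(a, c)
        bc = edge_ids(b, c)
        # grid[i][j]: barycentric point (f-i-j, i, j) in corners (a, b, c)
        grid: list[list[int]] = []
        for i in range(f + 1):  # steps toward b
            row: list[int] = []
            for j in range(f + 1 - i):  # steps toward c
                k = f - i - j
                if (i, j) == (0, 0):
                    row.append(a)
                elif (k, j) == (0, 0):
                    row.append(b)
                elif (k, i) == (0, 0):
                    row.append(c)
                elif k == 0:  # on edge b-c
                    row.append(bc[j - 1])
                elif j == 0:  # on edge a-b
                    row.append(ab[i - 1])
                elif i == 0:  # on edge a-c
                    row.append(ac[j - 1])
                else:  # interior
                    p = (k * base_v[a] + i * base_v[b] + j * base_v[c]) / f
                    verts.append(p)
                    row.append(len(verts) - 1)
            grid.append(row)
        for i in range(f):
            for j in range(f - i):
                faces.append((grid[i][j], grid[i + 1][j], grid[i][j + 1]))
                if j < f - i - 1:
                    faces.append((grid[i + 1][j], grid[i + 1][j + 1], grid[i][j + 1]))

    v = np.array(verts, dtype=np.float64)
    v = radius * v / np.linalg.norm(v, axis=1)[:, None]
    return SurfaceMesh(v, np.array(faces, dtype=np.int64))


def _smooth_radial_field(unit_dirs: np.ndarray, rng: np.random.Generator,
                         n_waves: int = 8) -> np.ndarray:
    """Smooth pseudo-random scalar field on the sphere, scaled to max |.| = 1."""
    field_vals = np.zeros(len(unit_dirs))
    for k in range(n_waves):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        freq = rng.uniform(1.0, 4.0)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        amp = 1.0 / (1.0 + k)
        field_vals += amp * np.cos(freq * (unit_dirs @ d) * math.pi + phase)
    m = np.abs(field_vals).max()
    return field_vals / m if m > 0 else field_vals


def make_synthetic_organ(kind: str, target_vertices: int, seed: int = 0,
                         bump_amplitude: float = 0.15) -> SurfaceMesh:
    """Watertight organ-like test mesh with ~``target_vertices`` vertices.

    Parameters
    ----------
    kind : ``"icosphere"``, ``"ellipsoid"`` or ``"blob"``.
        * icosphere — geodesic unit sphere;
        * ellipsoid — the sphere scaled by (1.0, 0.62, 0.45), a flattened
          lobed aspect ratio in the range of a liver-like organ;
        * blob — sphere with a smooth pseudo-random radial perturbation of
          relative amplitude ``bump_amplitude`` (deterministic in ``seed``).
    target_vertices : desired vertex count; the generator picks the geodesic
        frequency f with 10 f² + 2 closest to it (guaranteed within 20%).
    """
    if kind not in ("icosphere", "ellipsoid", "blob"):
        raise ValueError(f"unknown synthetic mesh kind {kind!r}")
    if target_vertices < 12:
        raise ValueError("target_vertices must be >= 12")
    f = max(1, round(math.sqrt((target_vertices - 2) / 10.0)))
    # pick the better of f and f+1 (rounding of sqrt can land either side)
    best = min((f, f + 1), key=lambda q: abs(10 * q * q + 2 - target_vertices))
    mesh = geodesic_sphere(best)
    if kind == "icosphere":
        return mesh
    if kind == "ellipsoid":
        v = mesh.vertices * np.array([1.0, 0.62, 0.45])
        return SurfaceMesh(v, mesh.triangles)
    rng = np.random.default_rng(seed)
    radial = 1.0 + bump_amplitude * _smooth_radial_field(mesh.vertices, rng)
    return SurfaceMesh(mesh.vertices * radial[:, None], mesh.triangles)
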