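"""Hierarchical cube lattice over a closed surface mesh.

The deformation model does not simulate the render mesh directly.  Instead a
padded axis-aligned bounding cube of the organ is subdivided octree-fashion:
cells crossed by the surface subdivide down to ``max_level`` (level 0 = the
root, largest cubes), cells entirely inside the organ stop subdividing and
become coarse *inside* cubes, and cells entirely outside are discarded.
After construction every render-mesh vertex is assigned to the unique
finest-level cube containing it (half-open extents break ties), and cubes
holding at least one vertex are labeled *surface* — the count of those is
``n_c``, the quantity the performance model is parameterized by.

Each assigned vertex also stores its normalized cube-local coordinates

    P_local = (P - C0) / L

with ``C0`` the cube origin corner and ``L`` the cube edge; these are the
interpolation coordinates consumed by the mapping module.

Corner particles are pooled and deduplicated exactly (integer lattice keys at
the finest resolution), so adjacent cubes share corner particles and the PBD
solver couples them automatically.  Corners of fine cubes lying on faces of
coarse neighbors (hanging nodes) remain independent particles; per-cube shape
matching needs no T-junction constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import SurfaceMesh

__all__ = [
    "CORNER_OFFSETS",
    "Cube",
    "OctreeLattice",
    "TopologyError",
    "AssignmentError",
    "build_octree",
    "classify_and_assign",
    "local_coordinates",
    "triangle_box_overlap",
    "winding_numbers",
]

# Fixed corner convention, in cube-local units.  The x axis blends corner
# pairs (0,1), (2,3), (4,5), (6,7); y blends across those; z blends last —
# the only ordering consistent with the cascaded-lerp interpolation formulas.
CORNER_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int64)


class TopologyError(ValueError):
    """The mesh is unsuitable for inside/outside classification."""


class AssignmentError(RuntimeError):
    """A mesh vertex fell in no retained cube (root padding too small)."""


@dataclass
class Cube:
    """One lattice cube.

    ``level`` 0 is the root (largest) size; ``edge_length`` equals
    ``root_edge / 2**level``.  ``cell`` is the integer grid index of the cube
    at its own level.  ``region`` is ``"surface"`` iff at least one mesh
    vertex is assigned to the cube; ``crosses_surface`` records the geometric
    fact that a mesh triangle overlaps the cube (surface cubes are always at
    the finest level).
    """

    level: int
    cell: tuple[int, int, int]
    origin: np.ndarray
    edge_length: float
    corner_ids: np.ndarray
    region: str = "inside"
    crosses_surface: bool = False


@dataclass
class OctreeLattice:
    """Cube hierarchy + shared corner pool + vertex assignment."""

    root_origin: np.ndarray
    root_edge: float
    max_level: int
    cubes: list[Cube]
    corner_rest_positions: np.ndarray  # (P, 3)
    vertex_assignment: np.ndarray = field(default=None)  # type: ignore[assignment]
    local_coords: np.ndarray = field(default=None)  # type: ignore[assignment]
    # finest-grid cell -> cube id, for cubes at max_level that cross the surface
    _cell_to_cube: dict = field(default_factory=dict, repr=False)

    # -- queries -------------------------------------------------------
    @property
    def n_corners(self) -> int:
        return len(self.corner_rest_positions)

    @property
    def surface_cube_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.cubes) if c.region == "surface"],
                        dtype=np.int64)

    @property
    def n_surface_cubes(self) -> int:
        """The paper-facing count n_c."""
        return int(sum(1 for c in self.cubes if c.region == "surface"))

    @property
    def finest_edge(self) -> float:
        return self.root_edge / (2 ** self.max_level)

    def cube_corners_rest(self, cube_id: int) -> np.ndarray:
        return self.corner_rest_positions[self.cubes[cube_id].corner_ids]

    def finest_cell_of_point(self, point) -> tuple[int, int, int]:
        """Half-open finest-grid cell containing ``point``."""
        idx = np.floor((np.asarray(point, dtype=np.float64) - self.root_origin)
                       / self.finest_edge).astype(np.int64)
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def find_boundary_cube(self, point) -> int | None:
        """Id of the finest-level surface-crossing cube containing ``point``."""
        return self._cell_to_cube.get(self.finest_cell_of_point(point))

    def level_table(self) -> dict[int, tuple[int, int]]:
        """Per-level (total cube count, surface cube count) breakdown."""
        table: dict[int, tuple[int, int]] = {}
        for c in self.cubes:
            tot, surf = table.get(c.level, (0, 0))
            table[c.level] = (tot + 1, surf + (c.region == "surface"))
        return dict(sorted(table.items()))

    # -- serialization -------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "root_origin": self.root_origin.tolist(),
            "root_edge": self.root_edge,
            "max_level": self.max_level,
            "corner_rest_positions": self.corner_rest_positions.tolist(),
            "cubes": [
                {
                    "level": c.level,
                    "cell": list(c.cell),
                    "edge_length": c.edge_length,
                    "origin": c.origin.tolist(),
                    "corner_ids": c.corner_ids.tolist(),
                    "region": c.region,
                    "crosses_surface": c.crosses_surface,
                }
                for c in self.cubes
            ],
            "vertex_assignment": None if self.vertex_assignment is None
            else self.vertex_assignment.tolist(),
            "local_coords": None if self.local_coords is None
            else self.local_coords.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "OctreeLattice":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        cubes = [
            Cube(
                level=c["level"], cell=tuple(c["cell"]),
                origin=np.array(c["origin"], dtype=np.float64),
                edge_length=c["edge_length"],
                corner_ids=np.array(c["corner_ids"], dtype=np.int64),
                region=c["region"], crosses_surface=c["crosses_surface"],
            )
            for c in doc["cubes"]
        ]
        lat = cls(
            root_origin=np.array(doc["root_origin"], dtype=np.float64),
            root_edge=float(doc["root_edge"]),
            max_level=int(doc["max_level"]),
            cubes=cubes,
            corner_rest_positions=np.array(doc["corner_rest_positions"], dtype=np.float64),
            vertex_assignment=None if doc["vertex_assignment"] is None
            else np.array(doc["vertex_assignment"], dtype=np.int64),
            local_coords=None if doc["local_coords"] is None
            else np.array(doc["local_coords"], dtype=np.float64),
        )
        lat._rebuild_cell_index()
        return lat

    def _rebuild_cell_index(self) -> None:
        self._cell_to_cube = {
            c.cell: i for i, c in enumerate(self.cubes)
            if c.level == self.max_level and c.crosses_surface
        }


def local_coordinates(vertex_position, cube: Cube) -> np.ndarray:
    """Normalized cube-local coordinates ``(P - C0) / L``.

    Values outside [0, 1] are permitted — the trilinear formula extrapolates;
    the mesh-partition module relies on that for duplicated boundary vertices.
    """
    if cube.edge_length <= 0:
        raise ValueError("cube edge_length must be positive")
    return (np.asarray(vertex_position, dtype=np.float64) - cube.origin) / cube.edge_length


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def triangle_box_overlap(box_origin, edge: float, triangles: np.ndarray) -> np.ndarray:
    """Vectorized separating-axis triangle / axis-aligned-cube overlap test.

    ``triangles`` is (m, 3, 3).  Returns a boolean mask of triangles whose
    closed triangle intersects the closed cube ``[origin, origin + edge]^3``.
    Standard 13-axis SAT: 3 box axes, the triangle plane, and the 9 cross
    products of box axes with triangle edges.
    """
    tri = np.asarray(triangles, dtype=np.float64)
    center = np.asarray(box_origin, dtype=np.float64) + edge / 2.0
    h = edge / 2.0
    v = tri - center  # (m, 3, 3)
    eps = 1e-12 * max(1.0, edge)

    ok = np.ones(len(tri), dtype=bool)
    # box axes
    for ax in range(3):
        lo = v[:, :, ax].min(axis=1)
        hi = v[:, :, ax].max(axis=1)
        ok &= (lo <= h + eps) & (hi >= -h - eps)
    # triangle plane
    e0 = v[:, 1] - v[:, 0]
    e1 = v[:, 2] - v[:, 1]
    e2 = v[:, 0] - v[:, 2]
    n = np.cross(e0, e1)
    d = np.einsum("ij,ij->i", n, v[:, 0])
    r = h * np.abs(n).sum(axis=1)
    ok &= np.abs(d) <= r + eps
    # 9 cross-axis tests: a = e_i x unit_axis_j
    for e in (e0, e1, e2):
        for ax in range(3):
            a = np.zeros_like(e)
            # cross(e, unit_ax): components
            a[:, (ax + 1) % 3] = e[:, (ax + 2) % 3]
            a[:, (ax + 2) % 3] = -e[:, (ax + 1) % 3]
            p = np.einsum("ij,ikj->ik", a, v)  # (m, 3) projections of corners
            rad = h * np.abs(a).sum(axis=1)
            ok &= (p.min(axis=1) <= rad + eps) & (p.max(axis=1) >= -rad - eps)
    return ok


def winding_numbers(points: np.ndarray, mesh: SurfaceMesh,
                    chunk: int = 2048) -> np.ndarray:
    """Generalized winding number of each query point w.r.t. the mesh.

    Sum of signed solid angles (van Oosterom–Strackee) over all triangles,
    divided by 4π.  For a watertight mesh this is ~1 inside and ~0 outside,
    robust to glancing rays where parity ray casting needs jitter.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.vertices[mesh.triangles]  # (m, 3, 3)
    out = np.empty(len(pts))
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]  # (q, 3)
        a = tri[None, :, 0] - p[:, None]  # (q, m, 3)
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("qmi,qmi->qm", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("qmi,qmi->qm", a, b) * lc
               + np.einsum("qmi,qmi->qm", b, c) * la
               + np.einsum("qmi,qmi->qm", c, a) * lb)
        out[s:s + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_octree(mesh: SurfaceMesh, max_level: int,
                 root_padding: float = 0.02) -> OctreeLattice:
    """Build the cube lattice over ``mesh`` and assign its vertices.

    The root cube is the axis-aligned bounding cube of the mesh padded by
    ``root_padding`` (fraction of the edge) so no vertex sits on the outer
    boundary.  Cells crossed by a triangle subdivide until ``max_level``;
    cells with no triangle are classified by the winding number of their
    center — entirely-inside cells become inside cubes at their current
    level, entirely-outside cells are discarded.
    """
    if not 0 <= max_level <= 8:
        raise ValueError("max_level must be in [0, 8]")
    if not mesh.is_watertight():
        raise TopologyError("mesh is not watertight; inside/outside tests undefined")

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    edge = float((hi - lo).max()) * (1.0 + 2.0 * root_padding)
    if edge <= 0:
        raise TopologyError("mesh has zero spatial extent")
    root_origin = (lo + hi) / 2.0 - edge / 2.0

    tri = mesh.vertices[mesh.triangles]
    boundary: list[tuple[int, int, int]] = []   # finest-level crossed cells
    empty: list[tuple[int, tuple[int, int, int]]] = []  # (level, cell)

    def recurse(level: int, cell: tuple[int, int, int], tri_idx: np.ndarray) -> None:
        L = edge / (2 ** level)
        origin = root_origin + np.array(cell, dtype=np.float64) * L
        mask = triangle_box_overlap(origin, L, tri[tri_idx])
        hits = tri_idx[mask]
        if len(hits) == 0:
            empty.append((level, cell))
            return
        if level == max_level:
            boundary.append(cell)
            return
        i, j, k = cell
        for off in CORNER_OFFSETS:
            recurse(level + 1, (2 * i + int(off[0]), 2 * j + int(off[1]),
                                2 * k + int(off[2])), hits)

    recurse(0, (0, 0, 0), np.arange(len(tri)))

    # classify triangle-free cells by their center point
    inside: list[tuple[int, tuple[int, int, int]]] = []
    if empty:
        centers = np.array([
            root_origin + (np.array(cell) + 0.5) * (edge / (2 ** lvl))
            for lvl, cell in empty])
        w = winding_numbers(centers, mesh)
        for (lvl_cell, wi) in zip(empty, w):
            if wi > 0.5:
                inside.append(lvl_cell)

    # assemble cubes in deterministic order: inside (level, cell) first by
    # level then cell, then boundary leaves by cell
    records = sorted(((lvl, cell, False) for lvl, cell in inside)) + \
        sorted(((max_level, cell, True) for cell in boundary))

    corner_pool: dict[tuple[int, int, int], int] = {}
    corner_keys: list[tuple[int, int, int]] = []

    def corner_id(key: tuple[int, int, int]) -> int:
        idx = corner_pool.get(key)
        if idx is None:
            idx = len(corner_keys)
            corner_pool[key] = idx
            corner_keys.append(key)
        return idx

    cubes: list[Cube] = []
    for lvl, cell, crosses in records:
        scale = 2 ** (max_level - lvl)
        L = edge / (2 ** lvl)
        origin = root_origin + np.array(cell, dtype=np.float64) * L
        base = np.array(cell, dtype=np.int64) * scale
        ids = np.array([corner_id(tuple(base + off * scale))
                        for off in CORNER_OFFSETS], dtype=np.int64)
        cubes.append(Cube(level=lvl, cell=tuple(int(x) for x in cell),
                          origin=origin, edge_length=L, corner_ids=ids,
                          crosses_surface=crosses))

    finest = edge / (2 ** max_level)
    corner_rest = root_origin + np.array(corner_keys, dtype=np.float64) * finest

    lattice = OctreeLattice(
        root_origin=root_origin, root_edge=edge, max_level=max_level,
        cubes=cubes, corner_rest_positions=corner_rest,
    )
    lattice._rebuild_cell_index()
    return classify_and_assign(lattice, mesh)


def classify_and_assign(lattice: OctreeLattice, mesh: SurfaceMesh) -> OctreeLattice:
    """Assign every mesh vertex to its containing finest-level cube.

    Containment uses half-open extents ``[origin, origin + L)`` per axis, so
    a vertex exactly on a shared face goes to the cube where that coordinate
    maps to local 0.  Cubes owning at least one vertex are labeled
    ``surface``; all others ``inside``.
    """
    n = mesh.n_vertices
    assignment = np.empty(n, dtype=np.int64)
    locals_ = np.empty((n, 3), dtype=np.float64)
    for vi in range(n):
        cube_id = lattice.find_boundary_cube(mesh.vertices[vi])
        if cube_id is None:
            raise AssignmentError(
                f"vertex {vi} at {mesh.vertices[vi]} falls in no retained cube; "
                "increase root_padding")
        assignment[vi] = cube_id
        locals_[vi] = local_coordinates(mesh.vertices[vi], lattice.cubes[cube_id])
    lattice.vertex_assignment = assignment
    lattice.local_coords = locals_
    counts = np.bincount(assignment, minlength=len(lattice.cubes))
    for i, c in enumerate(lattice.cubes):
        c.region = "surface" if counts[i] > 0 else "inside"
    return lattice


def format_level_table(lattice: OctreeLattice) -> str:
    """Human-readable per-level breakdown (surface counts in parentheses)."""
    lines = []
    total = surf_total = 0
    for lvl, (tot, surf) in lattice.level_table().items():
        total += tot
        surf_total += surf
        lines.append(f"Cube level {lvl}: {tot}" + (f" ({surf})" if surf else ""))
    lines.append(f"Total: {total} ({surf_total})")
    return "\n".join(lines)
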