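"""Splitting the render mesh into per-cube pieces and welding it back.

The batched mapping path needs the mesh cut into fragments that each live in
exactly one surface cube, because the 8 corner coordinates driving the
interpolation differ per cube (this mirrors splitting a single render object
into one object per cube, each carrying its cube's corners as uniforms).

Triangles are assigned whole, by the cube containing their centroid under
the half-open rule (falling back to the first vertex's cube when the
centroid's cell is not a surface cube).  A triangle whose vertices straddle
several cubes therefore pulls its off-cube vertices into the piece, stored
with *extrapolated* local coordinates — trilinear extrapolation is well
defined, triangle count is conserved exactly, and the rest state round-trips
bit-tight.  Under deformation the duplicated boundary vertices only agree
across pieces if the shared cube face deforms consistently; the weld step
measures and reports those discrepancies rather than hiding them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import SurfaceMesh
from .mapping import MappedBatch
from .octree import OctreeLattice, local_coordinates

__all__ = [
    "MeshPiece",
    "PartitionError",
    "WeldError",
    "WeldReport",
    "split_mesh",
    "weld_pieces",
    "pieces_to_json",
    "pieces_from_json",
]


class PartitionError(RuntimeError):
    """A triangle could not be assigned to any surface cube."""


class WeldError(RuntimeError):
    """Mapped output incongruent with the pieces being welded."""


@dataclass
class MeshPiece:
    """Fragment of the render mesh bound to one surface cube.

    Vertices are stored as normalized cube-local coordinates (components may
    lie outside [0, 1] for duplicated boundary vertices).  ``global_ids``
    maps local rows to original mesh vertex indices; ``triangle_global_ids``
    records each local triangle's index in the original mesh so welding
    restores the exact original connectivity.  ``corner_ids`` snapshots the
    piece's cube corner indices into the lattice pool — everything the
    batched path needs travels with the piece.
    """

    cube_id: int
    corner_ids: np.ndarray        # (8,) into the lattice corner pool
    local_vertices: np.ndarray    # (k, 3)
    local_normals: np.ndarray     # (k, 3) rest normals
    triangles: np.ndarray         # (t, 3) into local rows
    global_ids: np.ndarray        # (k,)
    triangle_global_ids: np.ndarray  # (t,)


def split_mesh(mesh: SurfaceMesh, lattice: OctreeLattice) -> list[MeshPiece]:
    """Split ``mesh`` into per-surface-cube pieces.

    Pieces are ordered by ascending cube id and, within a piece, vertices by
    ascending global id (deterministic layout; the batched output order is
    fixed at split time).  Pieces with zero triangles are omitted.
    """
    if lattice.vertex_assignment is None:
        raise PartitionError("lattice has no vertex assignment; build/classify first")
    surface_ids = set(int(i) for i in lattice.surface_cube_ids)
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)

    tri_cube = np.empty(mesh.n_triangles, dtype=np.int64)
    for ti in range(mesh.n_triangles):
        cid = lattice.find_boundary_cube(centroids[ti])
        if cid is None or cid not in surface_ids:
            cid = int(lattice.vertex_assignment[mesh.triangles[ti, 0]])
        if cid not in surface_ids:
            raise PartitionError(
                f"triangle {ti}: neither centroid cell nor first vertex lies "
                "in a surface cube")
        tri_cube[ti] = cid

    pieces: list[MeshPiece] = []
    for cid in sorted(set(int(c) for c in tri_cube)):
        tri_sel = np.flatnonzero(tri_cube == cid)
        tris = mesh.triangles[tri_sel]
        gids = np.unique(tris)  # ascending global id
        row_of = {int(g): i for i, g in enumerate(gids)}
        local_tris = np.vectorize(row_of.__getitem__)(tris)
        cube = lattice.cubes[cid]
        loc = np.array([local_coordinates(mesh.vertices[g], cube) for g in gids])
        pieces.append(MeshPiece(
            cube_id=cid,
            corner_ids=cube.corner_ids.copy(),
            local_vertices=loc,
            local_normals=mesh.normals[gids].copy(),
            triangles=local_tris.astype(np.int64),
            global_ids=gids.astype(np.int64),
            triangle_global_ids=tri_sel.astype(np.int64),
        ))
    return pieces


@dataclass
class WeldReport:
    """Cross-piece agreement of duplicated boundary vertices after mapping."""

    duplicated_ids: np.ndarray            # global ids appearing in >1 piece
    discrepancy: dict[int, float]         # global id -> max pairwise distance
    max_discrepancy: float

    def discrepant_ids(self, tol: float = 1e-6) -> list[int]:
        return [g for g, d in self.discrepancy.items() if d > tol]


def weld_pieces(pieces: list[MeshPiece], mapped: MappedBatch) -> tuple[SurfaceMesh, WeldReport]:
    """Re-assemble one mesh from mapped pieces.

    Duplicated boundary vertices are averaged; the report carries their
    per-vertex maximum pairwise distance so seams that crack under
    deformation are visible, not silently repaired.  Original triangle order
    and connectivity are restored exactly.
    """
    total = sum(len(p.local_vertices) for p in pieces)
    if len(mapped.positions) != total or len(mapped.piece_slices) != len(pieces):
        raise WeldError("mapped batch incongruent with pieces")

    n_vertices = int(max(p.global_ids.max() for p in pieces)) + 1
    n_tris = int(max(p.triangle_global_ids.max() for p in pieces)) + 1

    pos_sum = np.zeros((n_vertices, 3))
    nrm_sum = np.zeros((n_vertices, 3))
    count = np.zeros(n_vertices)
    np.add.at(pos_sum, mapped.global_ids, mapped.positions)
    if mapped.normals is not None:
        np.add.at(nrm_sum, mapped.global_ids, mapped.normals)
    np.add.at(count, mapped.global_ids, 1.0)
    if (count == 0).any():
        missing = int(np.flatnonzero(count == 0)[0])
        raise WeldError(f"global vertex id {missing} missing from all pieces")
    positions = pos_sum / count[:, None]

    triangles = np.empty((n_tris, 3), dtype=np.int64)
    tri_seen = np.zeros(n_tris, dtype=bool)
    for p in pieces:
        triangles[p.triangle_global_ids] = p.global_ids[p.triangles]
        tri_seen[p.triangle_global_ids] = True
    if not tri_seen.all():
        raise WeldError(f"triangle {int(np.flatnonzero(~tri_seen)[0])} missing from all pieces")

    # discrepancy among duplicates
    dup_ids = np.flatnonzero(count > 1)
    disc: dict[int, float] = {}
    max_disc = 0.0
    if len(dup_ids):
        by_gid: dict[int, list[np.ndarray]] = {}
        dup_set = set(int(g) for g in dup_ids)
        for gid, p in zip(mapped.global_ids, mapped.positions):
            g = int(gid)
            if g in dup_set:
                by_gid.setdefault(g, []).append(p)
        for g, ps in by_gid.items():
            arr = np.array(ps)
            d = float(np.linalg.norm(arr[:, None] - arr[None, :], axis=2).max())
            disc[g] = d
            max_disc = max(max_disc, d)

    if mapped.normals is not None:
        norms = np.linalg.norm(nrm_sum, axis=1)
        bad = norms < 1e-12
        nrm_sum[bad] = (0.0, 0.0, 1.0)
        norms[bad] = 1.0
        normals = nrm_sum / norms[:, None]
    else:
        normals = None

    mesh = SurfaceMesh(positions, triangles, normals)
    report = WeldReport(duplicated_ids=dup_ids, discrepancy=disc,
                        max_discrepancy=max_disc)
    return mesh, report


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def pieces_to_json(pieces: list[MeshPiece], path=None) -> str:
    doc = [
        {
            "cube_id": p.cube_id,
            "corner_ids": p.corner_ids.tolist(),
            "local_vertices": p.local_vertices.tolist(),
            "local_normals": p.local_normals.tolist(),
            "triangles": p.triangles.tolist(),
            "global_ids": p.global_ids.tolist(),
            "triangle_global_ids": p.triangle_global_ids.tolist(),
        }
        for p in pieces
    ]
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def pieces_from_json(source) -> list[MeshPiece]:
    if isinstance(source, (str, Path)) and Path(source).exists():
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    return [
        MeshPiece(
            cube_id=int(p["cube_id"]),
            corner_ids=np.array(p["corner_ids"], dtype=np.int64),
            local_vertices=np.array(p["local_vertices"], dtype=np.float64),
            local_normals=np.array(p["local_normals"], dtype=np.float64),
            triangles=np.array(p["triangles"], dtype=np.int64),
            global_ids=np.array(p["global_ids"], dtype=np.int64),
            triangle_global_ids=np.array(p["triangle_global_ids"], dtype=np.int64),
        )
        for p in doc
    ]
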