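"""Trilinear deformation mapping from lattice corners to render-mesh vertices.

Once the PBD solver has moved the lattice corners, every render-mesh vertex
is carried along by trilinear interpolation of the 8 deformed corners
C'_0 … C'_7 of its cube, evaluated at the vertex's normalized cube-local
coordinates (x, y, z).  The cascaded-lerp form used throughout is

    D0 = x (C'1 − C'0) + C'0        D1 = x (C'3 − C'2) + C'2
    D2 = x (C'5 − C'4) + C'4        D3 = x (C'7 − C'6) + C'6
    D4 = y (D1 − D0) + D0           D5 = y (D3 − D2) + D2
    P' = z (D5 − D4) + D4

which is algebraically the weight sum Σ_i w_i C'_i with the usual trilinear
weights.  Two code paths compute it:

* :func:`map_vertices_reference` — a per-vertex scalar loop (the CPU-style
  reference path);
* :func:`map_vertices_batched` — per mesh piece, gathers the piece's 8 cube
  corners once and transforms all its vertices in one vectorized evaluation
  (the vertex-shader-style path; the 8 corner positions play the role of the
  per-object uniforms uploaded to the GPU).

Their agreement on identical inputs is the module's central contract.

Normals: the trilinear map is not rigid, so normals must be transformed too.
The default mode pushes each rest normal through the inverse-transpose of
the interpolation Jacobian at the vertex (exact for the induced surface
deformation, reduces to a rotation for rigid cages); an alternative
``"trilinear"`` mode blends cube-corner-accumulated rest normals, rotated by
the cube's best-fit rotation, with the same trilinear weights.  Both modes
renormalize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .octree import CORNER_OFFSETS, OctreeLattice
from .pbd import LatticeState, extract_rotation

__all__ = [
    "trilinear_point",
    "trilinear_points",
    "trilinear_jacobian",
    "map_vertices_reference",
    "map_vertices_batched",
    "MappedBatch",
    "build_corner_normals",
    "MappingContractError",
]

NORMAL_MODES = ("jacobian", "trilinear")


class MappingContractError(RuntimeError):
    """A vertex or piece references a cube it must not."""


# ---------------------------------------------------------------------------
# the interpolation formula
# ---------------------------------------------------------------------------

def trilinear_point(local, corners) -> np.ndarray:
    """Cascaded-lerp trilinear interpolation of one point (scalar path).

    ``local`` may lie outside [0, 1]; the formula extrapolates.
    """
    local = np.asarray(local, dtype=np.float64)
    c = np.asarray(corners, dtype=np.float64)
    if not np.isfinite(local).all() or not np.isfinite(c).all():
        raise FloatingPointError("non-finite input to trilinear interpolation")
    x, y, z = local
    d0 = x * (c[1] - c[0]) + c[0]
    d1 = x * (c[3] - c[2]) + c[2]
    d2 = x * (c[5] - c[4]) + c[4]
    d3 = x * (c[7] - c[6]) + c[6]
    d4 = y * (d1 - d0) + d0
    d5 = y * (d3 - d2) + d2
    return z * (d5 - d4) + d4


def trilinear_points(locals_: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Vectorized cascade: (n, 3) locals against one (8, 3) corner set."""
    loc = np.asarray(locals_, dtype=np.float64).reshape(-1, 3)
    c = np.asarray(corners, dtype=np.float64)
    x = loc[:, 0:1]
    y = loc[:, 1:2]
    z = loc[:, 2:3]
    d0 = x * (c[1] - c[0]) + c[0]
    d1 = x * (c[3] - c[2]) + c[2]
    d2 = x * (c[5] - c[4]) + c[4]
    d3 = x * (c[7] - c[6]) + c[6]
    d4 = y * (d1 - d0) + d0
    d5 = y * (d3 - d2) + d2
    return z * (d5 - d4) + d4


def trilinear_jacobian(locals_: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """∂P'/∂local of the trilinear map: (n, 3, 3), columns d/dx, d/dy, d/dz."""
    loc = np.asarray(locals_, dtype=np.float64).reshape(-1, 3)
    c = np.asarray(corners, dtype=np.float64)
    x = loc[:, 0:1]
    y = loc[:, 1:2]
    z = loc[:, 2:3]
    ex0, ex1 = c[1] - c[0], c[3] - c[2]
    ex2, ex3 = c[5] - c[4], c[7] - c[6]
    dx = (1 - z) * ((1 - y) * ex0 + y * ex1) + z * ((1 - y) * ex2 + y * ex3)
    d0 = x * ex0 + c[0]
    d1 = x * ex1 + c[2]
    d2 = x * ex2 + c[4]
    d3 = x * ex3 + c[6]
    dy = (1 - z) * (d1 - d0) + z * (d3 - d2)
    dz = (y * (d3 - d2) + d2) - (y * (d1 - d0) + d0)
    return np.stack([dx, dy, dz], axis=2)


def _trilinear_weights(locals_: np.ndarray) -> np.ndarray:
    """(n, 8) product-form weights matching the corner convention."""
    loc = np.asarray(locals_, dtype=np.float64).reshape(-1, 3)
    w = np.empty((len(loc), 8))
    for i, off in enumerate(CORNER_OFFSETS):
        fx = loc[:, 0] if off[0] else 1.0 - loc[:, 0]
        fy = loc[:, 1] if off[1] else 1.0 - loc[:, 1]
        fz = loc[:, 2] if off[2] else 1.0 - loc[:, 2]
        w[:, i] = fx * fy * fz
    return w


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------

def build_corner_normals(lattice: OctreeLattice, rest_normals: np.ndarray) -> dict[int, np.ndarray]:
    """Per surface cube, rest normals accumulated onto the 8 corners.

    Each assigned vertex deposits its rest normal onto the cube corners with
    its trilinear weights; accumulated corner normals are normalized (zero
    accumulations stay zero and are skipped at blend time).  Used by the
    ``"trilinear"`` normal mode.
    """
    out: dict[int, np.ndarray] = {}
    assignment = lattice.vertex_assignment
    for cid in lattice.surface_cube_ids:
        sel = assignment == cid
        w = _trilinear_weights(lattice.local_coords[sel])  # (k, 8)
        acc = w.T @ rest_normals[sel]  # (8, 3)
        norms = np.linalg.norm(acc, axis=1)
        nz = norms > 1e-12
        acc[nz] /= norms[nz, None]
        out[int(cid)] = acc
    return out


def _normals_jacobian(locals_: np.ndarray, corners: np.ndarray,
                      rest_normals: np.ndarray) -> np.ndarray:
    jac = trilinear_jacobian(locals_, corners)
    out = np.empty_like(rest_normals)
    for i in range(len(out)):
        j = jac[i]
        try:
            n = np.linalg.solve(j.T, rest_normals[i])
        except np.linalg.LinAlgError:
            n = np.linalg.pinv(j.T) @ rest_normals[i]
        ln = np.linalg.norm(n)
        out[i] = n / ln if ln > 1e-12 else rest_normals[i]
    return out


def _normals_trilinear(locals_: np.ndarray, corners: np.ndarray,
                       rest_corners: np.ndarray, corner_normals: np.ndarray,
                       rest_normals: np.ndarray) -> np.ndarray:
    rc = rest_corners - rest_corners.mean(axis=0)
    cc = corners - corners.mean(axis=0)
    r = extract_rotation(cc, rc)
    rotated = corner_normals @ r.T
    blended = _trilinear_weights(locals_) @ rotated
    norms = np.linalg.norm(blended, axis=1)
    bad = norms <= 1e-12
    blended[bad] = rest_normals[bad]
    norms[bad] = np.linalg.norm(rest_normals[bad], axis=1)
    return blended / norms[:, None]


# ---------------------------------------------------------------------------
# mapping paths
# ---------------------------------------------------------------------------

def map_vertices_reference(source, state: LatticeState,
                           rest_normals: np.ndarray | None = None,
                           normal_mode: str = "jacobian"):
    """Per-vertex (CPU-style) mapping, looping one vertex at a time.

    ``source`` is either an :class:`~octodeform.octree.OctreeLattice` (each
    mesh vertex mapped through its *assigned* cube; output in original
    vertex order) or a list of mesh pieces (each piece row mapped through
    the piece's cube with the scalar cascade; output in batch row order —
    the apples-to-apples reference for :func:`map_vertices_batched`, since
    duplicated boundary vertices then go through the same neighbor cube on
    both paths).  Returns ``(positions, normals)``; ``normals`` is None when
    ``rest_normals`` is not supplied (for pieces, rest normals travel with
    the piece).
    """
    if normal_mode not in NORMAL_MODES:
        raise ValueError(f"normal_mode must be one of {NORMAL_MODES}")
    if isinstance(source, (list, tuple)):
        # for pieces, rest normals travel with the piece; the argument only
        # switches normal computation on
        return _map_pieces_reference(source, state, normal_mode,
                                     want_normals=rest_normals is not None)
    lattice: OctreeLattice = source
    if lattice.vertex_assignment is None:
        raise MappingContractError("lattice has no vertex assignment")
    n = len(lattice.vertex_assignment)
    positions = np.empty((n, 3))
    for vi in range(n):
        cid = int(lattice.vertex_assignment[vi])
        cube = lattice.cubes[cid]
        if cube.region != "surface":
            raise MappingContractError(
                f"vertex {vi} references inside cube {cid}; mapping is only "
                "performed for surface-region cubes")
        corners = state.positions[cube.corner_ids]
        positions[vi] = trilinear_point(lattice.local_coords[vi], corners)
    normals = None
    if rest_normals is not None:
        normals = np.empty((n, 3))
        corner_normals = (build_corner_normals(lattice, rest_normals)
                          if normal_mode == "trilinear" else None)
        for cid in np.unique(lattice.vertex_assignment):
            sel = lattice.vertex_assignment == cid
            cube = lattice.cubes[int(cid)]
            corners = state.positions[cube.corner_ids]
            loc = lattice.local_coords[sel]
            if normal_mode == "jacobian":
                normals[sel] = _normals_jacobian(loc, corners, rest_normals[sel])
            else:
                rest_c = lattice.cube_corners_rest(int(cid))
                normals[sel] = _normals_trilinear(
                    loc, corners, rest_c, corner_normals[int(cid)], rest_normals[sel])
    return positions, normals


def _map_pieces_reference(pieces, state: LatticeState, normal_mode: str,
                          want_normals: bool = False):
    """Scalar per-row reference over pieces (see map_vertices_reference)."""
    total = sum(len(p.local_vertices) for p in pieces)
    positions = np.empty((total, 3))
    normals = np.empty((total, 3))
    have_normals = want_normals and len(pieces) > 0 and \
        all(p.local_normals is not None for p in pieces)
    row = 0
    for p in pieces:
        corners = state.positions[p.corner_ids]
        for i in range(len(p.local_vertices)):
            positions[row + i] = trilinear_point(p.local_vertices[i], corners)
        if have_normals:
            if normal_mode != "jacobian":
                raise ValueError("piece-based reference mapping supports the "
                                 "jacobian normal mode only")
            for i in range(len(p.local_vertices)):
                normals[row + i] = _normals_jacobian(
                    p.local_vertices[i:i + 1], corners, p.local_normals[i:i + 1])[0]
        row += len(p.local_vertices)
    return positions, (normals if have_normals else None)


@dataclass
class MappedBatch:
    """Output of the batched path, ordered by (piece, within-piece vertex)."""

    positions: np.ndarray       # (total piece vertices, 3)
    normals: np.ndarray | None  # congruent, or None
    global_ids: np.ndarray      # original mesh vertex id per output row
    piece_slices: list[slice]   # row range of each piece

    def scatter_to_global(self, n_vertices: int):
        """Average duplicated rows back onto original vertex indices."""
        pos = np.zeros((n_vertices, 3))
        cnt = np.zeros(n_vertices)
        np.add.at(pos, self.global_ids, self.positions)
        np.add.at(cnt, self.global_ids, 1.0)
        covered = cnt > 0
        pos[covered] /= cnt[covered, None]
        return pos, covered


def map_vertices_batched(pieces, state: LatticeState,
                         normal_mode: str = "jacobian",
                         corner_normals: dict[int, np.ndarray] | None = None,
                         rest_corners: dict[int, np.ndarray] | None = None) -> MappedBatch:
    """Batched (vertex-shader-style) mapping of mesh pieces.

    For each piece the 8 deformed corner positions of its single cube are
    gathered once, then all piece vertices are transformed in one vectorized
    evaluation — the in-software analog of uploading the corner coordinates
    as per-object uniforms and letting the vertex shader transform the
    piece's vertex buffer.

    ``corner_normals``/``rest_corners`` are only needed for the
    ``"trilinear"`` normal mode (see :func:`build_corner_normals` and the
    partition module, which records each piece's rest corners).
    """
    if normal_mode not in NORMAL_MODES:
        raise ValueError(f"normal_mode must be one of {NORMAL_MODES}")
    n_total = sum(len(p.local_vertices) for p in pieces)
    positions = np.empty((n_total, 3))
    normals = np.empty((n_total, 3))
    have_normals = all(p.local_normals is not None for p in pieces) and len(pieces) > 0
    global_ids = np.empty(n_total, dtype=np.int64)
    slices: list[slice] = []
    row = 0
    n_corners = len(state.positions)
    for p in pieces:
        k = len(p.local_vertices)
        sl = slice(row, row + k)
        slices.append(sl)
        if (p.corner_ids < 0).any() or (p.corner_ids >= n_corners).any():
            raise KeyError(f"piece for cube {p.cube_id} references corners "
                           f"missing from the state (pool size {n_corners})")
        corners = state.positions[p.corner_ids]
        positions[sl] = trilinear_points(p.local_vertices, corners)
        global_ids[sl] = p.global_ids
        if have_normals:
            if normal_mode == "jacobian":
                normals[sl] = _normals_jacobian(p.local_vertices, corners, p.local_normals)
            else:
                if corner_normals is None or rest_corners is None:
                    raise ValueError("trilinear normal mode needs corner_normals "
                                     "and rest_corners")
                normals[sl] = _normals_trilinear(
                    p.local_vertices, corners, rest_corners[p.cube_id],
                    corner_normals[p.cube_id], p.local_normals)
        row += k
    return MappedBatch(positions=positions,
                       normals=normals if have_normals else None,
                       global_ids=global_ids, piece_slices=slices)
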