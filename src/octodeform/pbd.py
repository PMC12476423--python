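"""Position-based dynamics on the cube lattice with per-cube shape matching.

Each simulation frame performs the classic PBD loop over the lattice corner
particles:

1. *predict* — integrate external acceleration (gravity) into velocities and
   take an explicit position prediction ``x + dt v``;
2. *project* — a configurable number of Gauss–Seidel sweeps; every cube
   contributes one shape-matching constraint pulling its 8 corners toward the
   best-fit rigid transform (rotation + translation) of the undeformed cube,
   and a tray plane clamps penetrating corners each sweep;
3. *update* — velocities from the position change, positions from the
   prediction.

The rotation of the best rigid fit is the polar factor of the covariance
``A = Σ m_i (p_i − c)(q_i − c_q)ᵀ`` between current and rest corner offsets
(computed via SVD with determinant correction, so reflections are never
returned).  Using the undeformed cube as the constraint makes the lattice
resist stretch, shear *and* bend without the overshoot that pure distance
constraints exhibit under large deformation.

Shared corners are single particles that receive corrections from every
incident cube, which is what couples the cubes into one elastic body.
Corners with ``inverse_mass == 0`` are pinned and never move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .octree import OctreeLattice

__all__ = [
    "LatticeState",
    "ShapeMatchingConstraint",
    "TrayPlane",
    "SimulationConfig",
    "DivergenceError",
    "predict",
    "extract_rotation",
    "project_shape_matching",
    "project_tray_collision",
    "build_constraints",
    "step",
    "kinetic_energy",
]


class DivergenceError(FloatingPointError):
    """The solver produced non-finite corner positions."""


@dataclass
class LatticeState:
    """Per-corner dynamic state of the lattice.

    ``positions`` are the current corner positions C'_i; ``predicted`` holds
    the candidate positions inside a step.  ``inverse_masses`` of 0 mark
    pinned corners.
    """

    positions: np.ndarray
    velocities: np.ndarray
    inverse_masses: np.ndarray
    predicted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64).reshape(-1, 3)
        self.inverse_masses = np.ascontiguousarray(self.inverse_masses, dtype=np.float64).ravel()
        if self.predicted is None:
            self.predicted = self.positions.copy()
        n = len(self.positions)
        if len(self.velocities) != n or len(self.inverse_masses) != n:
            raise ValueError("state arrays incongruent with corner pool")
        if (self.inverse_masses < 0).any():
            raise ValueError("inverse masses must be >= 0")

    @classmethod
    def from_lattice(cls, lattice: OctreeLattice) -> "LatticeState":
        """Rest state: corners at rest positions, zero velocity, unit masses."""
        n = lattice.n_corners
        return cls(lattice.corner_rest_positions.copy(), np.zeros((n, 3)), np.ones(n))

    def copy(self) -> "LatticeState":
        return LatticeState(self.positions.copy(), self.velocities.copy(),
                            self.inverse_masses.copy(), self.predicted.copy())


@dataclass(frozen=True)
class ShapeMatchingConstraint:
    """Rest shape of one cube as a PBD constraint.

    ``rest_offsets`` are the 8 rest corner positions relative to their rest
    centroid (they sum to zero and form an axis-aligned cube of edge L).
    """

    cube_id: int
    corner_ids: np.ndarray
    rest_offsets: np.ndarray
    stiffness: float

    def __post_init__(self) -> None:
        if not 0.0 < self.stiffness <= 1.0:
            raise ValueError("stiffness must be in (0, 1]")
        if np.abs(self.rest_offsets.sum(axis=0)).max() > 1e-9 * max(
                1.0, np.abs(self.rest_offsets).max()):
            raise ValueError("rest_offsets must be centered")


@dataclass(frozen=True)
class TrayPlane:
    """Collision plane (the tray the organ drops onto): point + unit normal."""

    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=np.float64)
        return (points - np.asarray(self.point, dtype=np.float64)) @ n


@dataclass(frozen=True)
class SimulationConfig:
    """Solver parameters for one run.

    dt is the frame interval (default 1/30 s, the 30 fps framing of the
    real-time target); 30 Gauss–Seidel iterations per frame keeps the
    constraint solve well-converged.  ``damping`` multiplies velocities each
    predict (1.0 = none); drop-on-tray scenarios use a light viscous value.
    """

    dt: float = 1.0 / 30.0
    solver_iterations: int = 30
    gravity: tuple[float, float, float] = (0.0, -9.8, 0.0)
    stiffness: float = 0.9
    tray: TrayPlane | None = None
    damping: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.solver_iterations < 1:
            raise ValueError("solver_iterations must be >= 1")
        if not 0.0 < self.stiffness <= 1.0:
            raise ValueError("stiffness must be in (0, 1]")
        if self.tray is not None:
            n = np.linalg.norm(self.tray.normal)
            if abs(n - 1.0) > 1e-9:
                raise ValueError("tray normal must be unit length")

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        tray = doc.pop("tray", None)
        if tray is not None:
            tray = TrayPlane(point=tuple(tray.get("point", (0, 0, 0))),
                             normal=tuple(tray.get("normal", (0, 1, 0))))
        known = {k: doc[k] for k in
                 ("dt", "solver_iterations", "gravity", "stiffness", "damping", "seed")
                 if k in doc}
        if "gravity" in known:
            known["gravity"] = tuple(known["gravity"])
        return cls(tray=tray, **known)


# ---------------------------------------------------------------------------
# solver pieces
# ---------------------------------------------------------------------------

def predict(state: LatticeState, config: SimulationConfig) -> LatticeState:
    """Explicit prediction: v += dt g (unpinned), predicted = x + dt v."""
    st = state.copy()
    _predict_inplace(st, config)
    return st


def _predict_inplace(state: LatticeState, config: SimulationConfig) -> None:
    unpinned = state.inverse_masses > 0
    g = np.asarray(config.gravity, dtype=np.float64)
    state.velocities[unpinned] = (config.damping * state.velocities[unpinned]
                                  + config.dt * g)
    state.predicted[:] = state.positions
    state.predicted[unpinned] += config.dt * state.velocities[unpinned]


def extract_rotation(current_offsets: np.ndarray, rest_offsets: np.ndarray) -> np.ndarray:
    """Polar rotation factor of A = Σ current_i rest_iᵀ, det +1.

    Both offset sets must be centered.  Degenerate configurations (all
    corners collinear or coincident, rank(A) < 2) return the identity.
    """
    cur = np.asarray(current_offsets, dtype=np.float64)
    rest = np.asarray(rest_offsets, dtype=np.float64)
    scale = max(np.abs(cur).max(), np.abs(rest).max(), 1e-300)
    if np.abs(cur.sum(axis=0)).max() > 1e-9 * max(scale, 1.0) or \
       np.abs(rest.sum(axis=0)).max() > 1e-9 * max(scale, 1.0):
        raise ValueError("offset sets must be centered (sums zero)")
    a = cur.T @ rest
    u, s, vt = np.linalg.svd(a)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        # collinear/coincident corners: rotation about the residual axis is
        # unconstrained — fall back to identity (flagged degenerate)
        return np.eye(3)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        u = u.copy()
        u[:, -1] *= -1
    return u @ vt


def project_shape_matching(constraint: ShapeMatchingConstraint,
                           state: LatticeState) -> LatticeState:
    """One shape-matching projection of a cube's predicted corners."""
    st = state.copy()
    _project_shape_matching_inplace(constraint, st)
    return st


def _project_shape_matching_inplace(constraint: ShapeMatchingConstraint,
                                    state: LatticeState) -> None:
    ids = constraint.corner_ids
    p = state.predicted[ids]
    inv = state.inverse_masses[ids]
    # mass weighting; pinned corners act as (numerically) infinite mass anchors
    finite = inv > 0
    if finite.all():
        w = 1.0 / inv
    else:
        w = np.empty(8)
        ref = (1.0 / inv[finite]).max() if finite.any() else 1.0
        w[finite] = 1.0 / inv[finite]
        w[~finite] = 1e9 * ref
    wsum = w.sum()
    c = (w[:, None] * p).sum(axis=0) / wsum
    q = constraint.rest_offsets
    cq = (w[:, None] * q).sum(axis=0) / wsum
    r = extract_rotation_weighted(p - c, q - cq, w)
    goals = (q - cq) @ r.T + c
    corr = constraint.stiffness * (goals - p)
    corr[~finite] = 0.0
    state.predicted[ids] = p + corr


def extract_rotation_weighted(current_offsets: np.ndarray, rest_offsets: np.ndarray,
                              weights: np.ndarray) -> np.ndarray:
    """Rotation of the mass-weighted best rigid fit (reduces to
    :func:`extract_rotation` for equal weights)."""
    a = (weights[:, None] * current_offsets).T @ rest_offsets
    u, s, vt = np.linalg.svd(a)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        return np.eye(3)
    if np.linalg.det(u @ vt) < 0:
        u = u.copy()
        u[:, -1] *= -1
    return u @ vt


def project_tray_collision(state: LatticeState, config: SimulationConfig) -> LatticeState:
    """Clamp predicted corners below the tray plane back onto it."""
    st = state.copy()
    _project_tray_inplace(st, config)
    return st


def _project_tray_inplace(state: LatticeState, config: SimulationConfig) -> None:
    if config.tray is None:
        return
    d = config.tray.signed_distances(state.predicted)
    below = (d < 0) & (state.inverse_masses > 0)
    if below.any():
        n = np.asarray(config.tray.normal, dtype=np.float64)
        state.predicted[below] -= d[below, None] * n


def _check_finite(predicted: np.ndarray) -> None:
    if not np.isfinite(predicted).all():
        bad = int(np.flatnonzero(~np.isfinite(predicted).all(axis=1))[0])
        raise DivergenceError(f"non-finite position at corner {bad}")


def build_constraints(lattice: OctreeLattice, stiffness: float) -> list[ShapeMatchingConstraint]:
    """One shape-matching constraint per cube, ascending cube id."""
    cons = []
    for cid, cube in enumerate(lattice.cubes):
        rest = lattice.corner_rest_positions[cube.corner_ids]
        centroid = rest.mean(axis=0)
        cons.append(ShapeMatchingConstraint(
            cube_id=cid, corner_ids=cube.corner_ids.copy(),
            rest_offsets=rest - centroid, stiffness=stiffness))
    return cons


def step(lattice: OctreeLattice, state: LatticeState, config: SimulationConfig,
         constraints: list[ShapeMatchingConstraint] | None = None) -> LatticeState:
    """Advance one frame: predict, Gauss–Seidel constraint sweeps, update.

    Sweeps visit cube constraints in ascending cube-id order (fixed for
    determinism) and apply the tray projection at the end of every sweep.
    """
    if constraints is None:
        constraints = build_constraints(lattice, config.stiffness)
    st = state.copy()
    _predict_inplace(st, config)
    _check_finite(st.predicted)
    for _ in range(config.solver_iterations):
        for con in constraints:
            _project_shape_matching_inplace(con, st)
        _project_tray_inplace(st, config)
    _check_finite(st.predicted)
    unpinned = st.inverse_masses > 0
    st.velocities[unpinned] = (st.predicted[unpinned] - st.positions[unpinned]) / config.dt
    st.velocities[~unpinned] = 0.0
    st.positions[:] = st.predicted
    return st


def kinetic_energy(state: LatticeState) -> float:
    """Σ ½ m v² over unpinned corners."""
    unpinned = state.inverse_masses > 0
    m = 1.0 / state.inverse_masses[unpinned]
    return float(0.5 * (m * (state.velocities[unpinned] ** 2).sum(axis=1)).sum())


def simulate(lattice: OctreeLattice, config: SimulationConfig, n_frames: int,
             state: LatticeState | None = None):
    """Yield successive frame states starting from rest (or ``state``)."""
    st = LatticeState.from_lattice(lattice) if state is None else state.copy()
    constraints = build_constraints(lattice, config.stiffness)
    for _ in range(n_frames):
        st = step(lattice, st, config, constraints)
        yield st
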