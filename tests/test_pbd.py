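"""PBD solver: prediction, rotation extraction, shape matching, collision, step."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

import octodeform as od
from octodeform.pbd import (DivergenceError, ShapeMatchingConstraint,
                            kinetic_energy)


def make_state(positions, velocities=None, inv_masses=None):
    p = np.asarray(positions, dtype=float)
    v = np.zeros_like(p) if velocities is None else np.asarray(velocities, float)
    w = np.ones(len(p)) if inv_masses is None else np.asarray(inv_masses, float)
    return od.LatticeState(p, v, w)


def procrustes_rotation(current, rest):
    """Independent best-fit rotation oracle (orthogonal Procrustes + det fix)."""
    r, _ = orthogonal_procrustes(rest, current)  # rest @ r ≈ current
    r = r.T
    if np.linalg.det(r) < 0:
        u, _, vt = np.linalg.svd(r)
        u[:, -1] *= -1
        r = u @ vt
    return r


class TestPredict:
    def test_zero_gravity_zero_velocity_fixed_point(self, unit_cube_rest):
        st = make_state(unit_cube_rest)
        cfg = od.SimulationConfig(gravity=(0, 0, 0))
        out = od.predict(st, cfg)
        assert np.array_equal(out.predicted, st.positions)

    def test_explicit_formula_one_step(self, unit_cube_rest):
        v0 = np.full((8, 3), 0.3)
        st = make_state(unit_cube_rest, velocities=v0)
        cfg = od.SimulationConfig(gravity=(0, -9.8, 0))
        out = od.predict(st, cfg)
        expected = (st.positions + cfg.dt * v0
                    + cfg.dt ** 2 * np.array([0, -9.8, 0]))
        assert np.abs(out.predicted - expected).max() < 1e-12

    def test_pinned_corner_never_moves(self, unit_cube_rest):
        inv = np.ones(8)
        inv[0] = 0.0
        st = make_state(unit_cube_rest, inv_masses=inv)
        out = od.predict(st, od.SimulationConfig())
        assert np.array_equal(out.predicted[0], st.positions[0])
        assert np.array_equal(out.velocities[0], 0 * out.velocities[0])


class TestExtractRotation:
    def centered(self, x):
        return x - x.mean(axis=0)

    def test_identity(self, unit_cube_rest):
        q = self.centered(unit_cube_rest)
        assert np.abs(od.extract_rotation(q, q) - np.eye(3)).max() < 1e-12

    def test_exact_recovery_quarter_turn(self, unit_cube_rest):
        q = self.centered(unit_cube_rest)
        r0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert np.abs(od.extract_rotation(q @ r0.T, q) - r0).max() < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovery_under_stretch_matches_procrustes_oracle(self, unit_cube_rest, seed):
        q = self.centered(unit_cube_rest)
        r0 = Rotation.random(random_state=seed).as_matrix()
        cur = (q * np.array([1.2, 0.9, 1.0])) @ r0.T
        r = od.extract_rotation(cur, q)
        assert np.abs(r - r0).max() < 1e-8
        assert np.abs(r - procrustes_rotation(cur, q)).max() < 1e-8

    def test_degenerate_coincident_corners_identity(self, unit_cube_rest):
        q = self.centered(unit_cube_rest)
        assert np.array_equal(od.extract_rotation(np.zeros((8, 3)), q), np.eye(3))

    def test_uncentered_input_rejected(self, unit_cube_rest):
        with pytest.raises(ValueError):
            od.extract_rotation(unit_cube_rest, unit_cube_rest)


class TestProjectShapeMatching:
    def constraint(self, unit_cube_rest, stiffness=1.0):
        q = unit_cube_rest - unit_cube_rest.mean(axis=0)
        return ShapeMatchingConstraint(cube_id=0, corner_ids=np.arange(8),
                                       rest_offsets=q, stiffness=stiffness)

    @pytest.mark.parametrize("stiffness", [0.3, 1.0])
    def test_rigid_transform_is_fixed_point(self, unit_cube_rest, stiffness):
        r0 = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        rigid = unit_cube_rest @ r0.T + np.array([3.0, -1.0, 2.0])
        st = make_state(rigid)
        out = od.project_shape_matching(self.constraint(unit_cube_rest, stiffness), st)
        assert np.abs(out.predicted - rigid).max() < 1e-12

    def test_scaled_cube_projects_to_rest_cube_at_same_centroid(self, unit_cube_rest):
        centroid = unit_cube_rest.mean(axis=0)
        scaled = centroid + 2.0 * (unit_cube_rest - centroid)
        st = make_state(scaled)
        out = od.project_shape_matching(self.constraint(unit_cube_rest, 1.0), st)
        # best rigid fit of an isotropically scaled cube is the unscaled cube
        # about the same centroid (rotation = identity by the Procrustes oracle)
        oracle_r = procrustes_rotation(scaled - centroid, unit_cube_rest - centroid)
        goal = (unit_cube_rest - centroid) @ oracle_r.T + centroid
        assert np.abs(out.predicted - goal).max() < 1e-8
        assert np.abs(out.predicted - unit_cube_rest).max() < 1e-8

    def test_centroid_preserved_with_equal_masses(self, unit_cube_rest, rng):
        scrambled = unit_cube_rest + 0.4 * rng.normal(size=(8, 3))
        st = make_state(scrambled)
        out = od.project_shape_matching(self.constraint(unit_cube_rest, 0.7), st)
        assert np.abs(out.predicted.mean(axis=0) - scrambled.mean(axis=0)).max() < 1e-9


class TestTrayCollision:
    def test_projection_clamps_only_penetrating_corners(self):
        st = make_state([[0.0, -0.1, 0.0], [0.0, 0.1, 0.0]])
        st.predicted = st.positions.copy()
        cfg = od.SimulationConfig(tray=od.TrayPlane((0, 0, 0), (0, 1, 0)))
        out = od.project_tray_collision(st, cfg)
        assert np.allclose(out.predicted[0], [0, 0, 0])
        assert np.allclose(out.predicted[1], [0, 0.1, 0])
        assert cfg.tray.signed_distances(out.predicted).min() >= 0


class TestStep:
    def test_rest_state_is_equilibrium(self, blob_lattice):
        cfg = od.SimulationConfig(gravity=(0, 0, 0))
        st = od.LatticeState.from_lattice(blob_lattice)
        out = st
        for _ in range(3):
            out = od.step(blob_lattice, out, cfg)
        assert np.abs(out.positions - st.positions).max() < 1e-12

    def test_free_fall_translates_rigidly(self, blob_lattice):
        cfg = od.SimulationConfig(stiffness=0.5)  # no tray
        st = od.LatticeState.from_lattice(blob_lattice)
        out = od.step(blob_lattice, st, cfg)
        disp = out.positions - st.positions
        assert np.abs(disp - disp[0]).max() < 1e-9
        assert disp[0][1] == pytest.approx(-9.8 * cfg.dt ** 2, abs=1e-9)

    def test_determinism_bitwise(self, blob_lattice):
        cfg = od.SimulationConfig(tray=od.TrayPlane((0, -0.8, 0), (0, 1, 0)))
        runs = []
        for _ in range(2):
            st = od.LatticeState.from_lattice(blob_lattice)
            for _ in range(5):
                st = od.step(blob_lattice, st, cfg)
            runs.append(st.positions.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_rigid_motion_equivariance(self, blob_lattice):
        r0 = Rotation.from_euler("xyz", [15, 30, -25], degrees=True).as_matrix()
        t0 = np.array([0.5, -0.2, 1.0])
        plane_p = np.array([0.0, -0.9, 0.0])
        plane_n = np.array([0.0, 1.0, 0.0])
        cfg = od.SimulationConfig(
            gravity=(0, -9.8, 0),
            tray=od.TrayPlane(tuple(plane_p), tuple(plane_n)))
        g_rot = r0 @ np.array([0, -9.8, 0])
        cfg_rot = od.SimulationConfig(
            gravity=tuple(g_rot),
            tray=od.TrayPlane(tuple(r0 @ plane_p + t0), tuple(r0 @ plane_n)))
        st = od.LatticeState.from_lattice(blob_lattice)
        st_rot = st.copy()
        st_rot.positions = st.positions @ r0.T + t0
        st_rot.predicted = st_rot.positions.copy()
        # rotated constraints: shape matching is itself rotation-invariant,
        # so the same lattice serves both runs
        out = od.step(blob_lattice, st, cfg)
        out_rot = od.step(blob_lattice, st_rot, cfg_rot)
        assert np.abs(out_rot.positions - (out.positions @ r0.T + t0)).max() < 1e-9

    def test_drop_on_tray_settles(self, sphere_mesh):
        lattice = od.build_octree(sphere_mesh, max_level=1)
        cfg = od.SimulationConfig(tray=od.TrayPlane((0, 0, 0), (0, 1, 0)),
                                  damping=0.98)
        st = od.LatticeState.from_lattice(lattice)
        lift = 1.5 - lattice.corner_rest_positions[:, 1].min()
        st.positions[:, 1] += lift
        st.predicted[:, 1] += lift
        cons = od.build_constraints(lattice, cfg.stiffness)
        peak_ke = 0.0
        for _ in range(300):
            st = od.step(lattice, st, cfg, cons)
            peak_ke = max(peak_ke, kinetic_energy(st))
        assert cfg.tray.signed_distances(st.positions).min() >= -1e-6
        assert kinetic_energy(st) < 1e-6 * peak_ke

    def test_non_finite_positions_raise_named_divergence(self, blob_lattice):
        st = od.LatticeState.from_lattice(blob_lattice)
        st.positions[3] = np.nan
        st.predicted[3] = np.nan
        with pytest.raises(DivergenceError, match="corner"):
            od.step(blob_lattice, st, od.SimulationConfig(gravity=(0, 0, 0)))
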