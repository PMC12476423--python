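"""Timing-sample loading, cost-plane fits and the crossover condition.

The independent oracle for the OLS fit is statsmodels' OLS on the same
design; the packaged published samples are additionally checked against the
frozen coefficients they produce.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import octodeform as od
from octodeform.perf import (DataError, FitError, benchmark_records_to_frame,
                             max_cubes_for_gpu)


@pytest.fixture(scope="module")
def fixture_samples():
    return od.paper_samples()


@pytest.fixture(scope="module")
def fixture_planes(fixture_samples):
    return (od.fit_plane(fixture_samples, "cpu_map"),
            od.fit_plane(fixture_samples, "gpu_remaining"))


class TestLoadSamples:
    def test_seven_unique_samples_with_identities(self, fixture_samples):
        assert len(fixture_samples) == 7
        assert len({(s.n_v, s.n_c) for s in fixture_samples}) == 7
        for s in fixture_samples:
            assert s.t4c == pytest.approx(s.Tc - s.t2 - s.t3c, abs=0.05)
            assert s.t4g == pytest.approx(s.Tg - s.t2, abs=0.05)

    def test_published_example_remainders(self, fixture_samples):
        by_label = {s.label: s for s in fixture_samples}
        assert by_label["Mesh 1"].t4c == pytest.approx(5.1, abs=1e-9)
        assert by_label["Case 1"].t4g == pytest.approx(5.3, abs=1e-9)

    def test_all_zero_times_derive_zero_remainders(self):
        df = pd.DataFrame([{"n_v": 10, "n_c": 1, "t2_ms": 0.0, "t3c_ms": 0.0,
                            "Tc_ms": 0.0, "Tg_ms": 0.0}])
        s = od.load_samples(df)[0]
        assert s.t4c == 0.0 and s.t4g == 0.0

    def test_negative_time_rejected(self):
        df = pd.DataFrame([{"n_v": 10, "n_c": 1, "t2_ms": -1.0, "t3c_ms": 0.0,
                            "Tc_ms": 0.0, "Tg_ms": 0.0}])
        with pytest.raises(DataError):
            od.load_samples(df)

    def test_inconsistent_remainder_column_rejected(self):
        df = pd.DataFrame([{"n_v": 10, "n_c": 1, "t2_ms": 1.0, "t3c_ms": 1.0,
                            "Tc_ms": 10.0, "Tg_ms": 5.0, "t4c_ms": 3.0}])
        with pytest.raises(DataError):
            od.load_samples(df)

    def test_csv_roundtrip(self, tmp_path, fixture_samples):
        path = tmp_path / "samples.csv"
        pd.DataFrame([{
            "n_v": s.n_v, "n_c": s.n_c, "t2_ms": s.t2, "t3c_ms": s.t3c,
            "Tc_ms": s.Tc, "Tg_ms": s.Tg} for s in fixture_samples]).to_csv(
                path, index=False)
        back = od.load_samples(path)
        assert [(s.n_v, s.n_c) for s in back] == \
            [(s.n_v, s.n_c) for s in fixture_samples]


class TestFitPlane:
    def test_noiseless_plane_recovered_exactly(self, rng):
        a0, b0, c0 = 3.2e-5, 1.7e-3, 4.5
        rows = []
        for _ in range(8):
            n_v = int(rng.integers(10_000, 300_000))
            n_c = int(rng.integers(100, 4000))
            t = a0 * n_v + b0 * n_c + c0
            rows.append({"n_v": n_v, "n_c": n_c, "t2_ms": 0.0, "t3c_ms": t,
                         "Tc_ms": t, "Tg_ms": t})
        samples = od.load_samples(pd.DataFrame(rows))
        for resp in ("cpu_map", "gpu_remaining"):
            plane = od.fit_plane(samples, resp)
            assert plane.a == pytest.approx(a0, abs=1e-9)
            assert plane.b == pytest.approx(b0, abs=1e-9)
            assert plane.c == pytest.approx(c0, abs=1e-9)
            assert plane.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_statsmodels_oracle(self, fixture_samples):
        design = sm.add_constant(
            np.array([[s.n_v, s.n_c] for s in fixture_samples]), prepend=False)
        for resp in ("cpu_map", "gpu_remaining"):
            y = np.array([getattr(s, resp) for s in fixture_samples])
            res = sm.OLS(y, design).fit()
            plane = od.fit_plane(fixture_samples, resp)
            assert plane.a == pytest.approx(res.params[0], rel=1e-9)
            assert plane.b == pytest.approx(res.params[1], rel=1e-9)
            assert plane.c == pytest.approx(res.params[2], rel=1e-9)
            assert plane.r_squared == pytest.approx(res.rsquared, abs=1e-12)

    def test_frozen_fixture_coefficients(self, fixture_planes):
        # values produced by OLS on the seven printed rows (see also the
        # statsmodels cross-check above); frozen as a regression guard
        cpu, gpu = fixture_planes
        assert cpu.a == pytest.approx(5.2022e-5, rel=1e-3)
        assert cpu.b == pytest.approx(8.0513e-5, rel=1e-3)
        assert cpu.c == pytest.approx(5.1602, rel=1e-3)
        assert cpu.r_squared == pytest.approx(0.99148, abs=1e-4)
        assert gpu.a == pytest.approx(1.5369e-6, rel=1e-3)
        assert gpu.b == pytest.approx(4.1950e-3, rel=1e-3)
        assert gpu.c == pytest.approx(2.8574, rel=1e-3)
        assert gpu.r_squared == pytest.approx(0.99372, abs=1e-4)

    def test_mesh2_vertex_count_variants_agree(self):
        table = od.paper_samples(mesh2_vertices=81842)
        text = od.paper_samples(mesh2_vertices=81482)
        for resp in ("cpu_map", "gpu_remaining"):
            pa = od.fit_plane(table, resp)
            pb = od.fit_plane(text, resp)
            for attr in ("a", "b", "c", "r_squared"):
                assert getattr(pa, attr) == pytest.approx(
                    getattr(pb, attr), rel=2e-3, abs=1e-6)

    def test_collinear_design_rejected(self):
        rows = [{"n_v": 1000 * k, "n_c": 100 * k, "t2_ms": 0.0, "t3c_ms": 1.0,
                 "Tc_ms": 1.0, "Tg_ms": 1.0} for k in range(1, 6)]
        with pytest.raises(FitError, match="collinear"):
            od.fit_plane(od.load_samples(pd.DataFrame(rows)), "cpu_map")

    def test_too_few_samples_rejected(self, fixture_samples):
        with pytest.raises(FitError):
            od.fit_plane(fixture_samples[:3], "cpu_map")


class TestCrossover:
    def test_hand_built_planes_direct_subtraction(self):
        cpu = od.CostPlane(a=2.0, b=0.0, c=5.0, r_squared=1.0)
        gpu = od.CostPlane(a=1.0, b=3.0, c=4.0, r_squared=1.0)
        cond = od.crossover(cpu, gpu)
        assert (cond.beta_c, cond.beta_v, cond.beta_0) == (3.0, 1.0, 1.0)

    def test_identical_planes_never_strictly_faster(self, fixture_planes):
        cpu, _ = fixture_planes
        cond = od.crossover(cpu, cpu)
        assert (cond.beta_c, cond.beta_v, cond.beta_0) == (0.0, 0.0, 0.0)
        assert not cond.favors_batched(100_000, 1)

    def test_antisymmetry(self, fixture_planes):
        cpu, gpu = fixture_planes
        fwd = od.crossover(cpu, gpu)
        rev = od.crossover(gpu, cpu)
        assert fwd.beta_c == pytest.approx(-rev.beta_c)
        assert fwd.beta_v == pytest.approx(-rev.beta_v)
        assert fwd.beta_0 == pytest.approx(-rev.beta_0)

    def test_max_cubes_strict_floor(self):
        cond = od.CrossoverCondition(beta_c=1.0, beta_v=0.0, beta_0=10.0)
        assert max_cubes_for_gpu(cond, 123456) == 9  # strictly below 10

    def test_max_cubes_intercept_only(self, fixture_planes):
        import math
        cond = od.crossover(*fixture_planes)
        assert max_cubes_for_gpu(cond, 0) == math.floor(cond.beta_0 / cond.beta_c)

    def test_non_positive_slope_unbounded(self):
        cond = od.CrossoverCondition(beta_c=-0.5, beta_v=1.0, beta_0=0.0)
        assert max_cubes_for_gpu(cond, 1000) is None


class TestBenchmark:
    def test_harness_schema_feeds_fit(self, sphere_mesh):
        records = []
        for level in (0, 1):
            lat = od.build_octree(sphere_mesh, max_level=level)
            pieces = od.split_mesh(sphere_mesh, lat)
            records.append(od.benchmark_mapping(sphere_mesh, lat, pieces, repeats=2))
        small = od.make_synthetic_organ("icosphere", 320)
        for level in (1, 2):
            lat = od.build_octree(small, max_level=level)
            pieces = od.split_mesh(small, lat)
            records.append(od.benchmark_mapping(small, lat, pieces, repeats=2))
        for r in records:
            assert r["reference_ms"] > 0 and np.isfinite(r["batched_ms"])
        samples = od.load_samples(benchmark_records_to_frame(records))
        plane = od.fit_plane(samples, "cpu_map")
        assert 0.0 <= plane.r_squared <= 1.0
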