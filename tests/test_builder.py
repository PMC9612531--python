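import numpy as np
import pytest

from conftest import LOSSLESS_WATER
from skullbeam.builder import (
    ParameterGrid,
    ParameterPoint,
    SurrogateTensors,
    build_surrogate,
    compute_attenuation,
    compute_refraction,
    enumerate_points,
    simulate_pair,
)
from skullbeam.errors import DegenerateSimulationError, DomainError
from skullbeam.geometry import GridSpec, MaterialProps
from skullbeam.solver import SolverConfig, extract_peak

# small 2-D scene: every toy grid point below fits its interior
TOY_SCENE_GRID = GridSpec(shape=(96, 80), spacing=1e-3, pml_size=10,
                          pml_alpha=2.0)
TOY_SOLVER = SolverConfig(cfl=0.3, t_end=5.5e-5)
TOY_BONE = MaterialProps(density=1732.0, sound_speed=2850.0,
                         absorption_coeff=85.0, absorption_power=1.0)


def toy_param_grid(thickness_levels=(1e-3, 8e-3)):
    # thickness pair chosen off the slab's half-wave resonances at both toy
    # frequencies, so transmission decreases with thickness (Fabry-Perot
    # interference would otherwise invert the trend)
    return ParameterGrid(levels={
        "frequency": [4e5, 5e5],
        "thickness": list(thickness_levels),
        "trajectory": [80.0, 90.0],
        "depth": [30e-3, 40e-3],
        "diameter": [24e-3, 30e-3],
    })


class TestParameterTypes:
    def test_point_rejects_bad_trajectory(self):
        with pytest.raises(DomainError):
            ParameterPoint(5e5, 2e-3, 120.0, 40e-3, 30e-3)

    def test_grid_requires_all_axes_in_order(self):
        with pytest.raises(DomainError):
            ParameterGrid(levels={"frequency": [1, 2]})

    def test_grid_rejects_unsorted_levels(self):
        levels = toy_param_grid().levels.copy()
        levels["depth"] = np.array([40e-3, 30e-3])
        with pytest.raises(DomainError):
            ParameterGrid(levels=levels)


class TestEnumeratePoints:
    def test_cartesian_count_and_order(self):
        grid = toy_param_grid()
        pts = enumerate_points(grid, TOY_SCENE_GRID)
        assert len(pts) == 32
        # row-major: last axis (diameter) varies fastest
        assert pts[0][0] == (0, 0, 0, 0, 0)
        assert pts[1][0] == (0, 0, 0, 0, 1)
        assert pts[-1][0] == (1, 1, 1, 1, 1)

    def test_focus_inside_bone_flagged(self):
        grid = ParameterGrid(levels={
            "frequency": [4e5, 5e5],
            "thickness": [2e-3, 12e-3],
            "trajectory": [80.0, 90.0],
            "depth": [2e-3, 40e-3],
            "diameter": [24e-3, 30e-3],
        })
        pts = enumerate_points(grid, TOY_SCENE_GRID)
        flagged = {idx: reason for idx, _, reason in pts if reason}
        # depth 2 mm <= thickness 2 mm and 12 mm: always invalid
        for idx, point, reason in pts:
            if point.focal_depth <= point.bone_thickness:
                assert reason == "focus inside bone"

    def test_all_valid_toy_grid_has_no_flags(self):
        pts = enumerate_points(toy_param_grid(), TOY_SCENE_GRID)
        assert all(reason is None for _, _, reason in pts)

    def test_oversized_geometry_flagged_as_outside_head(self):
        grid = ParameterGrid(levels={
            "frequency": [4e5, 5e5],
            "thickness": [1e-3, 2e-3],
            "trajectory": [80.0, 90.0],
            "depth": [40e-3, 500e-3],
            "diameter": [24e-3, 30e-3],
        })
        pts = enumerate_points(grid, TOY_SCENE_GRID)
        deep = [r for _, p, r in pts if p.focal_depth > 0.1]
        assert all(r == "focus or transducer outside head" for r in deep)


class TestPairMetrics:
    @pytest.mark.parametrize(
        "bone_peak,water_peak,expected",
        [(0.0068, 1.0, 0.68), (1.0, 1.0, 100.0), (0.0, 1.0, 0.0)],
    )
    def test_attenuation_percent(self, bone_peak, water_peak, expected):
        assert compute_attenuation(bone_peak, water_peak) == pytest.approx(expected)

    def test_attenuation_rejects_zero_water_peak(self):
        with pytest.raises(DegenerateSimulationError):
            compute_attenuation(1.0, 0.0)

    @pytest.mark.parametrize(
        "a,b,expected_mm",
        [
            ((0.0, 0.0), (0.0, 0.0), 0.0),
            ((0.017, 0.0, 0.0), (0.0, 0.0, 0.0), 17.0),
            ((1.5e-3, 2e-3), (0.0, 0.0), 2.5),
        ],
    )
    def test_refraction_distance(self, a, b, expected_mm):
        assert compute_refraction(a, b) == pytest.approx(expected_mm)


class TestSimulatePair:
    @pytest.fixture(scope="class")
    def pair(self):
        point = ParameterPoint(5e5, 2e-3, 90.0, 35e-3, 24e-3)
        return point, simulate_pair(point, TOY_SOLVER, TOY_SCENE_GRID,
                                    bone=TOY_BONE, water=LOSSLESS_WATER)

    def test_water_record_matches_standalone_run(self, pair):
        from skullbeam.builder import scene_for_point
        from skullbeam.solver import run_simulation

        point, result = pair
        scene = scene_for_point(point, TOY_SCENE_GRID, with_bone=False,
                                bone=TOY_BONE, water=LOSSLESS_WATER)
        standalone = run_simulation(scene, TOY_SOLVER)
        assert np.array_equal(standalone.max_pressure,
                              result["water_record"].max_pressure)

    def test_bone_attenuates_peak(self, pair):
        _, result = pair
        bone_peak = extract_peak(result["bone_record"], result["search_mask"])
        water_peak = extract_peak(result["water_record"], result["search_mask"])
        assert bone_peak["peak_intensity"] < water_peak["peak_intensity"]

    def test_invalid_point_rejected(self):
        bad = ParameterPoint(5e5, 12e-3, 90.0, 5e-3, 24e-3)
        with pytest.raises(Exception):
            simulate_pair(bad, TOY_SOLVER, TOY_SCENE_GRID)


class TestSurrogateTensors:
    def test_invariants_enforced(self):
        grid = toy_param_grid()
        shape = grid.shape
        bad_att = np.full(shape, 150.0)
        with pytest.raises(DomainError):
            SurrogateTensors(attenuation=bad_att,
                             refraction=np.zeros(shape),
                             valid=np.ones(shape, bool), grid=grid)

    def test_invalid_entries_may_hold_nan(self):
        grid = toy_param_grid()
        shape = grid.shape
        att = np.full(shape, np.nan)
        att[(0,) * 5] = 50.0
        valid = np.zeros(shape, bool)
        valid[(0,) * 5] = True
        t = SurrogateTensors(attenuation=att, refraction=np.zeros(shape),
                             valid=valid, grid=grid)
        assert np.isnan(t.attenuation[(1,) * 5])


@pytest.fixture(scope="module")
def built_surrogate():
    """2-D toy sweep: 2 levels per axis, 32 bone/water pairs."""
    grid = toy_param_grid()
    return grid, build_surrogate(grid, TOY_SOLVER, TOY_SCENE_GRID,
                                 bone=TOY_BONE, water=LOSSLESS_WATER)


class TestBuildSurrogate:
    def test_all_entries_valid_and_bounded(self, built_surrogate):
        _, tensors = built_surrogate
        assert tensors.valid.all()
        assert np.all(tensors.attenuation >= 0)
        assert np.all(tensors.attenuation <= 120)
        assert np.all(tensors.refraction >= 0)

    def test_deterministic_rebuild(self, built_surrogate):
        grid, tensors = built_surrogate
        again = build_surrogate(grid, TOY_SOLVER, TOY_SCENE_GRID,
                                bone=TOY_BONE, water=LOSSLESS_WATER)
        assert np.array_equal(tensors.attenuation, again.attenuation)
        assert np.array_equal(tensors.refraction, again.refraction)

    def test_attenuation_decreases_with_thickness(self, built_surrogate):
        _, tensors = built_surrogate
        med_thin = np.median(tensors.attenuation[:, 0])
        med_thick = np.median(tensors.attenuation[:, 1])
        assert med_thick <= med_thin

    def test_entries_reproducible_from_records(self, built_surrogate):
        grid, tensors = built_surrogate
        idx = (1, 0, 1, 0, 1)
        point = grid.point(idx)
        pair = simulate_pair(point, TOY_SOLVER, TOY_SCENE_GRID,
                             bone=TOY_BONE, water=LOSSLESS_WATER)
        bone_peak = extract_peak(pair["bone_record"], pair["search_mask"])
        water_peak = extract_peak(pair["water_record"], pair["search_mask"])
        att = compute_attenuation(bone_peak["peak_intensity"],
                                  water_peak["peak_intensity"])
        refr = compute_refraction(bone_peak["location"], water_peak["location"])
        assert att == tensors.attenuation[idx]
        assert refr == tensors.refraction[idx]

    def test_round_trip_bit_identical(self, built_surrogate, tmp_path):
        from skullbeam import io as sbio

        _, tensors = built_surrogate
        path = tmp_path / "surrogate.h5"
        sbio.save_surrogate(path, tensors)
        loaded = sbio.load_surrogate(path)
        assert np.array_equal(tensors.attenuation, loaded.attenuation)
        assert np.array_equal(tensors.refraction, loaded.refraction)
        assert np.array_equal(tensors.valid, loaded.valid)
        for name in tensors.grid.axes:
            assert np.array_equal(tensors.grid.levels[name],
                                  loaded.grid.levels[name])

    def test_checkpoint_resume_skips_finished_points(self, built_surrogate,
                                                     tmp_path, monkeypatch):
        grid, tensors = built_surrogate
        ckpt = tmp_path / "ckpt.h5"
        first = build_surrogate(grid, TOY_SOLVER, TOY_SCENE_GRID,
                                bone=TOY_BONE, water=LOSSLESS_WATER,
                                checkpoint_path=ckpt)
        # a finished checkpoint must make the rebuild run zero simulations
        import skullbeam.builder as builder_mod

        def boom(*a, **k):
            raise AssertionError("simulation re-executed on resume")

        monkeypatch.setattr(builder_mod, "simulate_pair", boom)
        resumed = build_surrogate(grid, TOY_SOLVER, TOY_SCENE_GRID,
                                  bone=TOY_BONE, water=LOSSLESS_WATER,
                                  checkpoint_path=ckpt)
        assert np.array_equal(first.attenuation, resumed.attenuation)
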