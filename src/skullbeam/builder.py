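"""Sweep the 5-D study space and assemble attenuation/refraction tensors.

The study space has five axes, in fixed order: carrier frequency (Hz), bone
thickness (m), trajectory angle (degrees), focal depth (m) and transducer
diameter (m). For every grid point a bone and a water simulation are run
with identical geometry, drive and search mask; the peak focal intensity
and its location in each run give

* attenuation — bone peak intensity as a percent of the water peak
  (the transmitted fraction; 100% means bone had no effect), and
* refraction — the Euclidean distance in mm between the two peak locations.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSimulationError, DomainError, GeometryError
from .geometry import (
    BONE,
    WATER,
    GridSpec,
    MaterialProps,
    Scene,
    TransducerSpec,
    assemble_scene,
)
from .solver import PressureRecord, SolverConfig, extract_peak, run_simulation

logger = logging.getLogger(__name__)

AXIS_NAMES = ("frequency", "thickness", "trajectory", "depth", "diameter")

__all__ = [
    "AXIS_NAMES",
    "ParameterPoint",
    "ParameterGrid",
    "SurrogateTensors",
    "enumerate_points",
    "simulate_pair",
    "compute_attenuation",
    "compute_refraction",
    "build_surrogate",
]


@dataclass(frozen=True)
class ParameterPoint:
    """One location in the five-dimensional study space."""

    frequency: float
    bone_thickness: float
    trajectory_deg: float
    focal_depth: float
    transducer_diameter: float

    def __post_init__(self):
        vals = (self.frequency, self.bone_thickness, self.trajectory_deg,
                self.focal_depth, self.transducer_diameter)
        if any(v < 0 for v in vals) or self.frequency <= 0:
            raise DomainError("parameter values must be non-negative, frequency positive")
        if self.trajectory_deg <= 0 or self.trajectory_deg > 90:
            raise DomainError("trajectory_deg must lie in (0, 90]")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.frequency, self.bone_thickness, self.trajectory_deg,
                self.focal_depth, self.transducer_diameter)


@dataclass(frozen=True)
class ParameterGrid:
    """Rectilinear discretization of the study space.

    ``levels`` maps each of the five axis names to its strictly increasing
    coordinate levels (at least two per axis).
    """

    levels: dict

    def __post_init__(self):
        if tuple(self.levels.keys()) != AXIS_NAMES:
            raise DomainError(f"levels must carry exactly the axes {AXIS_NAMES} in order")
        clean = {}
        for name, lv in self.levels.items():
            arr = np.asarray(lv, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise DomainError(f"axis {name!r} needs >= 2 levels")
            if np.any(np.diff(arr) <= 0):
                raise DomainError(f"axis {name!r} levels must be strictly increasing")
            clean[name] = arr
        object.__setattr__(self, "levels", clean)

    @property
    def axes(self) -> tuple[str, ...]:
        return AXIS_NAMES

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.levels[a].size for a in AXIS_NAMES)

    def point(self, index: tuple[int, ...]) -> ParameterPoint:
        f, th, tr, de, di = (self.levels[a][i] for a, i in zip(AXIS_NAMES, index))
        return ParameterPoint(f, th, tr, de, di)


#: Full-scale voxel grid matching the published sweep: 256^3 at 0.5 mm.
FULL_SCALE_GRID = GridSpec(shape=(256, 256, 256), spacing=0.5e-3,
                           pml_size=10, pml_alpha=2.0)


def _preflight(point: ParameterPoint, grid_spec: GridSpec) -> str | None:
    """Reason a point cannot be simulated, or None if it is valid.

    A point is invalid when the theoretical focus lies inside bone
    (focal depth not beyond the slab) or when the transducer-plus-focus
    geometry does not fit the simulated head interior.
    """
    if point.focal_depth <= point.bone_thickness:
        return "focus inside bone"
    td = TransducerSpec(
        diameter=point.transducer_diameter,
        focal_depth=point.focal_depth,
        carrier_frequency=point.frequency,
        trajectory_deg=point.trajectory_deg,
    )
    dx = grid_spec.spacing
    interior = grid_spec.interior_extent
    tilt = np.deg2rad(td.tilt_deg)
    # axial reach: concavity + slab + focal depth + one wavelength of margin
    margin = 1482.0 / point.frequency
    axial = td.cap_height + point.bone_thickness + point.focal_depth * np.cos(tilt)
    lateral = td.diameter + point.focal_depth * np.sin(tilt)
    if axial + margin > interior[0] or lateral + margin > interior[1]:
        return "focus or transducer outside head"
    if td.cap_height < dx:
        return "bowl flatter than one voxel"
    return None


def enumerate_points(
    grid: ParameterGrid, grid_spec: GridSpec = FULL_SCALE_GRID
) -> list[tuple[tuple[int, ...], ParameterPoint, str | None]]:
    """Full Cartesian product of the grid in row-major axis order.

    Returns ``(index, point, invalid_reason)`` triples; ``invalid_reason``
    is ``None`` for simulable points and a short string (e.g. the focus
    falling inside bone or outside the head) for points the sweep skips.
    """
    out = []
    for index in itertools.product(*(range(n) for n in grid.shape)):
        point = grid.point(index)
        out.append((index, point, _preflight(point, grid_spec)))
    return out


def scene_for_point(
    point: ParameterPoint,
    grid_spec: GridSpec,
    with_bone: bool,
    bone: MaterialProps = BONE,
    water: MaterialProps = WATER,
) -> Scene:
    """Assemble the (bone or water) scene realizing a parameter point."""
    td = TransducerSpec(
        diameter=point.transducer_diameter,
        focal_depth=point.focal_depth,
        carrier_frequency=point.frequency,
        trajectory_deg=point.trajectory_deg,
    )
    return assemble_scene(
        grid_spec, td, thickness=point.bone_thickness, with_bone=with_bone,
        bone=bone, water=water,
    )


def simulate_pair(
    point: ParameterPoint,
    solver: SolverConfig,
    grid_spec: GridSpec,
    bone: MaterialProps = BONE,
    water: MaterialProps = WATER,
) -> dict:
    """Run the bone and water twins of one parameter point.

    The two runs differ only in the material maps; geometry, drive,
    duration and search mask are identical.
    """
    reason = _preflight(point, grid_spec)
    if reason is not None:
        raise GeometryError(f"invalid parameter point ({reason}): {point}")
    bone_scene = scene_for_point(point, grid_spec, True, bone=bone, water=water)
    water_scene = scene_for_point(point, grid_spec, False, bone=bone, water=water)
    try:
        bone_record = run_simulation(bone_scene, solver)
        water_record = run_simulation(water_scene, solver)
    except Exception as exc:
        raise type(exc)(f"{exc} (at parameter point {point})") from exc
    return {
        "bone_record": bone_record,
        "water_record": water_record,
        "search_mask": bone_scene.search_mask,
    }


def compute_attenuation(bone_peak: float, water_peak: float) -> float:
    """Bone-run peak intensity as a percent of the water-run peak."""
    if water_peak <= 0:
        raise DegenerateSimulationError("water simulation produced zero peak intensity")
    return 100.0 * bone_peak / water_peak


def compute_refraction(bone_location, water_location) -> float:
    """Euclidean distance between bone and water peak locations, mm."""
    a = np.asarray(bone_location, dtype=float)
    b = np.asarray(water_location, dtype=float)
    return float(np.linalg.norm(a - b) * 1e3)


@dataclass
class SurrogateTensors:
    """Paired 5-D attenuation (%) and refraction (mm) lookup tensors.

    Entries where ``valid`` is False were never simulated (pre-flagged
    invalid geometry or a failed run) and hold NaN, never silent zeros.
    """

    attenuation: np.ndarray
    refraction: np.ndarray
    valid: np.ndarray
    grid: ParameterGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = self.grid.shape
        for name in ("attenuation", "refraction", "valid"):
            if getattr(self, name).shape != shape:
                raise DomainError(f"{name} shape does not match grid {shape}")
        v = self.valid
        if v.any():
            att = self.attenuation[v]
            if np.any(att < 0) or np.any(att > 120):
                raise DomainError("valid attenuation entries must lie in [0, 120]%")
            if np.any(self.refraction[v] < 0):
                raise DomainError("valid refraction entries must be non-negative")


def build_surrogate(
    grid: ParameterGrid,
    solver: SolverConfig,
    grid_spec: GridSpec,
    bone: MaterialProps = BONE,
    water: MaterialProps = WATER,
    checkpoint_path=None,
    max_failure_fraction: float = 0.1,
) -> SurrogateTensors:
    """Fill the attenuation and refraction tensors point by point.

    Per-point simulation failures mark the entry invalid and the sweep
    continues; more than ``max_failure_fraction`` of simulable points
    failing aborts the build. When ``checkpoint_path`` is given, finished
    entries are written to HDF5 after every point and a rerun resumes
    instead of recomputing.
    """
    from . import io as sbio  # deferred: io imports this module's types

    shape = grid.shape
    attenuation = np.full(shape, np.nan)
    refraction = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    done = np.zeros(shape, dtype=bool)

    if checkpoint_path is not None:
        resumed = sbio.load_checkpoint(checkpoint_path)
        if resumed is not None:
            attenuation, refraction, valid, done = resumed

    points = enumerate_points(grid, grid_spec)
    metadata = {
        "solver": {"cfl": solver.cfl, "t_end": solver.t_end,
                   "source_mode": solver.source_mode,
                   "ramp_cycles": solver.ramp_cycles},
        "materials": {
            "bone": {"density": bone.density, "sound_speed": bone.sound_speed,
                     "absorption_coeff": bone.absorption_coeff,
                     "absorption_power": bone.absorption_power},
            "water": {"density": water.density, "sound_speed": water.sound_speed,
                      "absorption_coeff": water.absorption_coeff,
                      "absorption_power": water.absorption_power},
        },
        "grid_spec": {"shape": list(grid_spec.shape), "spacing": grid_spec.spacing,
                      "pml_size": grid_spec.pml_size, "pml_alpha": grid_spec.pml_alpha},
        "build_time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "code_version": _package_version(),
    }

    n_simulable = sum(1 for _, _, r in points if r is None)
    n_failed = 0
    for index, point, reason in points:
        if done[index]:
            continue
        if reason is not None:
            valid[index] = False
            done[index] = True
            logger.info("point %s skipped: %s", index, reason)
        else:
            t0 = time.perf_counter()
            try:
                pair = simulate_pair(point, solver, grid_spec, bone=bone, water=water)
                bone_peak = extract_peak(pair["bone_record"], pair["search_mask"])
                water_peak = extract_peak(pair["water_record"], pair["search_mask"])
                attenuation[index] = compute_attenuation(
                    bone_peak["peak_intensity"], water_peak["peak_intensity"]
                )
                refraction[index] = compute_refraction(
                    bone_peak["location"], water_peak["location"]
                )
                valid[index] = True
                logger.info(
                    "point %s done in %.2fs: attenuation=%.3f%% refraction=%.3fmm",
                    index, time.perf_counter() - t0,
                    attenuation[index], refraction[index],
                )
            except Exception:
                n_failed += 1
                valid[index] = False
                logger.exception("point %s failed", index)
                if n_failed > max_failure_fraction * max(n_simulable, 1):
                    raise DomainError(
                        f"aborting build: {n_failed}/{n_simulable} points failed"
                    )
            done[index] = True
        if checkpoint_path is not None:
            sbio.save_checkpoint(checkpoint_path, attenuation, refraction, valid, done)

    return SurrogateTensors(
        attenuation=attenuation, refraction=refraction, valid=valid,
        grid=grid, metadata=metadata,
    )


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("skullbeam")
    except Exception:
        return "unknown"
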