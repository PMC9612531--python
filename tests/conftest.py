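import numpy as np
import pytest

from skullbeam.builder import AXIS_NAMES, ParameterGrid, SurrogateTensors
from skullbeam.geometry import GridSpec, MaterialProps, Scene, TransducerSpec

LOSSLESS_WATER = MaterialProps(
    density=1000.0, sound_speed=1482.0, absorption_coeff=0.0, absorption_power=2.0
)


@pytest.fixture(scope="session")
def small_grid_2d() -> GridSpec:
    return GridSpec(shape=(96, 96), spacing=1e-3, pml_size=10, pml_alpha=2.0)


@pytest.fixture(scope="session")
def small_grid_3d() -> GridSpec:
    return GridSpec(shape=(64, 64, 64), spacing=1e-3, pml_size=10, pml_alpha=2.0)


def plane_wave_scene(
    alpha: float = 0.0,
    nx: int = 192,
    ny: int = 32,
    frequency: float = 1e6,
    spacing: float = 0.5e-3,
    bone_slab: tuple[int, int] | None = None,
    source_plane: int = 20,
    bone_absorption: float | None = None,
) -> Scene:
    """1-D-like plane-wave scene: full-width sheet source, periodic lateral
    boundary (PML only along the propagation axis)."""
    grid = GridSpec(shape=(nx, ny), spacing=spacing, pml_size=10,
                    pml_alpha=2.0, pml_axes=(0,))
    td = TransducerSpec(diameter=40e-3, focal_depth=40e-3,
                        carrier_frequency=frequency, source_pressure=1.0)
    density = np.full(grid.shape, 1000.0)
    speed = np.full(grid.shape, 1482.0)
    absorb = np.full(grid.shape, alpha)
    if bone_slab is not None:
        i0, n = bone_slab
        density[i0:i0 + n] = 1732.0
        speed[i0:i0 + n] = 2850.0
        absorb[i0:i0 + n] = 85.0 * (frequency / 1e6) if bone_absorption is None \
            else bone_absorption
    src = np.zeros(grid.shape, bool)
    src[source_plane, :] = True
    search = np.zeros(grid.shape, bool)
    search[source_plane + 10:-grid.pml_size] = True
    return Scene(
        grid=grid, transducer=td, density_map=density, speed_map=speed,
        absorption_map=absorb, source_mask=src, search_mask=search,
        bone_thickness=0.0, has_bone=bone_slab is not None,
    )


def toy_tensors(rng: np.random.Generator, shape=(3, 3, 3, 3, 3)) -> SurrogateTensors:
    """Random but physically plausible surrogate tensors on an all-valid grid."""
    levels = {
        "frequency": np.linspace(2.5e5, 1e6, shape[0]),
        "thickness": np.linspace(1e-3, 12e-3, shape[1]),
        "trajectory": np.linspace(40.0, 90.0, shape[2]),
        "depth": np.linspace(30e-3, 80e-3, shape[3]),
        "diameter": np.linspace(30e-3, 80e-3, shape[4]),
    }
    grid = ParameterGrid(levels=levels)
    return SurrogateTensors(
        attenuation=rng.uniform(0.0, 100.0, shape),
        refraction=rng.uniform(0.0, 20.0, shape),
        valid=np.ones(shape, dtype=bool),
        grid=grid,
        metadata={"origin": "toy"},
    )
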