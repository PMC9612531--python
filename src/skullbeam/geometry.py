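"""Voxelized simulation scenes for transcranial focused-ultrasound modelling.

A scene is a rectangular grid of voxels holding two-valued material maps
(water everywhere except a flat bone slab), a focused-bowl transducer
rasterized as a one-voxel-thick spherical-cap shell, a perfectly matched
layer (PML) description, and a search mask marking the region on the brain
side of the bone in which focal peaks are located.

Conventions
-----------
* Axis 0 is the transducer's nominal beam axis at normal incidence
  (trajectory 90 degrees); voxel indices are 0-based and physical positions
  are voxel centers at ``index * spacing``.
* The trajectory angle is measured between the beam axis and the bone
  surface, so 90 degrees means the transducer face lies flat against bone
  and smaller angles tilt the beam; the bone slab itself never rotates
  (it stays axis-aligned to avoid an aliased surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, GeometryError

__all__ = [
    "GridSpec",
    "MaterialProps",
    "TransducerSpec",
    "Scene",
    "WATER",
    "BONE",
    "compute_radius_of_curvature",
    "water_absorption",
    "grid_metrics",
    "voxelize_bowl",
    "build_bone_slab",
    "assemble_scene",
]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular voxel grid with an absorbing boundary layer.

    Parameters
    ----------
    shape
        Voxels per axis; two or three axes.
    spacing
        Isotropic voxel edge length in meters.
    pml_size
        Perfectly-matched-layer thickness in voxels on every side.
    pml_alpha
        Dimensionless PML absorption strength.
    """

    shape: tuple[int, ...]
    spacing: float
    pml_size: int = 10
    pml_alpha: float = 2.0
    pml_axes: tuple[int, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.pml_axes is not None:
            object.__setattr__(self, "pml_axes", tuple(int(a) for a in self.pml_axes))
        if len(self.shape) not in (2, 3):
            raise GeometryError(f"grid must have 2 or 3 axes, got {len(self.shape)}")
        if self.spacing <= 0:
            raise GeometryError("spacing must be positive")
        if self.pml_size < 0 or self.pml_alpha < 0:
            raise GeometryError("pml_size and pml_alpha must be non-negative")
        if any(self.shape[ax] < 4 * self.pml_size for ax in self.absorbing_axes):
            raise GeometryError(
                f"every axis ({self.shape}) must span at least 4 x pml_size "
                f"({self.pml_size}) voxels"
            )

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def absorbing_axes(self) -> tuple[int, ...]:
        """Axes carrying a PML; the rest are periodic (plane-wave studies)."""
        if self.pml_axes is None:
            return tuple(range(self.ndim))
        return self.pml_axes

    @property
    def interior_extent(self) -> tuple[float, ...]:
        """Physical extent per axis excluding the PML, meters."""
        return tuple((n - 2 * self.pml_size) * self.spacing for n in self.shape)

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of voxels outside the PML."""
        mask = np.ones(self.shape, dtype=bool)
        p = self.pml_size
        if p > 0:
            for ax in self.absorbing_axes:
                sl = [slice(None)] * self.ndim
                sl[ax] = slice(0, p)
                mask[tuple(sl)] = False
                sl[ax] = slice(-p, None)
                mask[tuple(sl)] = False
        return mask


@dataclass(frozen=True)
class MaterialProps:
    """Acoustic material parameters.

    ``absorption_coeff`` is the power-law prefactor in Np MHz^-power m^-1,
    i.e. the absorption at the carrier is
    ``absorption_coeff * (f / 1 MHz) ** absorption_power`` in Np/m.
    """

    density: float
    sound_speed: float
    absorption_coeff: float = 0.0
    absorption_power: float = 1.0

    def __post_init__(self):
        if self.density <= 0 or self.sound_speed <= 0:
            raise DomainError("density and sound_speed must be positive")
        if self.absorption_coeff < 0:
            raise DomainError("absorption_coeff must be non-negative")
        if not 0.0 <= self.absorption_power <= 3.0:
            raise DomainError("absorption_power must lie in [0, 3]")

    def absorption_at(self, frequency: float) -> float:
        """Absorption in Np/m at ``frequency`` (Hz)."""
        return self.absorption_coeff * (frequency / 1e6) ** self.absorption_power

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*c, Rayl."""
        return self.density * self.sound_speed


# Bulk-bone and body-temperature water values used for all default scenes.
BONE = MaterialProps(density=1732.0, sound_speed=2850.0,
                     absorption_coeff=85.0, absorption_power=1.0)


def compute_radius_of_curvature(focal_depth: float, radius: float) -> float:
    """Radius of curvature of a focused bowl from focal depth and aperture radius.

    The bowl is the spherical cap whose center of curvature sits at the
    geometric focus, ``focal_depth`` beyond the aperture (rim) plane, so
    ``roc = sqrt(focal_depth**2 + radius**2)``.
    """
    if focal_depth <= 0:
        raise GeometryError("focal_depth must be positive")
    if radius < 0:
        raise GeometryError("aperture radius must be non-negative")
    return float(np.hypot(focal_depth, radius))


@dataclass(frozen=True)
class TransducerSpec:
    """Single-element focused bowl transducer.

    ``focal_depth`` is the distance from the aperture (rim) plane to the
    geometric focus along the beam axis; ``radius_of_curvature`` is derived
    from it and the aperture radius. ``trajectory_deg`` is the angle between
    the beam axis and the bone surface (90 = normal incidence).
    """

    diameter: float
    focal_depth: float
    carrier_frequency: float
    source_pressure: float = 1.0558e6
    trajectory_deg: float = 90.0
    radius_of_curvature: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.diameter <= 0 or self.focal_depth <= 0:
            raise GeometryError("diameter and focal_depth must be positive")
        if not 0.0 < self.trajectory_deg <= 90.0:
            raise GeometryError("trajectory_deg must lie in (0, 90]")
        if self.carrier_frequency <= 0:
            raise DomainError("carrier_frequency must be positive")
        roc = compute_radius_of_curvature(self.focal_depth, self.diameter / 2)
        if self.radius_of_curvature is None:
            object.__setattr__(self, "radius_of_curvature", roc)
        elif abs(self.radius_of_curvature - roc) > 1e-12 * roc:
            raise GeometryError(
                "radius_of_curvature inconsistent with focal_depth and diameter"
            )

    @property
    def aperture_radius(self) -> float:
        return self.diameter / 2

    @property
    def cap_height(self) -> float:
        """Axial depth of the concave cap (apex to rim plane), meters."""
        return self.radius_of_curvature - self.focal_depth

    @property
    def tilt_deg(self) -> float:
        """Tilt of the beam axis away from axis 0 (0 at normal incidence)."""
        return 90.0 - self.trajectory_deg


# Pure-water ultrasonic absorption divided by frequency squared,
# alpha/f^2 in 1e-15 Np s^2 / m, against temperature in Celsius
# (classical pure-water measurement compilation; quadratic in frequency).
_WATER_ABS_T = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0])
_WATER_ABS_A = np.array([56.9, 44.1, 35.8, 29.8, 25.3, 22.0, 19.1, 14.6, 11.9, 10.2])
_water_abs_fit = PchipInterpolator(_WATER_ABS_T, _WATER_ABS_A)


def water_absorption(frequency: float, temperature: float = 37.0) -> float:
    """Absorption of pure water in Np/m at the given frequency and temperature.

    Uses a monotone piecewise-polynomial fit in temperature to published
    pure-water alpha/f^2 measurements, with the classical quadratic
    frequency dependence.

    Parameters
    ----------
    frequency
        Acoustic frequency, Hz.
    temperature
        Water temperature, degrees Celsius, in (0, 60).
    """
    if not 0.0 < temperature < 60.0:
        raise DomainError(f"temperature {temperature} C outside supported (0, 60)")
    if frequency <= 0:
        raise DomainError("frequency must be positive")
    alpha_over_f2 = float(_water_abs_fit(temperature)) * 1e-15  # Np s^2 / m
    return alpha_over_f2 * frequency**2


def water_material(temperature: float = 37.0) -> MaterialProps:
    """Body-temperature water with its quadratic absorption law."""
    return MaterialProps(
        density=1000.0,
        sound_speed=1482.0,
        absorption_coeff=water_absorption(1e6, temperature),
        absorption_power=2.0,
    )


WATER = water_material()


def grid_metrics(
    grid: GridSpec,
    medium_speed: float,
    frequency: float,
    cfl: float = 0.3,
    max_speed: float | None = None,
    t_end: float | None = None,
) -> dict:
    """Derived spatial/temporal discretization quantities.

    Returns points-per-wavelength (``ppw``), the interior extent per axis,
    and — when ``t_end`` is given — the stable time step
    ``dt = cfl * spacing / max_speed`` and the step count ``round(t_end/dt)``.
    """
    if medium_speed <= 0 or frequency <= 0 or cfl <= 0:
        raise DomainError("medium_speed, frequency and cfl must be positive")
    if cfl > 1:
        raise DomainError("cfl must not exceed 1")
    out = {
        "ppw": (medium_speed / frequency) / grid.spacing,
        "interior_extent": grid.interior_extent,
    }
    if max_speed is None:
        max_speed = medium_speed
    if max_speed <= 0:
        raise DomainError("max_speed must be positive")
    out["dt"] = cfl * grid.spacing / max_speed
    if t_end is not None:
        if t_end <= 0:
            raise DomainError("t_end must be positive")
        out["n_steps"] = int(round(t_end / out["dt"]))
    return out


def _voxel_centers(grid: GridSpec) -> list[np.ndarray]:
    """Per-axis physical coordinates of voxel centers (open meshgrid)."""
    axes = [np.arange(n, dtype=float) * grid.spacing for n in grid.shape]
    return list(np.meshgrid(*axes, indexing="ij", sparse=True))


def _bowl_frame(
    grid: GridSpec, transducer: TransducerSpec, apex_position, tilt_deg: float
):
    """Sphere center and beam-axis unit vector of the (possibly tilted) bowl.

    The bowl is tilted by rotating its defining sphere about the aperture-rim
    point nearest the domain interior (largest axis-1 coordinate), in the
    (axis 0, axis 1) plane, so the focus moves away from the PML.
    """
    ndim = grid.ndim
    apex = np.asarray(apex_position, dtype=float) * grid.spacing
    if apex.shape != (ndim,):
        raise GeometryError(f"apex_position must have {ndim} coordinates")
    roc = transducer.radius_of_curvature
    e0 = np.zeros(ndim)
    e0[0] = 1.0
    e1 = np.zeros(ndim)
    e1[1] = 1.0
    # untilted: center of curvature straight down the grid's 0-axis
    center = apex + roc * e0
    axis_dir = e0.copy()
    theta = np.deg2rad(tilt_deg)
    if theta != 0.0:
        pivot = apex + transducer.cap_height * e0 + transducer.aperture_radius * e1
        c, s = np.cos(theta), np.sin(theta)

        def rotate(v):
            d = v - pivot
            d0, d1 = d[0], d[1]
            d = d.copy()
            d[0] = c * d0 - s * d1
            d[1] = s * d0 + c * d1
            return pivot + d

        center = rotate(center)
        axis_dir = np.zeros(ndim)
        axis_dir[0] = c
        axis_dir[1] = s
    return apex, center, axis_dir


def voxelize_bowl(
    grid: GridSpec,
    transducer: TransducerSpec,
    apex_position,
    tilt_deg: float = 0.0,
) -> np.ndarray:
    """Rasterize a focused bowl as a one-voxel-thick spherical-cap shell.

    A voxel belongs to the shell when its center lies within half a voxel
    diagonal of the defining sphere and inside the aperture cone of the cap.
    ``apex_position`` is the voxel coordinate of the cap apex (back of the
    concavity); in two dimensions the "bowl" is the corresponding arc.

    Raises
    ------
    GeometryError
        If any shell voxel falls inside the PML or outside the grid.
    """
    apex, center, axis_dir = _bowl_frame(grid, transducer, apex_position, tilt_deg)
    roc = transducer.radius_of_curvature
    half_diag = grid.spacing * np.sqrt(grid.ndim) / 2.0
    coords = _voxel_centers(grid)

    dist_sq = sum((coords[i] - center[i]) ** 2 for i in range(grid.ndim))
    dist = np.sqrt(dist_sq)
    on_sphere = np.abs(dist - roc) <= half_diag
    # aperture cone: axial component of (x - center) along the beam axis must
    # reach past the rim plane toward the apex
    axial = sum((coords[i] - center[i]) * axis_dir[i] for i in range(grid.ndim))
    in_cap = axial <= -(transducer.focal_depth - grid.spacing / 2.0)
    # clamp the rim so the cap's chord stays within one voxel of the
    # requested aperture diameter
    lateral_sq = dist_sq - axial**2
    in_aperture = lateral_sq <= (transducer.aperture_radius + grid.spacing / 2.0) ** 2
    mask = on_sphere & in_cap & in_aperture

    if not mask.any():
        raise GeometryError("bowl rasterization produced an empty mask")
    p = grid.pml_size
    idx = np.nonzero(mask)
    for ax in grid.absorbing_axes:
        lo, hi = idx[ax].min(), idx[ax].max()
        if lo < p or hi >= grid.shape[ax] - p:
            raise GeometryError(
                f"bowl extends into the PML along axis {ax} "
                f"(indices {lo}..{hi}, interior {p}..{grid.shape[ax] - p - 1})"
            )
    return mask


def build_bone_slab(
    grid: GridSpec, thickness: float, standoff_plane: int
) -> np.ndarray:
    """Axis-aligned flat bone slab of ``round(thickness / spacing)`` planes.

    The slab occupies consecutive voxel planes perpendicular to axis 0
    starting at ``standoff_plane``; it stays axis-aligned regardless of
    transducer tilt so the bone surface is never aliased.
    """
    if thickness < 0:
        raise GeometryError("thickness must be non-negative")
    n_planes = int(round(thickness / grid.spacing))
    mask = np.zeros(grid.shape, dtype=bool)
    if n_planes == 0:
        return mask
    p = grid.pml_size
    if standoff_plane < p or standoff_plane + n_planes > grid.shape[0] - p:
        raise GeometryError(
            f"bone slab ({n_planes} planes from {standoff_plane}) does not fit "
            f"inside the interior along axis 0"
        )
    mask[standoff_plane : standoff_plane + n_planes] = True
    return mask


@dataclass
class Scene:
    """Fully assembled voxel scene ready for the wave solver.

    Material maps are two-valued (water / bone). ``search_mask`` marks the
    voxels eligible for focal-peak search: strictly beyond the inner face of
    the (possibly zero-thickness) bone slab, outside the PML and outside the
    transducer concavity. The search mask depends on the nominal bone
    thickness but not on ``has_bone``, so paired bone/water simulations
    search identical regions.
    """

    grid: GridSpec
    transducer: TransducerSpec
    density_map: np.ndarray
    speed_map: np.ndarray
    absorption_map: np.ndarray
    source_mask: np.ndarray
    search_mask: np.ndarray
    bone_thickness: float
    has_bone: bool
    apex_index: tuple[int, ...] = ()
    source_phase: np.ndarray | None = None

    def __post_init__(self):
        for name in ("density_map", "speed_map", "absorption_map",
                     "source_mask", "search_mask"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise GeometryError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if (self.source_mask & self.search_mask).any():
            raise GeometryError("source_mask and search_mask must be disjoint")

    @property
    def max_sound_speed(self) -> float:
        return float(self.speed_map.max())

    def source_signal(self, times: np.ndarray, ramp_cycles: float = 3.0) -> np.ndarray:
        """Sinusoidal drive at the carrier with a cosine-taper onset.

        The envelope rises as ``(1 - cos(pi t / t_ramp)) / 2`` over
        ``ramp_cycles`` carrier cycles, then stays at the full source
        pressure amplitude.
        """
        f = self.transducer.carrier_frequency
        t_ramp = ramp_cycles / f
        env = np.ones_like(times)
        if t_ramp > 0:
            rising = times < t_ramp
            env[rising] = 0.5 * (1.0 - np.cos(np.pi * times[rising] / t_ramp))
        return self.transducer.source_pressure * env * np.sin(2 * np.pi * f * times)


def assemble_scene(
    grid: GridSpec,
    transducer: TransducerSpec,
    thickness: float,
    with_bone: bool,
    bone: MaterialProps = BONE,
    water: MaterialProps = WATER,
    apex_position=None,
) -> Scene:
    """Build a complete scene: transducer shell, flat bone slab, material maps.

    The transducer apex is placed on the first interior voxel plane along
    axis 0 (meeting the PML), laterally centered, and tilted by
    ``90 - trajectory_deg`` degrees away from the PML. The bone slab's outer
    face sits on the first voxel plane past the deepest transducer voxel, so
    the slab meets the transducer face; the slab never tilts.
    """
    if apex_position is None:
        apex_position = (grid.pml_size,) + tuple(n // 2 for n in grid.shape[1:])
    source_mask = voxelize_bowl(grid, transducer, apex_position, transducer.tilt_deg)
    # phase-compensate the rasterized shell: each voxel center sits up to half
    # a voxel diagonal off the defining sphere; advancing its drive phase by
    # k (r - R) realigns all contributions at the geometric focus, so the
    # discrete shell radiates like the ideal thin cap
    _, center, _ = _bowl_frame(grid, transducer, apex_position, transducer.tilt_deg)
    vox = np.argwhere(source_mask) * grid.spacing
    r_vox = np.linalg.norm(vox - center[None, :], axis=1)
    k_src = 2 * np.pi * transducer.carrier_frequency / water.sound_speed
    source_phase = k_src * (r_vox - transducer.radius_of_curvature)
    face = int(np.nonzero(source_mask)[0].max()) + 1
    n_planes = int(round(thickness / grid.spacing))
    slab = build_bone_slab(grid, thickness if with_bone else 0.0, face)

    f = transducer.carrier_frequency
    density = np.full(grid.shape, water.density)
    speed = np.full(grid.shape, water.sound_speed)
    absorption = np.full(grid.shape, water.absorption_at(f))
    if slab.any():
        density[slab] = bone.density
        speed[slab] = bone.sound_speed
        absorption[slab] = bone.absorption_at(f)

    # peak search: interior, strictly beyond the slab's inner face (brain
    # side), independent of with_bone so bone/water pairs share the mask
    search = grid.interior_mask()
    search[: face + n_planes + 1] = False
    search &= ~source_mask

    return Scene(
        grid=grid,
        transducer=transducer,
        density_map=density,
        speed_map=speed,
        absorption_map=absorption,
        source_mask=source_mask,
        search_mask=search,
        bone_thickness=thickness,
        has_bone=bool(with_bone and n_planes > 0),
        apex_index=tuple(int(i) for i in np.atleast_1d(apex_position)),
        source_phase=source_phase,
    )
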