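"""Closed-form and semi-analytic reference fields for solver validation.

Contains the classic focused spherical-cap radiator on-axis solution, a
Rayleigh–Sommerfeld surface-integral oracle for the same source, the
three-medium (water–bone–water) plane-wave transmission coefficient, and
the focal-region area-under-curve deviation metric used to compare
simulated and analytic axial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AccuracyError, DomainError
from .geometry import MaterialProps, TransducerSpec

__all__ = [
    "AxialProfile",
    "oneil_axial_pressure",
    "rayleigh_field",
    "slab_transmission",
    "focal_auc_deviation",
]


@dataclass
class AxialProfile:
    """On-axis pressure-magnitude profile.

    ``positions`` are measured along the beam axis from the back of the
    transducer concavity (the cap apex), meters; ``pressure`` is the
    steady-state pressure amplitude in Pa.
    """

    positions: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.positions.shape != self.pressure.shape:
            raise DomainError("positions and pressure must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise DomainError("positions must be strictly increasing")
        if np.any(self.pressure < 0):
            raise DomainError("pressure must be non-negative")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.positions, self.pressure]),
            delimiter=",",
            header="position_m,pressure_pa",
            comments="",
        )


def oneil_axial_pressure(
    transducer: TransducerSpec,
    medium: MaterialProps,
    positions: np.ndarray,
) -> AxialProfile:
    """On-axis pressure of a uniformly driven focused spherical cap.

    For a cap of curvature radius ``R``, aperture radius ``a`` and uniform
    normal surface velocity ``u0 = p0 / (rho c)``, the classic solution has
    magnitude ``2 rho c u0 |sin(k (r_e - z) / 2)| / |1 - z/R|`` on the axis,
    where ``z`` is the distance from the apex and ``r_e`` the distance from
    the field point to the cap rim. The geometric-focus singularity is
    removable: the identity ``r_e - z = 2 h (R - z)/(r_e + z)`` (``h`` the
    cap height) lets the profile be evaluated in the stable form

        ``|p(z)| = p0 k (2 h R / (r_e + z)) |sinc(k h (R - z)/(r_e + z))|``

    with limit ``p0 k h`` (the focal gain) exactly at the focus.
    """
    z = np.asarray(positions, dtype=float)
    if np.any(z <= 0) or np.any(z > 4 * transducer.focal_depth):
        raise DomainError("positions must lie in (0, 4 x focal_depth]")
    R = transducer.radius_of_curvature
    a = transducer.aperture_radius
    h = transducer.cap_height
    k = 2 * np.pi * transducer.carrier_frequency / medium.sound_speed
    p0 = transducer.source_pressure
    r_edge = np.sqrt((z - h) ** 2 + a**2)
    x = k * h * (R - z) / (r_edge + z)  # = k (r_e - z) / 2, singularity-free
    mag = p0 * k * (2 * h * R / (r_edge + z)) * np.abs(np.sinc(x / np.pi))
    return AxialProfile(positions=z, pressure=mag)


def rayleigh_field(
    transducer: TransducerSpec,
    medium: MaterialProps,
    points: np.ndarray,
    elements_per_wavelength: float = 10.0,
) -> np.ndarray:
    """Pressure magnitude from a numerical Rayleigh integral over the cap.

    The concave cap surface is discretized into rings of surface elements
    (at least ``elements_per_wavelength`` per acoustic wavelength along both
    the arc and the circumference) and the baffled-source surface integral

        ``p(x) = -i omega rho u0 / (2 pi) * sum  e^{i k r} / r dS``

    is evaluated at each field point. Points are given in a frame whose
    origin is the cap apex with the beam axis along coordinate 0 (the two
    remaining coordinates are lateral); a (n, 3) array is expected.
    """
    if elements_per_wavelength < 4:
        raise AccuracyError(
            "surface discretization coarser than 4 elements per wavelength"
        )
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise DomainError("points must be (n, 3) in the apex frame")
    R = transducer.radius_of_curvature
    a = transducer.aperture_radius
    lam = medium.sound_speed / transducer.carrier_frequency
    k = 2 * np.pi / lam
    alpha = np.arcsin(a / R)

    n_theta = max(8, int(np.ceil(R * alpha / (lam / elements_per_wavelength))))
    n_phi = max(8, int(np.ceil(2 * np.pi * a / (lam / elements_per_wavelength))))
    theta = (np.arange(n_theta) + 0.5) * alpha / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    d_s = (R**2 * np.sin(theta) * (alpha / n_theta) * (2 * np.pi / n_phi))

    # surface points in the apex frame: axial = R (1 - cos theta)
    ax_s = R * (1.0 - np.cos(theta))[:, None] * np.ones_like(phi)[None, :]
    rad = (R * np.sin(theta))[:, None]
    y_s = rad * np.cos(phi)[None, :]
    z_s = rad * np.sin(phi)[None, :]
    surf = np.stack([ax_s.ravel(), y_s.ravel(), z_s.ravel()], axis=1)
    d_s = np.broadcast_to(d_s[:, None], ax_s.shape).ravel()

    u0 = transducer.source_pressure / (medium.density * medium.sound_speed)
    omega = 2 * np.pi * transducer.carrier_frequency
    out = np.empty(pts.shape[0])
    coeff = omega * medium.density * u0 / (2 * np.pi)
    for i, x in enumerate(pts):
        r = np.linalg.norm(surf - x[None, :], axis=1)
        if np.any(r < 1e-12):
            raise DomainError("field point lies on the source surface")
        out[i] = coeff * np.abs(np.sum(np.exp(1j * k * r) / r * d_s))
    return out


def slab_transmission(
    water: MaterialProps,
    bone: MaterialProps,
    thickness: float,
    frequency: float,
) -> float:
    """Intensity transmission of a normal-incidence plane wave through a slab.

    Standard three-medium (water-bone-water) transfer-matrix result with a
    complex wavenumber in bone, ``k2 = omega/c2 - i alpha2`` (absorption at
    the carrier), so internal multiples and layer resonances are included.
    Returns the transmitted/incident intensity fraction in [0, 1].
    """
    if thickness < 0:
        raise DomainError("thickness must be non-negative")
    if frequency <= 0:
        raise DomainError("frequency must be positive")
    if thickness == 0:
        return 1.0
    omega = 2 * np.pi * frequency
    z1 = water.impedance
    z2 = bone.impedance
    k2 = omega / bone.sound_speed - 1j * bone.absorption_at(frequency)
    kd = k2 * thickness
    t = 2.0 / (2.0 * np.cos(kd) + 1j * (z2 / z1 + z1 / z2) * np.sin(kd))
    return float(np.abs(t) ** 2)


def _focal_region(pressure: np.ndarray) -> slice:
    """Contiguous index range around the global peak where the intensity
    (pressure squared) stays at or above 50% of its maximum (-3 dB)."""
    if pressure.size == 0 or np.all(pressure == 0):
        raise DomainError("profile has no focal region")
    peak = int(np.argmax(pressure))
    thresh = pressure[peak] * np.sqrt(0.5)  # 50% of intensity
    lo = peak
    while lo > 0 and pressure[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < pressure.size - 1 and pressure[hi + 1] >= thresh:
        hi += 1
    return slice(lo, hi + 1)


def focal_auc_deviation(profile_a: AxialProfile, profile_b: AxialProfile) -> float:
    """Percent deviation of focal-region area under the curve, a vs b.

    Each profile is restricted to its own contiguous -3 dB focal region
    (intensity >= 50% of its maximum) around its global peak; areas are
    computed by the trapezoid rule over position and compared as
    ``100 |AUC_a - AUC_b| / AUC_b`` with ``b`` the analytic reference.
    Both profiles must share the same position vector.
    """
    if profile_a.positions.shape != profile_b.positions.shape or np.any(
        profile_a.positions != profile_b.positions
    ):
        raise DomainError("profiles must share positions; resample beforehand")
    sl_a = _focal_region(profile_a.pressure)
    sl_b = _focal_region(profile_b.pressure)
    auc_a = np.trapezoid(profile_a.pressure[sl_a], profile_a.positions[sl_a])
    auc_b = np.trapezoid(profile_b.pressure[sl_b], profile_b.positions[sl_b])
    if auc_b <= 0:
        raise DomainError("reference profile has empty focal region")
    return float(100.0 * abs(auc_a - auc_b) / auc_b)
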