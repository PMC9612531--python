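"""Interpolating queries and visualization over surrogate tensors.

``query`` answers a single five-parameter question by multilinear
interpolation of the attenuation and refraction tensors, with the tool's
error semantics: points outside the sampled hull raise
:class:`~skullbeam.errors.OutOfRangeError`, and points whose enclosing
2^5 cell touches an invalid entry (focus inside bone / outside the head)
raise :class:`~skullbeam.errors.InvalidRegionError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .builder import AXIS_NAMES, ParameterGrid, ParameterPoint, SurrogateTensors
from .errors import DomainError, InvalidRegionError, OutOfRangeError
from .solver import PressureRecord, extract_peak

__all__ = ["QueryResult", "query", "vis2d", "render_comparison"]


@dataclass(frozen=True)
class QueryResult:
    """Interpolated estimate plus the identity of the nearest stored run."""

    attenuation: float
    refraction: float
    nearest_index: tuple[int, ...]
    nearest_point: ParameterPoint


def _locate(levels: np.ndarray, value: float, axis: str) -> tuple[int, float]:
    """Enclosing-cell lower index and fractional offset along one axis.

    The sampled hull is treated as closed: values exactly on the boundary
    are accepted.
    """
    lo, hi = levels[0], levels[-1]
    if not lo <= value <= hi:
        raise OutOfRangeError(
            f"{axis} = {value} outside sampled range [{lo}, {hi}]"
        )
    i = int(np.searchsorted(levels, value, side="right")) - 1
    i = min(max(i, 0), levels.size - 2)
    frac = (value - levels[i]) / (levels[i + 1] - levels[i])
    return i, frac


def _nearest_level(levels: np.ndarray, value: float) -> int:
    """Index of the closest level; ties resolve toward the lower index."""
    return int(np.argmin(np.abs(levels - value)))


def query(tensors: SurrogateTensors, point: ParameterPoint) -> QueryResult:
    """Multilinear (5-linear) interpolation of both tensors at one point.

    Raises an error when the point leaves the sampled hull or when any of
    the 32 corners of the enclosing cell is invalid.
    """
    values = point.as_tuple()
    cells = []
    for name, v in zip(AXIS_NAMES, values):
        cells.append(_locate(tensors.grid.levels[name], v, name))
    corner = tuple(
        slice(i, i + 2) for (i, _) in cells
    )
    if not tensors.valid[corner].all():
        raise InvalidRegionError(
            "query cell touches an invalid region (focus inside bone or "
            f"outside the head) at {point}"
        )
    coords = [tensors.grid.levels[name] for name in AXIS_NAMES]
    att = float(RegularGridInterpolator(coords, tensors.attenuation)(values))
    refr = float(RegularGridInterpolator(coords, tensors.refraction)(values))
    nearest = tuple(
        _nearest_level(tensors.grid.levels[name], v)
        for name, v in zip(AXIS_NAMES, values)
    )
    return QueryResult(
        attenuation=att,
        refraction=refr,
        nearest_index=nearest,
        nearest_point=tensors.grid.point(nearest),
    )


def vis2d(
    tensors: SurrogateTensors,
    fixed: dict,
    upsample: int = 10,
) -> dict:
    """Two 2-D maps (attenuation, refraction) over the two free axes.

    ``fixed`` assigns values to exactly three of the five axes; the slice
    is taken by interpolating along the fixed axes at every node of the two
    free axes, then upsampled by linear interpolation by the integer factor
    ``upsample`` (coarse nodes are preserved exactly).

    Returns a dict with ``attenuation``, ``refraction`` (2-D arrays),
    ``axes`` (the two free axis names) and ``coords`` (their upsampled
    coordinates).
    """
    if len(fixed) != 3 or not set(fixed) <= set(AXIS_NAMES):
        raise DomainError("fixed must assign exactly three of the five axes")
    if upsample < 1:
        raise DomainError("upsample must be >= 1")
    free = [a for a in AXIS_NAMES if a not in fixed]
    for name, v in fixed.items():
        _locate(tensors.grid.levels[name], v, name)  # range check

    coords = [tensors.grid.levels[name] for name in AXIS_NAMES]
    f0, f1 = (tensors.grid.levels[a] for a in free)
    mesh = np.meshgrid(f0, f1, indexing="ij")
    pts = np.empty(mesh[0].shape + (5,))
    for k, name in enumerate(AXIS_NAMES):
        if name in fixed:
            pts[..., k] = fixed[name]
        else:
            pts[..., k] = mesh[free.index(name)]

    valid_interp = RegularGridInterpolator(coords, tensors.valid.astype(float))
    if not np.all(valid_interp(pts) == 1.0):
        raise InvalidRegionError("slice touches invalid surrogate entries")

    coarse_att = RegularGridInterpolator(coords, tensors.attenuation)(pts)
    coarse_ref = RegularGridInterpolator(coords, tensors.refraction)(pts)

    up0 = np.linspace(f0[0], f0[-1], (f0.size - 1) * upsample + 1)
    up1 = np.linspace(f1[0], f1[-1], (f1.size - 1) * upsample + 1)
    if upsample == 1:
        up0, up1 = f0.copy(), f1.copy()
    umesh = np.meshgrid(up0, up1, indexing="ij")
    upts = np.stack([umesh[0], umesh[1]], axis=-1)
    att = RegularGridInterpolator((f0, f1), coarse_att)(upts)
    refr = RegularGridInterpolator((f0, f1), coarse_ref)(upts)
    return {
        "attenuation": att,
        "refraction": refr,
        "axes": tuple(free),
        "coords": (up0, up1),
    }


def _central_slice(field: np.ndarray, index: tuple[int, ...]) -> np.ndarray:
    """2-D view of a field: identity in 2-D, plane through ``index`` in 3-D."""
    if field.ndim == 2:
        return field
    return field[:, :, index[2]]


def render_comparison(
    bone_record: PressureRecord,
    water_record: PressureRecord,
    search_mask: np.ndarray | None = None,
    save_path=None,
) -> dict:
    """Side-by-side intensity fields, their -3 dB regions, and the overlay.

    The -3 dB focal region is where intensity reaches at least 50% of that
    field's own (mask-restricted) maximum. Returns the underlying arrays —
    intensity fields, the two boolean regions, both peak locations and their
    distance in mm — and optionally writes a PNG.
    """
    if bone_record.grid != water_record.grid:
        raise DomainError("records must share the same grid")
    if search_mask is None:
        search_mask = bone_record.grid.interior_mask()

    out = {}
    peaks = {}
    for name, rec in (("bone", bone_record), ("water", water_record)):
        intensity = rec.max_pressure**2
        peak = extract_peak(rec, search_mask)
        region = intensity >= 0.5 * peak["peak_intensity"]
        region &= search_mask
        out[f"intensity_{name}"] = intensity
        out[f"region_{name}"] = region
        out[f"peak_{name}"] = peak
        peaks[name] = peak
    out["peak_distance_mm"] = float(
        np.linalg.norm(peaks["bone"]["location"] - peaks["water"]["location"]) * 1e3
    )

    if save_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        bidx = peaks["bone"]["index"]
        widx = peaks["water"]["index"]
        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        for row, name, pidx in ((0, "bone", bidx), (1, "water", widx)):
            img = _central_slice(out[f"intensity_{name}"], widx)
            reg = _central_slice(out[f"region_{name}"], widx)
            axes[row, 0].imshow(img.T, origin="lower", cmap="magma")
            axes[row, 0].set_title(f"{name}: intensity")
            axes[row, 1].imshow(reg.T, origin="lower", cmap="gray")
            axes[row, 1].set_title(f"{name}: -3 dB region")
            axes[row, 0].plot(pidx[0], pidx[1], "c+", ms=10)
        overlay = np.zeros(_central_slice(out["region_bone"], widx).shape + (3,))
        overlay[..., 0] = _central_slice(out["region_bone"], widx)
        overlay[..., 2] = _central_slice(out["region_water"], widx)
        axes[0, 2].imshow(np.swapaxes(overlay, 0, 1), origin="lower")
        axes[0, 2].plot(bidx[0], bidx[1], "r+", ms=10)
        axes[0, 2].plot(widx[0], widx[1], "b+", ms=10)
        axes[0, 2].set_title(
            f"overlay (peak distance {out['peak_distance_mm']:.1f} mm)"
        )
        axes[1, 2].axis("off")
        fig.tight_layout()
        fig.savefig(save_path, dpi=110)
        plt.close(fig)
        out["figure_path"] = str(save_path)
    return out
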