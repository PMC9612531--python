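"""HDF5 serialization of scenes, pressure records and surrogate tensors.

Layout of a surrogate file:

* ``/attenuation`` — 5-D percent tensor
* ``/refraction`` — 5-D mm tensor
* ``/valid`` — 5-D boolean mask
* ``/axes/<name>`` — axis coordinate levels, with a ``units`` attribute
* ``/metadata`` — JSON-encoded build settings

Round trips are bit-exact (no compression filters that alter values).
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .builder import AXIS_NAMES, ParameterGrid, SurrogateTensors
from .geometry import GridSpec, Scene, TransducerSpec
from .solver import PressureRecord

AXIS_UNITS = {
    "frequency": "Hz",
    "thickness": "m",
    "trajectory": "deg",
    "depth": "m",
    "diameter": "m",
}

__all__ = [
    "save_scene", "load_scene",
    "save_record", "load_record",
    "save_surrogate", "load_surrogate",
    "save_checkpoint", "load_checkpoint",
]


def _write_grid(group: h5py.Group, grid: GridSpec) -> None:
    group.attrs["shape"] = grid.shape
    group.attrs["spacing_m"] = grid.spacing
    group.attrs["pml_size"] = grid.pml_size
    group.attrs["pml_alpha"] = grid.pml_alpha
    if grid.pml_axes is not None:
        group.attrs["pml_axes"] = grid.pml_axes


def _read_grid(group: h5py.Group) -> GridSpec:
    return GridSpec(
        shape=tuple(int(n) for n in group.attrs["shape"]),
        spacing=float(group.attrs["spacing_m"]),
        pml_size=int(group.attrs["pml_size"]),
        pml_alpha=float(group.attrs["pml_alpha"]),
        pml_axes=tuple(int(a) for a in group.attrs["pml_axes"])
        if "pml_axes" in group.attrs
        else None,
    )


def save_scene(path, scene: Scene) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        _write_grid(g, scene.grid)
        for name in ("density_map", "speed_map", "absorption_map"):
            d = f.create_dataset(name, data=getattr(scene, name))
            d.attrs["units"] = {"density_map": "kg/m^3", "speed_map": "m/s",
                                "absorption_map": "Np/m"}[name]
        f.create_dataset("source_mask", data=scene.source_mask)
        f.create_dataset("search_mask", data=scene.search_mask)
        f.attrs["bone_thickness_m"] = scene.bone_thickness
        f.attrs["has_bone"] = scene.has_bone
        f.attrs["apex_index"] = scene.apex_index
        t = scene.transducer
        td = f.create_group("transducer")
        td.attrs["diameter_m"] = t.diameter
        td.attrs["focal_depth_m"] = t.focal_depth
        td.attrs["carrier_frequency_hz"] = t.carrier_frequency
        td.attrs["source_pressure_pa"] = t.source_pressure
        td.attrs["trajectory_deg"] = t.trajectory_deg


def load_scene(path) -> Scene:
    with h5py.File(path, "r") as f:
        td = f["transducer"]
        transducer = TransducerSpec(
            diameter=float(td.attrs["diameter_m"]),
            focal_depth=float(td.attrs["focal_depth_m"]),
            carrier_frequency=float(td.attrs["carrier_frequency_hz"]),
            source_pressure=float(td.attrs["source_pressure_pa"]),
            trajectory_deg=float(td.attrs["trajectory_deg"]),
        )
        return Scene(
            grid=_read_grid(f["grid"]),
            transducer=transducer,
            density_map=f["density_map"][...],
            speed_map=f["speed_map"][...],
            absorption_map=f["absorption_map"][...],
            source_mask=f["source_mask"][...].astype(bool),
            search_mask=f["search_mask"][...].astype(bool),
            bone_thickness=float(f.attrs["bone_thickness_m"]),
            has_bone=bool(f.attrs["has_bone"]),
            apex_index=tuple(int(i) for i in f.attrs["apex_index"]),
        )


def save_record(path, record: PressureRecord) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("max_pressure", data=record.max_pressure)
        d.attrs["units"] = "Pa"
        f.attrs["n_steps"] = record.n_steps
        f.attrs["dt_s"] = record.dt
        _write_grid(f.create_group("grid"), record.grid)


def load_record(path) -> PressureRecord:
    with h5py.File(path, "r") as f:
        return PressureRecord(
            max_pressure=f["max_pressure"][...],
            grid=_read_grid(f["grid"]),
            n_steps=int(f.attrs["n_steps"]),
            dt=float(f.attrs["dt_s"]),
        )


def save_surrogate(path, tensors: SurrogateTensors) -> None:
    with h5py.File(path, "w") as f:
        a = f.create_dataset("attenuation", data=tensors.attenuation)
        a.attrs["units"] = "percent"
        r = f.create_dataset("refraction", data=tensors.refraction)
        r.attrs["units"] = "mm"
        f.create_dataset("valid", data=tensors.valid)
        axes = f.create_group("axes")
        for name in AXIS_NAMES:
            d = axes.create_dataset(name, data=tensors.grid.levels[name])
            d.attrs["units"] = AXIS_UNITS[name]
        f.create_dataset(
            "metadata", data=json.dumps(tensors.metadata, sort_keys=True)
        )


def load_surrogate(path) -> SurrogateTensors:
    with h5py.File(path, "r") as f:
        levels = {name: f["axes"][name][...] for name in AXIS_NAMES}
        meta = json.loads(f["metadata"][()].decode()
                          if isinstance(f["metadata"][()], bytes)
                          else str(f["metadata"][()]))
        return SurrogateTensors(
            attenuation=f["attenuation"][...],
            refraction=f["refraction"][...],
            valid=f["valid"][...].astype(bool),
            grid=ParameterGrid(levels=levels),
            metadata=meta,
        )


def save_checkpoint(path, attenuation, refraction, valid, done) -> None:
    """Partial-build state: tensors plus a done mask, overwritten atomically."""
    with h5py.File(path, "w") as f:
        f.create_dataset("attenuation", data=attenuation)
        f.create_dataset("refraction", data=refraction)
        f.create_dataset("valid", data=valid)
        f.create_dataset("done", data=done)


def load_checkpoint(path):
    """Return (attenuation, refraction, valid, done) or None if absent."""
    import os

    if not os.path.exists(path):
        return None
    with h5py.File(path, "r") as f:
        return (
            f["attenuation"][...],
            f["refraction"][...],
            f["valid"][...].astype(bool),
            f["done"][...].astype(bool),
        )
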