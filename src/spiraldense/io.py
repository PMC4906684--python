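"""Dataset container I/O and configuration round-tripping.

Complex k-space with arbitrary trajectories has no standard clinical format,
so datasets are stored in a self-describing HDF5 container:

    /images            complex (frame, encoding, coil, y, x) + axis labels
    /kspace/coords     (frame, interleaf, sample, 2) cycles/pixel
    /kspace/data       complex (frame, encoding, phase_cycle, coil, interleaf, sample)
    /kspace/dcf        (interleaf, sample)
    /maps              complex (coil, y, x) + /maps_support
    /meta              config echo (JSON), package version, seed

A reader stub for the ISMRMRD raw-data standard documents how external raw
files would map onto :class:`~spiraldense.phantom.KSpaceData`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict

import h5py
import numpy as np

from .coilmaps import CoilSensitivities
from .phantom import DenseImageSeries, KSpaceData, PhantomConfig
from .trajectory import SpiralTrajectory, TrajectoryConfig

__all__ = [
    "save_container",
    "load_container",
    "read_ismrmrd",
]

_FORMAT_VERSION = 1


def _config_json(cfg) -> str:
    return json.dumps(asdict(cfg)) if dataclasses.is_dataclass(cfg) else json.dumps(cfg)


def save_container(path, images: DenseImageSeries | None = None,
                   kspace: KSpaceData | None = None,
                   trajectory: SpiralTrajectory | None = None,
                   maps: CoilSensitivities | None = None,
                   meta: dict | None = None) -> None:
    """Write any subset of the dataset to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        if images is not None:
            d = f.create_dataset("images", data=images.data)
            d.attrs["axes"] = "frame,encoding,coil,y,x"
            d.attrs["encoding_labels"] = ",".join(images.encoding_labels)
            d.attrs["ke_cycles_per_mm"] = images.ke
            d.attrs["pixel_spacing_mm"] = images.pixel_spacing
            if images.config is not None:
                d.attrs["phantom_config"] = _config_json(images.config)
        traj = trajectory or (kspace.trajectory if kspace is not None else None)
        if traj is not None:
            g = f.require_group("kspace")
            g.create_dataset("coords", data=traj.coords)
            g["coords"].attrs["units"] = "cycles/pixel"
            g.create_dataset("dcf", data=traj.dcf)
            g.attrs["trajectory_config"] = _config_json(traj.config)
        if kspace is not None:
            g = f.require_group("kspace")
            d = g.create_dataset("data", data=kspace.data)
            d.attrs["axes"] = "frame,encoding,phase_cycle,coil,interleaf,sample"
            d.attrs["encoding_labels"] = ",".join(kspace.encoding_labels)
            d.attrs["ke_cycles_per_mm"] = kspace.ke
            d.attrs["pixel_spacing_mm"] = kspace.pixel_spacing
        if maps is not None:
            f.create_dataset("maps", data=maps.maps)
            f.create_dataset("maps_support", data=maps.support)
        if meta:
            g = f.require_group("meta")
            for k, v in meta.items():
                g.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v


def load_container(path) -> dict:
    """Read a container back into the package's in-memory types.  Returns a
    dict with whichever of ``images``, ``kspace``, ``trajectory``, ``maps``
    and ``meta`` the file holds."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        traj = None
        if "kspace" in f and "coords" in f["kspace"]:
            g = f["kspace"]
            cfg = json.loads(g.attrs["trajectory_config"])
            traj = SpiralTrajectory(coords=g["coords"][()], dcf=g["dcf"][()],
                                    config=TrajectoryConfig(**cfg))
            out["trajectory"] = traj
        if "images" in f:
            d = f["images"]
            cfg = None
            if "phantom_config" in d.attrs:
                cfg = PhantomConfig(**json.loads(d.attrs["phantom_config"]))
            out["images"] = DenseImageSeries(
                data=d[()],
                encoding_labels=tuple(d.attrs["encoding_labels"].split(",")),
                ke=float(d.attrs["ke_cycles_per_mm"]),
                pixel_spacing=float(d.attrs["pixel_spacing_mm"]),
                config=cfg,
            )
        if "kspace" in f and "data" in f["kspace"]:
            d = f["kspace/data"]
            out["kspace"] = KSpaceData(
                data=d[()], trajectory=traj,
                encoding_labels=tuple(d.attrs["encoding_labels"].split(",")),
                ke=float(d.attrs["ke_cycles_per_mm"]),
                pixel_spacing=float(d.attrs["pixel_spacing_mm"]),
            )
        if "maps" in f:
            out["maps"] = CoilSensitivities(maps=f["maps"][()],
                                            support=f["maps_support"][()])
        if "meta" in f:
            out["meta"] = dict(f["meta"].attrs)
    return out


def read_ismrmrd(path):
    """Stub reader for the ISMRMRD raw-data standard.

    A full implementation would walk the acquisitions in the file's
    ``dataset/data`` stream and map each header to the container's axes:
    ``idx.phase`` -> frame, ``idx.set`` -> displacement encoding, ``idx.
    repetition`` (or the user-defined counter used by the sequence) -> phase
    cycle, ``active_channels`` -> coil, ``idx.kspace_encode_step_1`` ->
    interleaf, with the trajectory taken from the acquisition's ``traj``
    field in cycles/pixel.  Raw-file support is out of scope here.
    """
    raise NotImplementedError(
        "ISMRMRD raw-data reading is a documented stub; see the docstring for "
        "the intended acquisition-to-axis mapping"
    )
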