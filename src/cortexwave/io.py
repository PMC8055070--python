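"""Reading and writing movies, phase movies, fields, and mode sets.

Two on-disk forms are supported for movies: multi-frame 32-bit float TIFF
(no metadata beyond the frames; the frame rate must be supplied on read)
and an HDF5 container that carries frame_rate, pixel_pitch, and the
generating spec as attributes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import tifffile

from .datatypes import PhaseMovie, PhaseVelocityField, SVDModeSet, VoltageMovie

__all__ = [
    "read_movie", "write_movie",
    "read_phase", "write_phase",
    "read_fields", "write_fields",
    "read_modes", "write_modes",
    "read_region_map", "write_region_map",
]


def write_movie(path, movie: VoltageMovie, spec_text: str = "") -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.data.astype(np.float32))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("movie", data=movie.data)
        f.create_dataset("valid_mask", data=movie.valid_mask)
        f.attrs["frame_rate"] = movie.frame_rate
        f.attrs["pixel_pitch"] = movie.pixel_pitch
        f.attrs["spec"] = spec_text


def read_movie(path, frame_rate: Optional[float] = None) -> VoltageMovie:
    """Load a movie from TIFF or the HDF5 container.

    TIFF files carry no frame rate, so ``frame_rate`` is required for them;
    for HDF5 it overrides the stored attribute when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a (T, H, W) stack, got {data.shape}")
        if frame_rate is None:
            raise ValueError(f"{path}: TIFF carries no frame rate; pass one "
                             "explicitly (--fps)")
        return VoltageMovie(data=np.asarray(data, dtype=float), frame_rate=frame_rate)
    with h5py.File(path, "r") as f:
        data = f["movie"][...]
        fr = frame_rate if frame_rate is not None else f.attrs.get("frame_rate")
        if fr is None:
            raise ValueError(f"{path}: missing frame_rate attribute")
        movie = VoltageMovie(data=data, frame_rate=float(fr),
                             pixel_pitch=float(f.attrs.get("pixel_pitch", 29.0)))
        if "valid_mask" in f:
            movie.valid_mask = f["valid_mask"][...].astype(bool)
    return movie


def write_phase(path, phase: PhaseMovie) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=phase.phase)
        f.create_dataset("amplitude", data=phase.amplitude)
        f.create_dataset("valid_mask", data=phase.valid_mask)
        f.attrs["frame_rate"] = phase.frame_rate


def read_phase(path) -> PhaseMovie:
    with h5py.File(path, "r") as f:
        return PhaseMovie(phase=f["phase"][...], amplitude=f["amplitude"][...],
                          frame_rate=float(f.attrs["frame_rate"]),
                          valid_mask=f["valid_mask"][...].astype(bool))


def write_fields(path, fields: Sequence[PhaseVelocityField]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("v", data=np.stack([fld.v for fld in fields]))
        f.create_dataset("reliability",
                         data=np.stack([fld.reliability for fld in fields]))
        f.create_dataset("t", data=np.array([fld.t for fld in fields]))
        f.create_dataset("converged",
                         data=np.array([fld.converged for fld in fields]))


def read_fields(path):
    with h5py.File(path, "r") as f:
        v = f["v"][...]
        rel = f["reliability"][...].astype(bool)
        ts = f["t"][...]
        conv = f["converged"][...].astype(bool)
    return [PhaseVelocityField(v=v[i], t=int(ts[i]), reliability=rel[i],
                               converged=bool(conv[i])) for i in range(len(ts))]


def write_modes(path, modeset: SVDModeSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("modes", data=modeset.modes)
        f.create_dataset("sigma", data=modeset.singular_values)
        f.create_dataset("variance_fractions", data=modeset.variance_fractions)
        f.create_dataset("projections", data=modeset.projections)
        f.attrs["shape"] = modeset.shape


def read_modes(path) -> SVDModeSet:
    with h5py.File(path, "r") as f:
        return SVDModeSet(modes=f["modes"][...],
                          singular_values=f["sigma"][...],
                          variance_fractions=f["variance_fractions"][...],
                          projections=f["projections"][...],
                          shape=tuple(int(x) for x in f.attrs["shape"]))


def write_region_map(path, region_map: np.ndarray) -> None:
    """Region label image as a plain-text integer grid."""
    np.savetxt(path, np.asarray(region_map, dtype=int), fmt="%d")


def read_region_map(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)
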