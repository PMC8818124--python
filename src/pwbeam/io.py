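"""HDF5 and YAML I/O for acquisitions, images, and ROI specifications.

Container layout (one acquisition per HDF5 file):

* datasets ``channel_data_real`` and, for IQ data only, ``channel_data_imag``
  with shape (n_angles, n_elements, n_samples);
* datasets ``angles`` (radians), ``element_positions`` (m), ``time_zero`` (s);
* scalar root attributes ``fc``, ``fs``, ``fdemod``, ``c0`` (SI units) and
  ``description``.

ROI files are declarative YAML in physical coordinates, never pixel
indices, so they bind to any grid.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import yaml

from .core import (
    BeamformedImage,
    FormatError,
    PixelGrid,
    PlaneWaveAcquisition,
    ROISpec,
)

__all__ = [
    "read_acquisition",
    "write_acquisition",
    "read_image",
    "write_image",
    "load_rois",
    "save_rois",
    "validate_file",
]

_REQUIRED_DATASETS = ("channel_data_real", "angles", "element_positions", "time_zero")
_REQUIRED_ATTRS = ("fc", "fs", "fdemod", "c0")


def write_acquisition(acq: PlaneWaveAcquisition, path: str | os.PathLike) -> None:
    """Write an acquisition to an HDF5 container readable by `read_acquisition`."""
    acq.validate()
    with h5py.File(path, "w") as f:
        if np.iscomplexobj(acq.channel_data):
            f.create_dataset("channel_data_real", data=acq.channel_data.real)
            f.create_dataset("channel_data_imag", data=acq.channel_data.imag)
        else:
            f.create_dataset("channel_data_real", data=acq.channel_data)
        f.create_dataset("angles", data=acq.angles_rad)
        f.create_dataset("element_positions", data=acq.element_x_m)
        f.create_dataset("time_zero", data=acq.time_zero_s)
        f.attrs["fc"] = float(acq.fc_hz)
        f.attrs["fs"] = float(acq.fs_hz)
        f.attrs["fdemod"] = float(acq.fdemod_hz)
        f.attrs["c0"] = float(acq.c_mps)
        f.attrs["description"] = acq.description


def read_acquisition(path: str | os.PathLike) -> PlaneWaveAcquisition:
    """Read and validate an acquisition from an HDF5 container.

    Raises ``FormatError`` naming the missing dataset or attribute if the
    file does not follow the container layout, and ``ValidationError`` if
    the stored values violate an acquisition invariant.
    """
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"{path}: missing required dataset '{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"{path}: missing required attribute '{name}'")
        real = f["channel_data_real"][...]
        if "channel_data_imag" in f:
            data = real + 1j * f["channel_data_imag"][...]
        else:
            data = real
        return PlaneWaveAcquisition(
            channel_data=data,
            angles_rad=f["angles"][...],
            element_x_m=f["element_positions"][...],
            time_zero_s=f["time_zero"][...],
            fc_hz=float(f.attrs["fc"]),
            fs_hz=float(f.attrs["fs"]),
            fdemod_hz=float(f.attrs["fdemod"]),
            c_mps=float(f.attrs["c0"]),
            description=str(f.attrs.get("description", "")),
        )


def write_image(img: BeamformedImage, path: str | os.PathLike) -> None:
    """Write a beamformed image with its grid and provenance attributes."""
    with h5py.File(path, "w") as f:
        if np.iscomplexobj(img.pixels):
            f.create_dataset("pixels_real", data=img.pixels.real)
            f.create_dataset("pixels_imag", data=img.pixels.imag)
        else:
            f.create_dataset("pixels_real", data=img.pixels)
        f.create_dataset("grid_x", data=img.grid.x_m)
        f.create_dataset("grid_z", data=img.grid.z_m)
        f.attrs["stage"] = img.stage
        f.attrs["provenance"] = yaml.safe_dump(_plain(img.provenance))


def read_image(path: str | os.PathLike) -> BeamformedImage:
    with h5py.File(path, "r") as f:
        for name in ("pixels_real", "grid_x", "grid_z"):
            if name not in f:
                raise FormatError(f"{path}: missing required dataset '{name}'")
        pixels = f["pixels_real"][...]
        if "pixels_imag" in f:
            pixels = pixels + 1j * f["pixels_imag"][...]
        grid = PixelGrid(x_m=f["grid_x"][...], z_m=f["grid_z"][...])
        provenance = yaml.safe_load(f.attrs.get("provenance", "{}")) or {}
        return BeamformedImage(
            pixels=pixels, grid=grid, stage=str(f.attrs["stage"]),
            provenance=provenance,
        )


def load_rois(path: str | os.PathLike) -> dict[str, ROISpec]:
    """Load a named set of ROIs from a YAML file.

    The file maps ROI names to mappings accepted by ``ROISpec.from_dict``::

        lesion:    {shape: circle, role: target, center_x: 0.0,
                    center_z: 0.02, radius: 0.003}
        backgnd:   {shape: rectangle, role: background, x_min: -0.008, ...}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise FormatError(f"{path}: expected a non-empty mapping of named ROIs")
    return {name: ROISpec.from_dict(d) for name, d in raw.items()}


def save_rois(rois: dict[str, ROISpec], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({name: r.to_dict() for name, r in rois.items()}, fh)


def validate_file(path: str | os.PathLike) -> PlaneWaveAcquisition:
    """Read a container, run all invariant checks, and return the result."""
    acq = read_acquisition(path)
    acq.validate()
    return acq


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
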