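"""Delay-and-sum plane-wave beamforming with coherent angular compounding.

The delay law is the conventional coherent-plane-wave-compounding geometry
for a linear array: a steered plane wave reaches pixel (x, z) at

    tau_tx = (z*cos(theta) + x*sin(theta)) / c

after crossing the array origin, and the echo returns to element xe after

    tau_rx = sqrt((x - xe)**2 + z**2) / c.

Each element trace is sampled at (tau_tx + tau_rx - time_zero) * fs by
linear interpolation and summed across the aperture; compounding sums the
complex single-angle images before envelope detection, which is what
recovers focusing quality from unfocused transmissions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import das_single_angle
from .core import BeamformedImage, PixelGrid, PlaneWaveAcquisition, ValidationError

__all__ = [
    "transmit_delay",
    "receive_delay",
    "DelayLaw",
    "beamform_single",
    "beamform_compound",
    "envelope",
    "log_compress",
]


def transmit_delay(
    grid: PixelGrid, angle_rad: float, c_mps: float
) -> np.ndarray:
    """Plane-wave transmit time of flight to every pixel, seconds.

    tau_tx(x, z) = (z*cos(theta) + x*sin(theta)) / c, measured from the
    instant the wavefront crosses the array origin.  May be slightly
    negative for steered waves at shallow lateral extremes.
    """
    if c_mps <= 0:
        raise ValidationError(f"sound speed must be positive, got {c_mps}")
    if abs(angle_rad) >= np.pi / 2:
        raise ValidationError("|angle| must be < pi/2")
    xx, zz = grid.meshgrid()
    return (zz * np.cos(angle_rad) + xx * np.sin(angle_rad)) / c_mps


def receive_delay(
    grid: PixelGrid, element_x_m: np.ndarray, c_mps: float
) -> np.ndarray:
    """Receive time of flight from every pixel to every element, seconds.

    Returns shape ``grid.shape + (n_elements,)`` with
    tau_rx(x, z, xe) = sqrt((x - xe)**2 + z**2) / c.
    """
    if c_mps <= 0:
        raise ValidationError(f"sound speed must be positive, got {c_mps}")
    element_x_m = np.atleast_1d(np.asarray(element_x_m, dtype=float))
    xx, zz = grid.meshgrid()
    dx = xx[..., None] - element_x_m
    return np.sqrt(dx**2 + zz[..., None] ** 2) / c_mps


@dataclass
class DelayLaw:
    """Per-pixel transmit and per-pixel-per-element receive delays."""

    tx_delay_s: np.ndarray
    rx_delay_s: np.ndarray

    @classmethod
    def compute(
        cls, grid: PixelGrid, angle_rad: float, element_x_m: np.ndarray,
        c_mps: float,
    ) -> "DelayLaw":
        return cls(
            tx_delay_s=transmit_delay(grid, angle_rad, c_mps),
            rx_delay_s=receive_delay(grid, element_x_m, c_mps),
        )


def beamform_single(
    acq: PlaneWaveAcquisition,
    grid: PixelGrid,
    angle_index: int,
    c_mps: float | None = None,
    f_number: float = 0.0,
) -> BeamformedImage:
    """Beamform one steered transmission onto the grid.

    Parameters
    ----------
    c_mps
        Sound speed for the focusing delays; defaults to the acquisition's
        nominal speed.
    f_number
        Receive f-number for aperture growth (elements with
        ``|x - xe| > z / (2 f#)`` are excluded).  0 keeps the full
        aperture with rectangular apodization, the plain-summation
        baseline.
    """
    if not 0 <= angle_index < acq.n_angles:
        raise IndexError(
            f"angle_index {angle_index} out of range for {acq.n_angles} angles"
        )
    # checked once per acquisition object; repeated beamforms skip the scan
    if not getattr(acq, "_finite_checked", False):
        if np.any(~np.isfinite(acq.channel_data)):
            raise ValidationError("channel data contain NaN or infinite samples")
        acq._finite_checked = True
    c = acq.c_mps if c_mps is None else float(c_mps)
    if c <= 0:
        raise ValidationError(f"sound speed must be positive, got {c}")

    baseband, fdemod = acq.baseband_channel_data()
    traces = np.ascontiguousarray(baseband[angle_index])
    xx, zz = grid.meshgrid()
    tau_tx = transmit_delay(grid, float(acq.angles_rad[angle_index]), c)
    flat = das_single_angle(
        traces,
        np.ascontiguousarray(acq.element_x_m),
        np.ascontiguousarray(xx.ravel()),
        np.ascontiguousarray(zz.ravel()),
        np.ascontiguousarray(tau_tx.ravel()),
        c,
        float(acq.fs_hz),
        float(fdemod),
        float(acq.time_zero_s[angle_index]),
        float(f_number),
    )
    return BeamformedImage(
        pixels=flat.reshape(grid.shape),
        grid=grid,
        stage="complex",
        provenance={"angles": [int(angle_index)], "c_mps": c,
                    "f_number": f_number},
    )


def beamform_compound(
    acq: PlaneWaveAcquisition,
    grid: PixelGrid,
    angle_indices: Sequence[int] | None = None,
    c_mps: float | None = None,
    f_number: float = 0.0,
) -> BeamformedImage:
    """Coherently compound several steered transmissions.

    The single-angle complex images are summed before envelope detection;
    ``angle_indices=None`` uses every available angle.
    """
    if angle_indices is None:
        angle_indices = range(acq.n_angles)
    angle_indices = list(angle_indices)
    if not angle_indices:
        raise ValidationError("angle_indices must be non-empty")
    total = None
    for idx in angle_indices:
        img = beamform_single(acq, grid, idx, c_mps=c_mps, f_number=f_number)
        total = img.pixels if total is None else total + img.pixels
    return BeamformedImage(
        pixels=total,
        grid=grid,
        stage="complex",
        provenance={
            "angles": [int(i) for i in angle_indices],
            "c_mps": acq.c_mps if c_mps is None else float(c_mps),
            "f_number": f_number,
        },
    )


def envelope(img: BeamformedImage) -> BeamformedImage:
    """Per-pixel magnitude of a complex beamformed image.

    RF acquisitions are beamformed from their analytic signal, so the
    magnitude here is the detected envelope in both the RF and IQ paths.
    """
    if img.stage != "complex":
        raise ValidationError(f"envelope expects a complex image, got {img.stage}")
    return BeamformedImage(
        pixels=np.abs(img.pixels),
        grid=img.grid,
        stage="envelope",
        provenance=dict(img.provenance),
    )


def log_compress(img: BeamformedImage, dynamic_range_db: float = 60.0) -> BeamformedImage:
    """Log-compress an envelope image to dB below its own maximum.

    Values are 20*log10(env / max(env)), so the maximum is exactly 0 dB.
    ``dynamic_range_db`` is recorded for display clipping; the stored
    pixel values themselves are not clipped.
    """
    if img.stage != "envelope":
        raise ValidationError(f"log_compress expects an envelope image, got {img.stage}")
    peak = float(np.max(img.pixels))
    if peak <= 0:
        raise ValidationError("cannot log-compress an all-zero image")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(img.pixels / peak)
    prov = dict(img.provenance)
    prov["dynamic_range_db"] = float(dynamic_range_db)
    return BeamformedImage(pixels=db, grid=img.grid, stage="log_db", provenance=prov)
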