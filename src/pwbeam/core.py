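"""Core data model for plane-wave ultrasound acquisitions and images.

All physical quantities are SI internally: positions in meters, times in
seconds, frequencies in Hz, sound speeds in m/s.  The lateral axis ``x`` is
centered on the array; depth ``z`` is positive away from the transducer
face.  Images are stored depth-major: row index is depth, column index is
lateral position, matching conventional B-mode display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PlaneWaveAcquisition",
    "PixelGrid",
    "ROISpec",
    "BeamformedImage",
    "bind_roi",
]


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class FormatError(ValueError):
    """A file or mapping does not conform to the expected container layout."""


@dataclass
class PlaneWaveAcquisition:
    """Raw multi-angle plane-wave channel data plus acquisition metadata.

    Parameters
    ----------
    channel_data : ndarray, shape (n_angles, n_elements, n_samples)
        Per-transmission, per-element receive traces.  Real-valued for RF
        data (``fdemod_hz == 0``), complex for demodulated IQ data.
    angles_rad : ndarray, shape (n_angles,)
        Steering angle of each plane-wave transmission, radians.
    element_x_m : ndarray, shape (n_elements,)
        Lateral positions of the (linear) array elements, meters,
        centered on x = 0.
    fc_hz, fs_hz : float
        Center and sampling frequency, Hz.
    fdemod_hz : float
        Demodulation frequency, Hz.  Zero for RF data.
    c_mps : float
        Nominal sound speed assumed at acquisition time, m/s.
    time_zero_s : ndarray, shape (n_angles,)
        Per-angle time of sample index 0, relative to the instant the
        steered wavefront crosses the array origin (x = 0, z = 0).
    description : str
        Free-form provenance string.
    """

    channel_data: np.ndarray
    angles_rad: np.ndarray
    element_x_m: np.ndarray
    fc_hz: float
    fs_hz: float
    fdemod_hz: float
    c_mps: float
    time_zero_s: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.channel_data = np.asarray(self.channel_data)
        self.angles_rad = np.atleast_1d(np.asarray(self.angles_rad, dtype=float))
        self.element_x_m = np.atleast_1d(np.asarray(self.element_x_m, dtype=float))
        self.time_zero_s = np.atleast_1d(np.asarray(self.time_zero_s, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.channel_data.ndim != 3:
            raise ValidationError(
                "channel_data must be 3-D (angle, element, sample); "
                f"got shape {self.channel_data.shape}"
            )
        n_angles, n_elements, _ = self.channel_data.shape
        if len(self.angles_rad) != n_angles:
            raise ValidationError(
                f"angles_rad has length {len(self.angles_rad)}, "
                f"channel_data has {n_angles} angles"
            )
        if len(self.element_x_m) != n_elements:
            raise ValidationError(
                f"element_x_m has length {len(self.element_x_m)}, "
                f"channel_data has {n_elements} elements"
            )
        if len(self.time_zero_s) != n_angles:
            raise ValidationError(
                f"time_zero_s has length {len(self.time_zero_s)}, expected {n_angles}"
            )
        if not self.fs_hz > 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if not self.fc_hz > 0:
            raise ValidationError(f"fc_hz must be positive, got {self.fc_hz}")
        if self.fdemod_hz < 0:
            raise ValidationError(f"fdemod_hz must be >= 0, got {self.fdemod_hz}")
        if np.any(np.abs(self.angles_rad) >= np.pi / 2):
            raise ValidationError("all steering angles must satisfy |angle| < pi/2")
        if not 1000.0 <= self.c_mps <= 2000.0:
            raise ValidationError(
                f"c_mps must lie in [1000, 2000] m/s, got {self.c_mps}"
            )
        if np.iscomplexobj(self.channel_data) and self.fdemod_hz == 0:
            raise ValidationError("RF data (fdemod_hz == 0) must be real-valued")

    @property
    def n_angles(self) -> int:
        return self.channel_data.shape[0]

    @property
    def n_elements(self) -> int:
        return self.channel_data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.channel_data.shape[2]

    @property
    def is_rf(self) -> bool:
        return self.fdemod_hz == 0

    @property
    def wavelength_m(self) -> float:
        """Wavelength at the nominal sound speed and center frequency."""
        return self.c_mps / self.fc_hz

    def analytic_channel_data(self) -> np.ndarray:
        """Complex traces suitable for baseband delay-and-sum.

        For RF data this is the analytic signal along the sample axis, so
        that the magnitude of the beamformed output is the envelope.  IQ
        data are already complex and are returned as-is.  The result is
        cached: it does not depend on any beamforming parameter.
        """
        cached = getattr(self, "_analytic_cache", None)
        if cached is None:
            if self.is_rf:
                cached = hilbert(self.channel_data.astype(np.float64), axis=-1)
            else:
                cached = np.ascontiguousarray(
                    self.channel_data.astype(np.complex128)
                )
            self._analytic_cache = cached
        return cached

    def baseband_channel_data(self) -> tuple[np.ndarray, float]:
        """Complex baseband traces and the demodulation frequency used.

        IQ data are already baseband.  RF data are mixed down at the
        center frequency after the analytic transform: the interpolation
        inside delay-and-sum then acts on a slowly varying signal instead
        of the carrier, which avoids the amplitude loss of linearly
        interpolating an oscillation sampled near Nyquist.  The result is
        cached.
        """
        cached = getattr(self, "_baseband_cache", None)
        if cached is None:
            if self.is_rf:
                t = np.arange(self.n_samples) / self.fs_hz
                t_abs = t + self.time_zero_s[:, None, None]
                cached = (
                    self.analytic_channel_data()
                    * np.exp(-2j * np.pi * self.fc_hz * t_abs)
                ).astype(np.complex64)
            else:
                cached = self.analytic_channel_data().astype(np.complex64)
            self._baseband_cache = cached
        return cached, (self.fc_hz if self.is_rf else self.fdemod_hz)


@dataclass
class PixelGrid:
    """Physical imaging grid: strictly increasing lateral and depth axes."""

    x_m: np.ndarray
    z_m: np.ndarray

    def __post_init__(self) -> None:
        self.x_m = np.atleast_1d(np.asarray(self.x_m, dtype=float))
        self.z_m = np.atleast_1d(np.asarray(self.z_m, dtype=float))
        if self.x_m.size == 0 or self.z_m.size == 0:
            raise ValidationError("grid axes must be non-empty")
        for name, ax in (("x_m", self.x_m), ("z_m", self.z_m)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if np.any(self.z_m < 0):
            raise ValidationError("z_m must be >= 0 (depth below the array)")

    @property
    def shape(self) -> tuple[int, int]:
        """(n_depth, n_lateral) — depth-major image shape."""
        return (self.z_m.size, self.x_m.size)

    @property
    def dx(self) -> float:
        return float(self.x_m[1] - self.x_m[0]) if self.x_m.size > 1 else 0.0

    @property
    def dz(self) -> float:
        return float(self.z_m[1] - self.z_m[0]) if self.z_m.size > 1 else 0.0

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates as 2-D arrays of shape ``self.shape``."""
        xx, zz = np.meshgrid(self.x_m, self.z_m)
        return xx, zz

    @classmethod
    def regular(
        cls, x_min: float, x_max: float, z_min: float, z_max: float, spacing_m: float
    ) -> "PixelGrid":
        """Uniform grid with the given spacing covering the given extent."""
        if spacing_m <= 0:
            raise ValidationError("spacing must be positive")
        return cls(
            x_m=np.arange(x_min, x_max + spacing_m / 2, spacing_m),
            z_m=np.arange(z_min, z_max + spacing_m / 2, spacing_m),
        )

    @classmethod
    def default_for(
        cls,
        acq: PlaneWaveAcquisition,
        z_min: float = 1e-3,
        z_max: float | None = None,
        c_mps: float | None = None,
    ) -> "PixelGrid":
        """Isotropic grid at one-third wavelength spacing over the aperture.

        Depth extent defaults to the round-trip range implied by the record
        length at the nominal sound speed.
        """
        c = acq.c_mps if c_mps is None else c_mps
        spacing = (c / acq.fc_hz) / 3.0
        if z_max is None:
            z_max = c * (acq.n_samples / acq.fs_hz + float(np.min(acq.time_zero_s))) / 2
        return cls.regular(
            float(acq.element_x_m.min()),
            float(acq.element_x_m.max()),
            z_min,
            z_max,
            spacing,
        )


_ROLES = ("target", "background", "speckle", "point")


@dataclass
class ROISpec:
    """Region of interest in physical coordinates.

    ``shape`` is ``"rectangle"`` (``x_min/x_max/z_min/z_max``) or
    ``"circle"`` (``center_x/center_z/radius``); ``role`` declares how the
    region is used by the metrics (``target``, ``background``, ``speckle``
    or ``point``).
    """

    shape: Literal["rectangle", "circle"]
    role: str = "target"
    x_min: float | None = None
    x_max: float | None = None
    z_min: float | None = None
    z_max: float | None = None
    center_x: float | None = None
    center_z: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.shape == "rectangle":
            vals = (self.x_min, self.x_max, self.z_min, self.z_max)
            if any(v is None for v in vals):
                raise ValidationError("rectangle ROI needs x_min/x_max/z_min/z_max")
            if not (self.x_max > self.x_min and self.z_max > self.z_min):
                raise ValidationError("rectangle ROI extents must be positive")
        elif self.shape == "circle":
            vals = (self.center_x, self.center_z, self.radius)
            if any(v is None for v in vals):
                raise ValidationError("circle ROI needs center_x/center_z/radius")
            if not self.radius > 0:
                raise ValidationError("circle ROI radius must be positive")
        else:
            raise ValidationError(f"unknown ROI shape {self.shape!r}")

    @classmethod
    def rectangle(
        cls, x_min: float, x_max: float, z_min: float, z_max: float,
        role: str = "target",
    ) -> "ROISpec":
        return cls(shape="rectangle", role=role,
                   x_min=x_min, x_max=x_max, z_min=z_min, z_max=z_max)

    @classmethod
    def circle(
        cls, center_x: float, center_z: float, radius: float, role: str = "target"
    ) -> "ROISpec":
        return cls(shape="circle", role=role,
                   center_x=center_x, center_z=center_z, radius=radius)

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boolean membership of points (x, z), broadcasting as numpy does."""
        if self.shape == "rectangle":
            return (
                (x >= self.x_min) & (x <= self.x_max)
                & (z >= self.z_min) & (z <= self.z_max)
            )
        return (x - self.center_x) ** 2 + (z - self.center_z) ** 2 <= self.radius**2

    def to_dict(self) -> dict:
        d = {"shape": self.shape, "role": self.role}
        if self.shape == "rectangle":
            d.update(x_min=self.x_min, x_max=self.x_max,
                     z_min=self.z_min, z_max=self.z_max)
        else:
            d.update(center_x=self.center_x, center_z=self.center_z,
                     radius=self.radius)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        try:
            shape = d["shape"]
        except KeyError as exc:
            raise FormatError("ROI mapping lacks required key 'shape'") from exc
        known = {"shape", "role", "x_min", "x_max", "z_min", "z_max",
                 "center_x", "center_z", "radius"}
        kwargs = {k: v for k, v in d.items() if k in known and k != "shape"}
        return cls(shape=shape, **kwargs)


def bind_roi(roi: ROISpec, grid: PixelGrid) -> np.ndarray:
    """Rasterize an ROI onto a grid as a boolean pixel mask.

    A pixel belongs to the ROI when its center lies inside the region.
    Raises ``ValidationError`` if no pixel center falls inside the ROI, so
    that metrics can never silently average over an empty region.
    """
    xx, zz = grid.meshgrid()
    mask = roi.contains(xx, zz)
    if not mask.any():
        raise ValidationError(
            f"ROI ({roi.shape}, role={roi.role}) selects no pixel on the grid"
        )
    return mask


_STAGES = ("complex", "envelope", "log_db")


@dataclass
class BeamformedImage:
    """Pixel values on a :class:`PixelGrid` at a known processing stage.

    ``stage`` is one of ``complex`` (raw beamsum), ``envelope``
    (non-negative magnitude), or ``log_db`` (dB relative to the image
    maximum, peak exactly 0 dB).  ``provenance`` records the angles and
    sound speed used to form the image.
    """

    pixels: np.ndarray
    grid: PixelGrid
    stage: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.stage not in _STAGES:
            raise ValidationError(f"stage must be one of {_STAGES}")
        if self.pixels.shape != self.grid.shape:
            raise ValidationError(
                f"pixels shape {self.pixels.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if self.stage == "envelope" and np.any(self.pixels < 0):
            raise ValidationError("envelope stage must be non-negative")
        if self.stage == "log_db" and not np.isclose(np.max(self.pixels), 0.0):
            raise ValidationError("log_db stage must have maximum 0 dB")

    def values_in(self, roi: ROISpec) -> np.ndarray:
        """Pixel values inside an ROI (flattened)."""
        return self.pixels[bind_roi(roi, self.grid)]
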