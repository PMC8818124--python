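"""Compiled inner loops for delay-and-sum and the single-scattering simulator.

These kernels are deliberately free of any domain object: they take flat
float arrays and scalars so they can be compiled once and reused across
angles and sound-speed evaluations.  Everything above them (delay laws,
apodization policy, pulse definition) lives in the plain-Python modules.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


# one-cycle complex-exponential table for the demodulation phase rotation;
# 4096 bins with linear interpolation keep the phase error below 1e-6 rad
_PHASE_BINS = 4096
_phase_angles = 2.0 * np.pi * np.arange(_PHASE_BINS + 1) / _PHASE_BINS
_COS_LUT = np.cos(_phase_angles)
_SIN_LUT = np.sin(_phase_angles)


@njit(cache=True, fastmath=True)
def das_single_angle(
    traces: np.ndarray,      # complex128 (n_elements, n_samples)
    element_x: np.ndarray,   # float64 (n_elements,)
    pixel_x: np.ndarray,     # float64 (n_pixels,)
    pixel_z: np.ndarray,     # float64 (n_pixels,)
    tau_tx: np.ndarray,      # float64 (n_pixels,) transmit time of flight
    c: float,
    fs: float,
    fdemod: float,
    time_zero: float,
    f_number: float,         # 0 disables receive aperture growth
    cos_lut: np.ndarray = _COS_LUT,
    sin_lut: np.ndarray = _SIN_LUT,
) -> np.ndarray:
    """Delay-and-sum one steered transmission onto a flat pixel list.

    Per pixel and element the total delay is tau_tx + receive time of
    flight - time_zero; the element trace is sampled there by linear
    interpolation (out-of-range contributions are zero).  Demodulated data
    are phase-rotated by exp(+2j*pi*fdemod*tau) to restore the carrier
    phase at the pixel; the rotation comes from the one-cycle lookup
    table, which keeps transcendentals out of the inner loop.
    """
    n_elements, n_samples = traces.shape
    n_pixels = pixel_x.size
    out = np.zeros(n_pixels, dtype=np.complex128)
    n_bins = cos_lut.size - 1
    for p in range(n_pixels):
        x = pixel_x[p]
        z = pixel_z[p]
        t_tx = tau_tx[p]
        half_aperture = z / (2.0 * f_number) if f_number > 0.0 else 0.0
        acc = 0.0 + 0.0j
        for e in range(n_elements):
            dx = x - element_x[e]
            if f_number > 0.0 and abs(dx) > half_aperture:
                continue
            tau = t_tx + math.sqrt(dx * dx + z * z) / c - time_zero
            s = tau * fs
            i0 = int(math.floor(s))
            if i0 < 0 or i0 >= n_samples - 1:
                continue
            w = s - i0
            val = traces[e, i0] * (1.0 - w) + traces[e, i0 + 1] * w
            if fdemod > 0.0:
                cycles = fdemod * tau
                frac = (cycles - math.floor(cycles)) * n_bins
                j = int(frac)
                fw = frac - j
                cr = cos_lut[j] * (1.0 - fw) + cos_lut[j + 1] * fw
                ci = sin_lut[j] * (1.0 - fw) + sin_lut[j + 1] * fw
                val *= complex(cr, ci)
            acc += val
        out[p] = acc
    return out


@njit(cache=True, fastmath=True)
def scatter_traces(
    scat_x: np.ndarray,     # float64 (n_scatterers,)
    scat_z: np.ndarray,
    amplitude: np.ndarray,
    element_x: np.ndarray,  # float64 (n_elements,)
    sin_theta: float,
    cos_theta: float,
    c: float,
    fs: float,
    pulse_lut: np.ndarray,  # pulse sampled on [-t_half, +t_half]
    t_half: float,          # pulse support half-width, seconds
    time_zero: float,
    n_samples: int,
) -> np.ndarray:
    """Synthesize RF element traces for one plane-wave transmission.

    Linear single-scattering model: each scatterer contributes the pulse
    waveform centered at its round-trip arrival time, scaled by its
    reflectivity.  The pulse is supplied as a densely sampled lookup
    table over its finite support and evaluated by linear interpolation,
    which keeps the inner loop free of transcendentals.
    """
    n_scat = scat_x.size
    n_elements = element_x.size
    n_lut = pulse_lut.size
    traces = np.zeros((n_elements, n_samples))
    lut_scale = (n_lut - 1) / (2.0 * t_half)
    window_half = int(math.ceil(t_half * fs)) + 1
    for e in range(n_elements):
        xe = element_x[e]
        for s in range(n_scat):
            dx = scat_x[s] - xe
            tau_tx = (scat_z[s] * cos_theta + scat_x[s] * sin_theta) / c
            tau = tau_tx + math.sqrt(dx * dx + scat_z[s] * scat_z[s]) / c - time_zero
            center = tau * fs
            i_lo = int(math.floor(center)) - window_half
            i_hi = i_lo + 2 * window_half
            if i_hi < 0 or i_lo >= n_samples:
                continue
            if i_lo < 0:
                i_lo = 0
            if i_hi > n_samples:
                i_hi = n_samples
            a = amplitude[s]
            for i in range(i_lo, i_hi):
                u = (i / fs - tau + t_half) * lut_scale
                j = int(math.floor(u))
                if j < 0 or j >= n_lut - 1:
                    continue
                w = u - j
                traces[e, i] += a * (
                    pulse_lut[j] * (1.0 - w) + pulse_lut[j + 1] * w
                )
    return traces
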