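"""Global sound-speed estimation by speckle-brightness maximization.

When channel data are beamformed with the wrong sound speed, the focusing
delays are mismatched and the coherent sum over the aperture loses
amplitude.  Over a homogeneous region of fully developed speckle the mean
envelope brightness is therefore maximized at the true propagation speed,
which makes it a simple, widely accepted focusing criterion.  The
estimator runs adaptive-moment (Adam) gradient ascent on that objective
with a decaying step size; a brute-force grid search over a sound-speed
lattice serves as the verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamform import beamform_compound
from .core import PixelGrid, PlaneWaveAcquisition, ValidationError

__all__ = [
    "SoundSpeedResult",
    "speckle_brightness",
    "estimate_sound_speed",
    "grid_search_sound_speed",
]

C_MIN = 1000.0
C_MAX = 2000.0


@dataclass
class SoundSpeedResult:
    """Estimate plus the full optimization trajectory.

    ``trajectory`` holds (sound speed, brightness) per iteration, starting
    with the initial point, so it has ``steps + 1`` entries; ``c_hat_mps``
    is the speed with the highest recorded brightness, not necessarily the
    last iterate.
    """

    c_hat_mps: float
    trajectory: list[tuple[float, float]]
    objective_final: float


def speckle_brightness(
    acq: PlaneWaveAcquisition,
    speckle_grid: PixelGrid,
    c_mps: float,
    angle_indices: list[int] | None = None,
) -> float:
    """Mean compounded envelope over a homogeneous speckle region.

    All available angles are compounded by default.  The caller is
    responsible for placing ``speckle_grid`` in homogeneous speckle; the
    objective is meaningless over structured targets.
    """
    if not C_MIN <= c_mps <= C_MAX:
        raise ValidationError(
            f"sound speed {c_mps} outside the physical range "
            f"[{C_MIN}, {C_MAX}] m/s"
        )
    img = beamform_compound(acq, speckle_grid, angle_indices, c_mps=c_mps)
    return float(np.mean(np.abs(img.pixels)))


def estimate_sound_speed(
    acq: PlaneWaveAcquisition,
    speckle_grid: PixelGrid,
    c_init_mps: float | None = None,
    steps: int = 30,
    step_size_mps: float = 10.0,
    decay: float = 0.9,
    fd_delta_mps: float = 0.5,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    angle_indices: list[int] | None = None,
) -> SoundSpeedResult:
    """Maximize speckle brightness over the global sound speed.

    Adaptive-moment gradient ascent with an exponentially decaying step
    size (``step_size_mps * decay**k`` at iteration k) and a gradient from
    central finite differences of half-meter-per-second spacing.  Because
    the moment ratio normalizes the gradient scale, each update moves by
    roughly the current step size in the uphill direction, and the result
    is invariant to positive rescaling of the channel data.

    Returns the best speed observed along the trajectory.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    c = float(acq.c_mps if c_init_mps is None else c_init_mps)
    trajectory: list[tuple[float, float]] = []

    def objective(cc: float) -> float:
        val = speckle_brightness(acq, speckle_grid, cc, angle_indices)
        if not np.isfinite(val):
            raise ValidationError(
                f"non-finite speckle brightness at c={cc}; trajectory so far: "
                f"{trajectory}"
            )
        return val

    trajectory.append((c, objective(c)))
    m = 0.0
    v = 0.0
    for k in range(1, steps + 1):
        g = (
            objective(min(c + fd_delta_mps, C_MAX))
            - objective(max(c - fd_delta_mps, C_MIN))
        ) / (2.0 * fd_delta_mps)
        m = beta1 * m + (1.0 - beta1) * g
        v = beta2 * v + (1.0 - beta2) * g * g
        m_hat = m / (1.0 - beta1**k)
        v_hat = v / (1.0 - beta2**k)
        lr = step_size_mps * decay ** (k - 1)
        c = c + lr * m_hat / (np.sqrt(v_hat) + eps)
        c = float(np.clip(c, C_MIN, C_MAX))
        trajectory.append((c, objective(c)))

    best = max(trajectory, key=lambda cb: cb[1])
    return SoundSpeedResult(
        c_hat_mps=best[0], trajectory=trajectory, objective_final=best[1]
    )


def grid_search_sound_speed(
    acq: PlaneWaveAcquisition,
    speckle_grid: PixelGrid,
    c_min_mps: float,
    c_max_mps: float,
    step_mps: float,
    angle_indices: list[int] | None = None,
) -> float:
    """Brute-force argmax of speckle brightness over a sound-speed lattice.

    Ties break toward the lowest speed.  This is the oracle the iterative
    estimator is verified against.
    """
    if not c_min_mps < c_max_mps:
        raise ValidationError("need c_min < c_max")
    if step_mps <= 0:
        raise ValidationError("step must be positive")
    lattice = np.arange(c_min_mps, c_max_mps + step_mps / 2, step_mps)
    if lattice.size == 0:
        raise ValidationError("empty sound-speed lattice")
    brightness = [
        speckle_brightness(acq, speckle_grid, float(c), angle_indices)
        for c in lattice
    ]
    return float(lattice[int(np.argmax(brightness))])
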