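"""Shared fixtures: small rigs for unit tests, full-scale phantoms for the
end-to-end checks.  Everything is generated at test time from fixed seeds;
the heavy acquisitions are session-scoped so simulation cost is paid once."""

from __future__ import annotations

import numpy as np
import pytest

from pwbeam import (
    PixelGrid,
    ROISpec,
    SimulationConfig,
    make_lesion_phantom,
    make_point_phantom,
    make_speckle_phantom,
    simulate_channel_data,
)

RAYLEIGH_SNR = float(np.sqrt(np.pi / (4 - np.pi)))  # ~1.9131

# sound speeds spanning the range observed across contributed phantom data
SOUND_SPEED_CASES = (1450.0, 1500.0, 1540.0, 1580.0, 1620.0)


def small_config(**overrides) -> SimulationConfig:
    """A deliberately tiny rig for fast unit tests (not the study rig)."""
    defaults = dict(
        n_elements=32,
        angles_rad=np.linspace(np.deg2rad(-16), np.deg2rad(16), 9),
        max_depth_m=0.022,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def point_acq_small(small_cfg):
    """One scatterer at (0, 15 mm) on the small rig."""
    field = make_point_phantom([(0.0, 0.015)])
    return simulate_channel_data(field, small_cfg)


@pytest.fixture(scope="session")
def point_acq_default(default_cfg):
    """Five point targets on the full-scale rig (3 on axis, 2 off axis)."""
    field = make_point_phantom(
        [(0.0, 0.015), (0.0, 0.020), (0.0, 0.025), (-5e-3, 0.020), (5e-3, 0.020)]
    )
    return simulate_channel_data(field, default_cfg)


@pytest.fixture(scope="session")
def point_grid_default(point_acq_default):
    lam = point_acq_default.wavelength_m
    return PixelGrid.regular(-7e-3, 7e-3, 13e-3, 27e-3, lam / 3)


def _speckle_case(c_true: float, seed: int):
    """Speckle acquisition + brightness grid for sound-speed recovery.

    The nominal (assumed) speed is always 1540 m/s regardless of the true
    simulation speed, as on a scanner.  Density is a scaled-down 10 per
    cell: brightness-based estimation does not rely on asymptotic
    Rayleigh statistics.
    """
    cfg = SimulationConfig(c_true_mps=c_true, c_nominal_mps=1540.0)
    region = ROISpec.rectangle(-4e-3, 4e-3, 15.5e-3, 24.5e-3, role="speckle")
    field = make_speckle_phantom(region, scatterers_per_cell=10, seed=seed,
                                 config=cfg)
    acq = simulate_channel_data(field, cfg)
    lam = 1540.0 / cfg.fc_hz
    grid = PixelGrid.regular(-3e-3, 3e-3, 17e-3, 23e-3, lam / 3)
    return acq, grid


@pytest.fixture(scope="session")
def sound_speed_cases():
    """(c_true -> (acquisition, speckle grid)) across the tested range."""
    return {
        c: _speckle_case(c, seed=10 + i)
        for i, c in enumerate(SOUND_SPEED_CASES)
    }


@pytest.fixture(scope="session")
def rayleigh_phantoms(default_cfg):
    """Two full-density speckle acquisitions for envelope-statistics checks."""
    region = ROISpec.rectangle(-4e-3, 4e-3, 16e-3, 24e-3, role="speckle")
    out = []
    for seed in (0, 1):
        field = make_speckle_phantom(region, seed=seed, config=default_cfg)
        out.append(simulate_channel_data(field, default_cfg))
    return out


@pytest.fixture(scope="session")
def speckle_grid_default(default_cfg):
    lam = default_cfg.c_nominal_mps / default_cfg.fc_hz
    return PixelGrid.regular(-3.2e-3, 3.2e-3, 16.8e-3, 23.2e-3, lam / 3)


@pytest.fixture(scope="session")
def lesion_setup(default_cfg):
    """Anechoic 3 mm lesion in speckle, with its grid and metric ROIs."""
    region = ROISpec.rectangle(-6e-3, 6e-3, 14e-3, 26e-3, role="background")
    lesion = ROISpec.circle(0.0, 20e-3, 3e-3, role="target")
    field = make_lesion_phantom(region, lesion, amplitude_ratio=0.0,
                                scatterers_per_cell=10, seed=7,
                                config=default_cfg)
    acq = simulate_channel_data(field, default_cfg)
    lam = default_cfg.c_nominal_mps / default_cfg.fc_hz
    grid = PixelGrid.regular(-5e-3, 5e-3, 15e-3, 25e-3, lam / 3)
    rois = {
        "lesion": ROISpec.circle(0.0, 20e-3, 2.2e-3, role="target"),
        "background": ROISpec.rectangle(3.2e-3, 4.8e-3, 17.5e-3, 22.5e-3,
                                        role="background"),
    }
    return acq, grid, rois
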