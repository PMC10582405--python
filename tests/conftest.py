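"""Shared fixtures: small grids, a desk-scale transducer, point-source helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pavol.acoustics import ScanConfig, TransducerSpec
from pavol.grid import VoxelGrid
from pavol.phantom import VesselPhantom
from pavol.recon import ReconVolume


@pytest.fixture
def small_grid() -> VoxelGrid:
    """6.4 x 12.8 x 3.2 mm grid at 0.1/0.2 mm spacing, 30 mm standoff."""
    return VoxelGrid(shape=(64, 64, 16), spacing_mm=(0.1, 0.2, 0.2), standoff_mm=30.0)


@pytest.fixture
def desk_spec() -> TransducerSpec:
    return TransducerSpec(n_elements=32, pitch_mm=0.4)


@pytest.fixture
def single_frame_scan() -> ScanConfig:
    return ScanConfig(
        step_mm=0.2, n_positions=1, sampling_rate_MHz=20.0, subregion_elevation_mm=3.2
    )


def point_source_phantom(grid: VoxelGrid, zi: int, xi: int, yi: int) -> VesselPhantom:
    a = np.zeros(grid.shape, dtype=np.float32)
    a[zi, xi, yi] = 1.0
    return VesselPhantom(grid=grid, absorption=a)


def random_volume(shape, seed=0, normalized=True) -> ReconVolume:
    rng = np.random.default_rng(seed)
    data = rng.uniform(0.0, 1.0, size=shape).astype(np.float32)
    data[tuple(np.unravel_index(np.argmax(data), shape))] = 1.0
    return ReconVolume(
        data=data, grid=VoxelGrid(shape=shape, spacing_mm=(0.1, 0.1, 0.1)),
        normalized=normalized,
    )
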