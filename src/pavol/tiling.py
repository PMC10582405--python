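"""Cube division and exponential-weighted seam-free fusion.

Volumes are processed by the enhancement network one cube at a time
(128 voxels per side at full scale). Adjacent cubes overlap; when they are
recombined, values inside each overlap are blended with a normalized
nonlinear weighting map

    M(x) = (exp(x / A) - 1) / (e - 1),   1 <= x <= A,

where ``x`` indexes position across the overlap and ``A`` is the overlap
width (32 by default). The incoming cube is weighted by M(x) and the
incumbent by 1 - M(x), a partition of unity, so constants are preserved
exactly and cube seams vanish. Weighting is applied along every axis where
adjacent tiles overlap; corner regions use separable per-axis weights
renormalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .recon import ReconVolume

__all__ = ["CubeTile", "fusion_weight", "split_cubes", "fuse_tiles"]


@dataclass
class CubeTile:
    """A cube_size^3 sub-volume with its origin index in the parent volume."""

    data: np.ndarray
    origin: tuple[int, int, int]
    cube_size: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (self.cube_size,) * 3:
            raise ValueError(
                f"tile shape {self.data.shape} != cube_size {self.cube_size}"
            )


def fusion_weight(x, A: int):
    """Evaluate the exponential weighting map M(x) = (e^{x/A} - 1)/(e - 1).

    Strictly increasing on [1, A] with M(A) = 1. ``x`` may be a scalar or
    array; values outside [1, A] are rejected.
    """
    x = np.asarray(x, dtype=np.float64)
    if A < 1:
        raise ValueError("overlap width A must be >= 1")
    if np.any(x < 1) or np.any(x > A):
        raise ValueError(f"x must lie in [1, {A}]")
    out = (np.exp(x / A) - 1.0) / (np.e - 1.0)
    return float(out) if out.ndim == 0 else out


def _axis_origins(dim: int, cube: int, stride: int) -> list[int]:
    if dim <= cube:
        return [0]
    origins = list(range(0, dim - cube + 1, stride))
    if origins[-1] != dim - cube:
        origins.append(dim - cube)
    return origins


def split_cubes(vol: ReconVolume, cube_size: int = 128, overlap: int = 32) -> list[CubeTile]:
    """Divide a volume into overlapping cubes covering it completely.

    Tiles advance with stride ``cube_size - overlap`` per axis, with a final
    tile flush against each boundary. Volumes smaller than ``cube_size``
    along an axis are zero-padded up to the cube (the fusion step crops back
    to the parent shape).
    """
    if overlap < 0 or overlap >= cube_size:
        raise ValueError(f"overlap must lie in [0, cube_size), got {overlap}")
    data = vol.data
    pad = [(0, max(0, cube_size - s)) for s in data.shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad)
    stride = cube_size - overlap
    axes_origins = [_axis_origins(s, cube_size, stride) for s in data.shape]
    tiles = []
    for oz in axes_origins[0]:
        for ox in axes_origins[1]:
            for oy in axes_origins[2]:
                tiles.append(
                    CubeTile(
                        data=data[
                            oz:oz + cube_size, ox:ox + cube_size, oy:oy + cube_size
                        ].copy(),
                        origin=(oz, ox, oy),
                        cube_size=cube_size,
                    )
                )
    return tiles


def _tile_axis_profile(origin: int, cube: int, dim: int, A: int) -> np.ndarray:
    """Per-axis blending profile: M-ramp at a leading edge that overlaps a
    previous tile, (1 - M)-ramp at a trailing edge that overlaps a next one."""
    prof = np.ones(cube, dtype=np.float64)
    ramp = fusion_weight(np.arange(1, A + 1), A)
    if origin > 0:
        prof[:A] = ramp
    if origin + cube < dim:
        prof[-A:] = 1.0 - ramp
    return prof


def fuse_tiles(
    tiles: list[CubeTile],
    parent_shape: tuple[int, int, int],
    A: int = 32,
) -> np.ndarray:
    """Recombine tiles into the parent volume with exponential edge blending.

    Within each pairwise overlap of width ``A`` the incoming tile ramps up
    with M(x) while the incumbent ramps down with 1 - M(x); separable
    per-axis weights are accumulated and renormalized so contributions sum
    to one everywhere. Fusing unprocessed tiles reproduces the source volume.
    """
    if not tiles:
        raise ValueError("no tiles to fuse")
    cube = tiles[0].cube_size
    padded_shape = tuple(max(s, cube) for s in parent_shape)
    acc = np.zeros(padded_shape, dtype=np.float64)
    wsum = np.zeros(padded_shape, dtype=np.float64)
    for t in tiles:
        if t.cube_size != cube:
            raise ValueError("tiles have inconsistent cube sizes")
        oz, ox, oy = t.origin
        if any(o + cube > d for o, d in zip(t.origin, padded_shape)):
            raise ValueError(f"tile at {t.origin} exceeds parent shape {parent_shape}")
        w = (
            _tile_axis_profile(oz, cube, padded_shape[0], A)[:, None, None]
            * _tile_axis_profile(ox, cube, padded_shape[1], A)[None, :, None]
            * _tile_axis_profile(oy, cube, padded_shape[2], A)[None, None, :]
        )
        sl = (slice(oz, oz + cube), slice(ox, ox + cube), slice(oy, oy + cube))
        acc[sl] += w * np.asarray(t.data, dtype=np.float64)
        wsum[sl] += w
    if np.any(wsum <= 0):
        raise ValueError("tiles do not cover the parent volume")
    fused = acc / wsum
    return fused[: parent_shape[0], : parent_shape[1], : parent_shape[2]].astype(
        np.float32
    )
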