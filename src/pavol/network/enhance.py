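"""Whole-volume inference: cube split -> per-cube forward -> weighted fusion."""

from __future__ import annotations

import numpy as np

from ..recon import ReconVolume
from ..tiling import CubeTile, fuse_tiles, split_cubes
from .model import EnhancerModel

__all__ = ["enhance_volume"]


def enhance_volume(
    model: EnhancerModel,
    vol: ReconVolume,
    cube_size: int = 128,
    overlap: int = 32,
    clip: bool = True,
) -> ReconVolume:
    """Enhance a normalized volume cube by cube and fuse the results.

    Cubes are processed independently in inference mode and recombined with
    the exponential overlap weighting, so the output shape equals the input
    shape and repeated runs are bit-identical. ``clip`` clamps the network
    output to [0, 1] (the training targets' range).
    """
    if not vol.normalized:
        raise ValueError("enhance_volume expects a normalized volume")
    if cube_size % model.config.min_divisor:
        raise ValueError(
            f"cube_size {cube_size} not divisible by {model.config.min_divisor} "
            f"required by n_levels={model.config.n_levels}"
        )
    tiles = split_cubes(vol, cube_size=cube_size, overlap=overlap)
    out_tiles = []
    for t in tiles:
        pred = model.forward(t.data[None, None].astype(np.float32), training=False)
        out_tiles.append(CubeTile(data=pred[0, 0], origin=t.origin, cube_size=cube_size))
    fused = fuse_tiles(out_tiles, parent_shape=vol.data.shape, A=overlap)
    if clip:
        fused = np.clip(fused, 0.0, 1.0)
    return ReconVolume(data=fused, grid=vol.grid, normalized=True)
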