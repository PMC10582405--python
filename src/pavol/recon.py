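"""2D-stack delay-and-sum reconstruction, normalization and noise injection.

One cross-sectional image is back-projected per scan position and the frames
are stacked along elevation into a volume. Because each frame ignores
out-of-plane arrivals, structures blur along elevation — the central
degradation the enhancement network is trained to undo. Image-domain noise
(thermal plus EMI-like stripe interference) is then applied to the
normalized volume to produce the degraded network inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .acoustics import ScanConfig, Sinogram, TransducerSpec
from .grid import VoxelGrid

__all__ = [
    "ReconVolume",
    "NoiseModel",
    "das_frame",
    "stack_frames",
    "normalize_volume",
    "add_noise_volume",
]

log = logging.getLogger(__name__)


@dataclass
class ReconVolume:
    """Reconstructed 3D image (axial, lateral, elevation) with grid metadata."""

    data: np.ndarray
    grid: VoxelGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("ReconVolume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ReconVolume contains non-finite values")


@dataclass(frozen=True)
class NoiseModel:
    """Parametric image-domain noise: thermal Gaussian plus EMI stripes.

    The EMI component is a seeded surrogate for recorded interference: each
    elevation frame independently receives, at rate ``emi_stripe_rate``,
    laterally-extended oscillatory bands localized in a few axial rows.
    ``emi_cycles_per_mm`` sets the lateral oscillation frequency.
    """

    thermal_sigma: float = 0.05
    emi_amplitude: float = 0.3
    emi_stripe_rate: float = 0.3
    emi_cycles_per_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_sigma < 0 or self.emi_amplitude < 0 or self.emi_stripe_rate < 0:
            raise ValueError("noise amplitudes and rates must be non-negative")


def das_frame(
    sino: Sinogram,
    grid: VoxelGrid,
    spec: TransducerSpec,
    sound_speed_m_s: float = 1500.0,
    envelope: bool = True,
) -> np.ndarray:
    """Delay-and-sum back-projection of one sinogram onto the (axial, lateral) plane.

    Each pixel sums, over elements whose angle to the pixel lies within the
    acceptance angle, the linearly-interpolated sample at the pixel-element
    time of flight. With ``envelope`` (default), the magnitude of the
    analytic signal along each axial line of the summed RF image is returned,
    giving a non-negative image suitable for [0, 1] normalization.
    """
    c = sound_speed_m_s / 1000.0  # mm/us
    fs = sino.sampling_rate_MHz
    nz, nx = grid.shape[0], grid.shape[1]
    z = grid.axis_coords_mm(0) + grid.standoff_mm     # depth below face
    x = grid.axis_coords_mm(1)
    xe = spec.element_lateral_mm(grid.extent_mm[1])
    tan_acc = np.tan(np.deg2rad(spec.acceptance_angle_deg))

    img = np.zeros((nz, nx), dtype=np.float64)
    n_clipped = 0
    Z = z[:, None]
    for e in range(sino.n_elements):
        dx = x[None, :] - xe[e]
        dist = np.sqrt(Z**2 + dx**2)
        accept = np.abs(dx) / Z <= tan_acc
        t_idx = dist / c * fs - sino.t0_us * fs
        i0 = np.floor(t_idx).astype(np.int64)
        frac = t_idx - i0
        inside = (i0 >= 0) & (i0 < sino.n_samples - 1)
        n_clipped += int(np.count_nonzero(accept & ~inside))
        use = accept & inside
        i0c = np.clip(i0, 0, sino.n_samples - 2)
        line = sino.data[e].astype(np.float64)
        vals = line[i0c] * (1.0 - frac) + line[i0c + 1] * frac
        img += np.where(use, vals, 0.0)
    if n_clipped:
        log.warning(
            "das_frame: %d pixel/element pairs had time of flight beyond the "
            "record length; their contribution was zeroed",
            n_clipped,
        )
    if envelope:
        img = np.abs(hilbert(img, axis=0))
    return img.astype(np.float32)


def stack_frames(
    frames: list[np.ndarray],
    step_mm: float,
    grid: VoxelGrid,
) -> ReconVolume:
    """Stack per-position 2D frames into a volume, resampling along elevation.

    Frames are assumed ordered by scan position with constant ``step_mm``
    spacing. When the step differs from the grid's elevation spacing, frames
    are linearly interpolated onto the finer/coarser grid; the output
    elevation size is ``round(step/spacing) * (n_frames - 1) + 1`` for
    integer ratios.
    """
    if not frames:
        raise ValueError("no frames to stack")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    arr = np.stack(frames, axis=-1).astype(np.float32)  # (axial, lateral, pos)
    n_frames = arr.shape[-1]
    spacing = grid.spacing_mm[2]
    src = np.arange(n_frames) * step_mm
    if n_frames == 1:
        out = arr
        n_out = 1
    else:
        ratio = step_mm / spacing
        n_out = int(round(ratio * (n_frames - 1))) + 1
        dst = np.linspace(0.0, src[-1], n_out)
        idx = np.clip(np.searchsorted(src, dst, side="right") - 1, 0, n_frames - 2)
        w = (dst - src[idx]) / step_mm
        out = arr[..., idx] * (1.0 - w) + arr[..., idx + 1] * w
    vol_grid = VoxelGrid(
        shape=(arr.shape[0], arr.shape[1], n_out),
        spacing_mm=(grid.spacing_mm[0], grid.spacing_mm[1], spacing),
        standoff_mm=grid.standoff_mm,
    )
    return ReconVolume(data=out.astype(np.float32), grid=vol_grid, normalized=False)


def normalize_volume(vol: ReconVolume) -> ReconVolume:
    """Max-normalize the magnitude: output = |data| / max(|data|).

    All-zero volumes pass through unchanged (flagged normalized) rather than
    dividing by zero.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("cannot normalize a volume with NaN/Inf")
    mag = np.abs(vol.data)
    peak = float(mag.max())
    data = mag if peak == 0.0 else mag / peak
    return ReconVolume(data=data.astype(np.float32), grid=vol.grid, normalized=True)


def add_noise_volume(vol: ReconVolume, model: NoiseModel) -> ReconVolume:
    """Apply seeded thermal + EMI noise to a normalized volume, clipped to [0, 1].

    With all amplitudes zero the input is returned bit-exactly. Otherwise the
    output is ``clip(vol + N(0, thermal_sigma) + stripes, 0, 1)`` where the
    stripes are per-frame lateral oscillatory bands with a Gaussian axial
    envelope.
    """
    if not vol.normalized:
        raise ValueError("add_noise_volume expects a normalized volume")
    if model.thermal_sigma == 0 and (model.emi_amplitude == 0 or model.emi_stripe_rate == 0):
        return ReconVolume(data=vol.data.copy(), grid=vol.grid, normalized=True)
    rng = np.random.default_rng(model.seed)
    nz, nx, ny = vol.data.shape
    noisy = vol.data.astype(np.float64)
    if model.thermal_sigma > 0:
        noisy = noisy + rng.normal(0.0, model.thermal_sigma, size=vol.data.shape)
    if model.emi_amplitude > 0 and model.emi_stripe_rate > 0:
        x_mm = vol.grid.axis_coords_mm(1)
        z_idx = np.arange(nz)
        n_stripes = rng.poisson(model.emi_stripe_rate, size=ny)
        for j in range(ny):
            for _ in range(int(n_stripes[j])):
                z0 = rng.uniform(0, nz)
                width = rng.uniform(1.0, 4.0)              # axial rows
                phase = rng.uniform(0, 2 * np.pi)
                amp = model.emi_amplitude * rng.uniform(0.5, 1.0)
                envelope = np.exp(-0.5 * ((z_idx - z0) / width) ** 2)
                wave = np.sin(2 * np.pi * model.emi_cycles_per_mm * x_mm + phase)
                noisy[:, :, j] += amp * envelope[:, None] * wave[None, :]
    data = np.clip(noisy, 0.0, 1.0).astype(np.float32)
    return ReconVolume(data=data, grid=vol.grid, normalized=True)
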