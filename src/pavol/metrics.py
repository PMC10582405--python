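"""Quantification of volumetric image quality and vascular structure.

Covers the validation metrics (MSE, PSNR, SSIM on normalized volumes), SNR
in dB from signal/noise regions, FWHM-based size/resolution measurement,
depth-encoded maximum-amplitude-projection rendering, binarization, the
leakage index used to grade vessel blurriness, and vessel density within a
region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

from .recon import ReconVolume

__all__ = [
    "RoiSpec",
    "DepthMap",
    "mse",
    "psnr",
    "ssim",
    "snr_db",
    "fwhm",
    "depth_encoded_map",
    "binarize",
    "leakage_index",
    "vessel_density",
]

_AXES = {"axial": 0, "lateral": 1, "elevation": 2}


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, ReconVolume) else np.asarray(vol)


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned box (half-open, 0-based) or explicit binary mask."""

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.box is None) == (self.mask is None):
            raise ValueError("provide exactly one of box or mask")

    def to_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != tuple(shape):
                raise ValueError(f"mask shape {m.shape} != volume shape {shape}")
            if not m.any():
                raise ValueError("empty ROI")
            return m
        m = np.zeros(shape, dtype=bool)
        sl = []
        for (start, stop), n in zip(self.box, shape):
            if not 0 <= start < stop <= n:
                raise ValueError(f"box {self.box} outside volume of shape {shape}")
            sl.append(slice(start, stop))
        m[tuple(sl)] = True
        return m


@dataclass
class DepthMap:
    """Max projection plus the depth (argmax index) of each projected maximum."""

    intensity: np.ndarray
    depth: np.ndarray
    axis: str

    def render_rgb(self, cmap: str = "jet") -> np.ndarray:
        """Color the depth with a colormap and scale value by intensity."""
        import matplotlib

        n = max(int(self.depth.max()), 1)
        rgba = matplotlib.colormaps[cmap](self.depth / n)
        return (rgba[..., :3] * self.intensity[..., None]).astype(np.float32)


def mse(a, b) -> float:
    """Mean squared voxel-wise difference."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))


def psnr(a, b, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs give +inf."""
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def ssim(a, b, window: int = 7) -> float:
    """Mean local structural similarity over a 3D sliding window.

    Uses the standard constants K1 = 0.01, K2 = 0.03 with dynamic range 1
    (volumes are expected normalized to [0, 1]).
    """
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if window > min(a.shape):
        raise ValueError(f"window {window} exceeds the smallest dimension {min(a.shape)}")
    return float(
        structural_similarity(
            a.astype(np.float64),
            b.astype(np.float64),
            win_size=window,
            data_range=1.0,
            gaussian_weights=False,
        )
    )


def snr_db(vol, signal_roi: RoiSpec, noise_roi: RoiSpec) -> float:
    """20 log10(peak signal / noise standard deviation), in dB."""
    arr = _as_array(vol)
    sig = signal_roi.to_mask(arr.shape)
    noi = noise_roi.to_mask(arr.shape)
    if np.any(sig & noi):
        raise ValueError("signal and noise ROIs overlap")
    peak = float(np.max(np.abs(arr[sig])))
    sd = float(np.std(arr[noi]))
    if sd == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak / sd))


def fwhm(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum of a peaked 1D profile, in mm.

    Half-maximum crossings on each side of the (unique) global maximum are
    located by linear interpolation between samples.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    peak = p.max()
    if peak <= 0:
        raise ValueError("profile has no positive peak")
    imax = int(np.argmax(p))
    half = peak / 2.0

    def _crossing(side: int) -> float:
        i = imax
        while 0 <= i + side < p.size:
            j = i + side
            if p[j] < half:
                # interpolate between j-side (>= half) and j (< half)
                f = (p[i] - half) / (p[i] - p[j])
                return i + side * f
            i = j
        raise ValueError("profile does not cross half maximum on one side")

    left = _crossing(-1)
    right = _crossing(+1)
    return float((right - left) * spacing_mm)


def depth_encoded_map(vol, axis: str = "axial") -> DepthMap:
    """Maximum amplitude projection with argmax depth (shallowest on ties)."""
    arr = _as_array(vol)
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    return DepthMap(
        intensity=np.max(arr, axis=ax),
        depth=np.argmax(arr, axis=ax),
        axis=axis if isinstance(axis, str) else "axial",
    )


def binarize(vol, method: str = "fixed_fraction", fraction: float = 0.1) -> np.ndarray:
    """Threshold a normalized volume to a binary vessel mask.

    ``fixed_fraction`` thresholds at ``fraction x max``; ``otsu`` uses Otsu's
    histogram threshold.
    """
    arr = _as_array(vol)
    if method == "fixed_fraction":
        if not 0.0 < fraction < 1.0:
            raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
        thresh = fraction * float(arr.max())
    elif method == "otsu":
        thresh = float(threshold_otsu(np.asarray(arr)))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return arr > thresh


def leakage_index(
    input_vol,
    output_vol,
    method: str = "fixed_fraction",
    fraction: float = 0.1,
) -> float:
    """Ratio of binarized nonzero counts, input over enhanced output.

    Values above 1 indicate the input's vessels are blurrier (spread over
    more voxels) than the enhanced output's.
    """
    a, b = _as_array(input_vol), _as_array(output_vol)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n_in = int(np.count_nonzero(binarize(a, method, fraction)))
    n_out = int(np.count_nonzero(binarize(b, method, fraction)))
    if n_out == 0:
        raise ValueError("binarized output volume is empty")
    return n_in / n_out


def vessel_density(binary_vol: np.ndarray, roi: RoiSpec) -> float:
    """Fraction of vessel-positive voxels inside the ROI."""
    arr = np.asarray(binary_vol, dtype=bool)
    m = roi.to_mask(arr.shape)
    return float(np.count_nonzero(arr & m)) / float(np.count_nonzero(m))
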