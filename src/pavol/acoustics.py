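"""Scanned linear-array photoacoustic acquisition simulator.

Models the acquisition geometry of a 128-element 2.25 MHz linear array swept
mechanically along elevation: at each scan position, every element records an
A-line that is the superposition of spherical wavelets from all absorbing
voxels inside a moving simulated sub-region around the imaging plane. The
forward model is analytic time-of-flight with 1/r spherical spreading,
cosine-squared element directivity truncated at an acceptance angle, an
elevation focal line (acceptance measured from the focus), and a band-limited
bipolar impulse response. Acoustic heterogeneity, attenuation and fluence
variations are deliberately not modelled; the degradations the enhancement
network must learn (elevation blur, limited view, band-limiting) all arise
from this geometry.

Internal units: mm, microseconds, MHz (so sound speed is mm/us).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .grid import VoxelGrid
from .phantom import VesselPhantom

__all__ = [
    "TransducerSpec",
    "ScanConfig",
    "Sinogram",
    "impulse_response",
    "impulse_response_kernel",
    "simulate_frame",
    "simulate_scan",
    "scan_positions_mm",
]

_DIRECTIVITY_POWER = 2  # cosine-power falloff exponent


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry and frequency response of the linear array.

    Defaults mimic a customized 2.25 MHz, 128-element array with an 86 mm
    aperture (pitch 0.672 mm). Element height, elevation focus and acceptance
    angle are not published for the physical probe and are exposed as
    configuration with documented defaults.
    """

    n_elements: int = 128
    center_freq_MHz: float = 2.25
    fractional_bandwidth: float = 0.6
    pitch_mm: float = 0.672
    element_height_mm: float = 4.0
    elevation_focus_mm: float = 30.0
    acceptance_angle_deg: float = 15.0
    elevation_acceptance_deg: float | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.center_freq_MHz <= 0 or self.fractional_bandwidth <= 0:
            raise ValueError("center frequency and bandwidth must be positive")
        if self.pitch_mm <= 0 or self.element_height_mm <= 0:
            raise ValueError("pitch and element height must be positive")

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    @property
    def elevation_acceptance(self) -> float:
        """Elevation acceptance half-angle in degrees (defaults to the
        in-plane acceptance when not set explicitly)."""
        return (
            self.acceptance_angle_deg
            if self.elevation_acceptance_deg is None
            else self.elevation_acceptance_deg
        )

    def element_lateral_mm(self, lateral_extent_mm: float) -> np.ndarray:
        """Element centers along lateral, centered on the volume."""
        n = self.n_elements
        return lateral_extent_mm / 2.0 + (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm


@dataclass(frozen=True)
class ScanConfig:
    """Mechanical elevation scan and digitizer settings."""

    step_mm: float = 0.2
    n_positions: int = 1
    sound_speed_m_s: float = 1500.0
    sampling_rate_MHz: float = 20.0
    subregion_elevation_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.subregion_elevation_mm < self.step_mm:
            raise ValueError("sub-region must span at least one step")

    def validate_sampling(self, spec: TransducerSpec) -> None:
        f_upper = spec.center_freq_MHz * (1 + spec.fractional_bandwidth / 2.0)
        if self.sampling_rate_MHz < 4.0 * f_upper:
            raise ValueError(
                f"sampling rate {self.sampling_rate_MHz} MHz below 4x the "
                f"upper band edge {f_upper} MHz"
            )

    @property
    def c_mm_us(self) -> float:
        return self.sound_speed_m_s / 1000.0


@dataclass
class Sinogram:
    """Channel data for one scan position: (n_elements, n_samples)."""

    data: np.ndarray
    sampling_rate_MHz: float
    t0_us: float = 0.0
    position_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D (elements x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def n_elements(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _wavelet_sigma_us(spec: TransducerSpec) -> float:
    # Gaussian envelope whose -6 dB (half-amplitude) spectral width equals
    # fractional_bandwidth * center frequency.
    sigma_f = spec.center_freq_MHz * spec.fractional_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return 1.0 / (2.0 * np.pi * sigma_f)


def impulse_response(t: np.ndarray, spec: TransducerSpec) -> np.ndarray:
    """Band-limited bipolar element impulse response, unit peak magnitude.

    A Gaussian-modulated cosine at the center frequency with its (tiny)
    residual DC component projected out, so the wavelet is exactly zero-mean
    on the sample grid. The envelope width is set so the -6 dB spectral
    width equals ``fractional_bandwidth x center_freq``.

    ``t`` must be uniformly sampled (microseconds) and sampled above the
    Nyquist rate of the upper band edge.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.size < 2:
        raise ValueError("t must contain at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("t must be uniformly sampled")
    fs = 1.0 / dt[0]
    f_upper = spec.center_freq_MHz * (1 + spec.fractional_bandwidth / 2.0)
    if fs < 2.0 * f_upper:
        raise ValueError(
            f"sampling rate {fs:.3f} MHz below Nyquist of the upper band "
            f"edge {f_upper:.3f} MHz"
        )
    sigma_t = _wavelet_sigma_us(spec)
    env = np.exp(-0.5 * (t / sigma_t) ** 2)
    h = env * np.cos(2.0 * np.pi * spec.center_freq_MHz * t)
    h -= env * (h.sum() / env.sum())  # exact zero mean on this grid
    return (h / np.max(np.abs(h))).astype(np.float64)


def impulse_response_kernel(spec: TransducerSpec, sampling_rate_MHz: float) -> np.ndarray:
    """Symmetric wavelet kernel sampled at the digitizer rate (odd length)."""
    sigma_t = _wavelet_sigma_us(spec)
    half = int(np.ceil(4.0 * sigma_t * sampling_rate_MHz))
    t = np.arange(-half, half + 1) / sampling_rate_MHz
    return impulse_response(t, spec)


def scan_positions_mm(grid: VoxelGrid, scan: ScanConfig) -> np.ndarray:
    """Frame-plane elevation coordinates, centered on the volume."""
    n = scan.n_positions
    center = grid.extent_mm[2] / 2.0
    return center + (np.arange(n) - (n - 1) / 2.0) * scan.step_mm


def default_n_samples(grid: VoxelGrid, spec: TransducerSpec, scan: ScanConfig) -> int:
    ez, ex, _ = grid.extent_mm
    zmax = grid.standoff_mm + ez
    dx = max(ex, spec.aperture_mm)
    dy = scan.subregion_elevation_mm / 2.0 + spec.element_height_mm
    dmax = np.sqrt(zmax**2 + dx**2 + dy**2)
    sigma_t = _wavelet_sigma_us(spec)
    return int(np.ceil((dmax / scan.c_mm_us + 4.0 * sigma_t) * scan.sampling_rate_MHz)) + 8


def simulate_frame(
    phantom: VesselPhantom,
    spec: TransducerSpec,
    scan: ScanConfig,
    position_index: int,
    n_samples: int | None = None,
) -> Sinogram:
    """Synthesize one sinogram at a single scan position.

    Each A-line sums, over absorbing voxels inside the moving sub-region and
    inside the acceptance cone, ``absorption / distance`` delayed by
    ``distance / c`` and weighted by lateral and elevation directivity, then
    convolves with the element impulse response. The element face is
    integrated across its height with 3-point Simpson quadrature including
    the elevation-lens delay compensation (focal line at
    ``elevation_focus_mm``).
    """
    scan.validate_sampling(spec)
    if not 0 <= position_index < scan.n_positions:
        raise IndexError(
            f"position_index {position_index} outside scan range "
            f"[0, {scan.n_positions})"
        )
    grid = phantom.grid
    if spec.aperture_mm > grid.extent_mm[1] + 1e-9:
        raise ValueError(
            f"array aperture {spec.aperture_mm:.1f} mm exceeds the simulated "
            f"lateral extent {grid.extent_mm[1]:.1f} mm"
        )
    if n_samples is None:
        n_samples = default_n_samples(grid, spec, scan)
    fs = scan.sampling_rate_MHz
    c = scan.c_mm_us
    y_pos = scan_positions_mm(grid, scan)[position_index]

    record = np.zeros((spec.n_elements, n_samples), dtype=np.float64)
    zi, xi, yi = np.nonzero(phantom.absorption)
    if zi.size:
        z = (zi + 0.5) * grid.spacing_mm[0] + grid.standoff_mm  # depth below face
        x = (xi + 0.5) * grid.spacing_mm[1]
        y = (yi + 0.5) * grid.spacing_mm[2]
        val = phantom.absorption[zi, xi, yi].astype(np.float64)

        inwin = np.abs(y - y_pos) <= scan.subregion_elevation_mm / 2.0
        if inwin.any():
            z, x, y, val = z[inwin], x[inwin], y[inwin], val[inwin]
            # elevation acceptance from the virtual focal line
            dz_focus = np.maximum(np.abs(z - spec.elevation_focus_mm), 1e-6)
            tan_el = np.abs(y - y_pos) / dz_focus
            tan_acc_el = np.tan(np.deg2rad(spec.elevation_acceptance))
            ok = tan_el <= tan_acc_el
            if ok.any():
                z, x, y, val = z[ok], x[ok], y[ok], val[ok]
                cos_el = 1.0 / np.sqrt(1.0 + (np.abs(y - y_pos) / dz_focus[ok]) ** 2)
                amp_el = val * cos_el**_DIRECTIVITY_POWER
                tan_acc_lat = np.tan(np.deg2rad(spec.acceptance_angle_deg))
                _accumulate_record(
                    record, z, x, y - y_pos, amp_el, spec, grid, fs, c, tan_acc_lat
                )

    kernel = impulse_response_kernel(spec, fs)
    data = fftconvolve(record, kernel[None, :], mode="same", axes=1)
    return Sinogram(
        data=data.astype(np.float32),
        sampling_rate_MHz=fs,
        t0_us=0.0,
        position_index=position_index,
    )


def _accumulate_record(record, z, x, dy, amp, spec, grid, fs, c, tan_acc):
    """Scatter delayed 1/r contributions into the (element, sample) record."""
    n_el, n_samples = record.shape
    xe = spec.element_lateral_mm(grid.extent_mm[1])
    h = spec.element_height_mm
    zf = spec.elevation_focus_mm
    quad = ((-h / 2.0, 1.0 / 6.0), (0.0, 4.0 / 6.0), (h / 2.0, 1.0 / 6.0))
    # chunk sources so the (sources x elements) blocks stay small
    chunk = max(1, 4_000_000 // n_el)
    for s0 in range(0, z.size, chunk):
        sl = slice(s0, s0 + chunk)
        zc, xc, dyc, ac = z[sl], x[sl], dy[sl], amp[sl]
        dxe = xc[:, None] - xe[None, :]           # (S, E)
        lat_tan = np.abs(dxe) / zc[:, None]
        lat_ok = lat_tan <= tan_acc
        if not lat_ok.any():
            continue
        cos_lat = 1.0 / np.sqrt(1.0 + lat_tan**2)
        w_lat = np.where(lat_ok, cos_lat**_DIRECTIVITY_POWER, 0.0)
        r_inplane2 = zc[:, None] ** 2 + dxe**2
        for u, wq in quad:
            lens_delay = (np.sqrt(zf**2 + u**2) - zf) / c
            dist = np.sqrt(r_inplane2 + (dyc[:, None] - u) ** 2)
            a = wq * ac[:, None] * w_lat / dist
            t_idx = dist / c * fs - lens_delay * fs
            i0 = np.floor(t_idx).astype(np.int64)
            frac = t_idx - i0
            valid = (i0 >= 0) & (i0 < n_samples - 1) & (a != 0.0)
            if not valid.any():
                continue
            eidx = np.broadcast_to(np.arange(n_el)[None, :], i0.shape)[valid]
            i0v, fv, av = i0[valid], frac[valid], a[valid]
            flat = eidx * n_samples + i0v
            acc = np.bincount(flat, weights=av * (1.0 - fv), minlength=record.size)
            acc += np.bincount(flat + 1, weights=av * fv, minlength=record.size)
            record += acc.reshape(record.shape)


def simulate_scan(
    phantom: VesselPhantom,
    spec: TransducerSpec,
    scan: ScanConfig,
    n_samples: int | None = None,
) -> list[Sinogram]:
    """Run :func:`simulate_frame` at every scan position.

    The scan must fit inside the phantom's elevation extent.
    """
    if scan.n_positions * scan.step_mm > phantom.grid.extent_mm[2] + 1e-9:
        raise ValueError(
            f"scan span {scan.n_positions * scan.step_mm:.1f} mm exceeds the "
            f"phantom elevation extent {phantom.grid.extent_mm[2]:.1f} mm"
        )
    if n_samples is None:
        n_samples = default_n_samples(phantom.grid, spec, scan)
    return [
        simulate_frame(phantom, spec, scan, k, n_samples=n_samples)
        for k in range(scan.n_positions)
    ]
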