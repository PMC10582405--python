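"""Forward acquisition model: impulse response, time of flight, scan geometry."""

import numpy as np
import pytest

from pavol.acoustics import (
    ScanConfig,
    TransducerSpec,
    impulse_response,
    impulse_response_kernel,
    simulate_frame,
    simulate_scan,
)
from pavol.grid import VoxelGrid
from pavol.phantom import VesselPhantom

from conftest import point_source_phantom


def _wavelet(spec, fs=40.0, half_us=4.0):
    n = int(half_us * fs)
    t = np.arange(-n, n + 1) / fs
    return t, impulse_response(t, spec)


class TestImpulseResponse:
    def test_zero_mean(self):
        t, h = _wavelet(TransducerSpec())
        assert abs(h.sum()) <= 1e-6 * np.max(np.abs(h))

    def test_unit_peak(self):
        _, h = _wavelet(TransducerSpec())
        assert np.max(np.abs(h)) == pytest.approx(1.0)

    def test_spectral_peak_at_center_frequency(self):
        spec = TransducerSpec()
        fs = 40.0
        t, h = _wavelet(spec, fs=fs)
        nfft = 1 << 14
        f = np.fft.rfftfreq(nfft, d=1 / fs)
        mag = np.abs(np.fft.rfft(h, nfft))
        peak = f[np.argmax(mag)]
        assert abs(peak - spec.center_freq_MHz) <= f[1]

    def test_doubling_bandwidth_halves_temporal_support(self):
        """-6 dB envelope width scales inversely with fractional bandwidth."""

        def width_us(bw):
            spec = TransducerSpec(fractional_bandwidth=bw)
            t, h = _wavelet(spec, fs=80.0, half_us=6.0)
            env = np.abs(h)
            above = t[env >= 0.5 * env.max()]
            return above[-1] - above[0]

        ratio = width_us(0.4) / width_us(0.8)
        assert abs(ratio - 2.0) / 2.0 < 0.1

    def test_undersampled_grid_rejected(self):
        spec = TransducerSpec()
        t = np.arange(-50, 51) / 4.0  # 4 MHz sampling, below Nyquist of band edge
        with pytest.raises(ValueError, match="Nyquist"):
            impulse_response(t, spec)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            impulse_response(t, TransducerSpec())


class TestSimulateFrame:
    def test_empty_phantom_gives_zero_sinogram(self, small_grid, desk_spec, single_frame_scan):
        ph = VesselPhantom(grid=small_grid, absorption=np.zeros(small_grid.shape))
        sino = simulate_frame(ph, desk_spec, single_frame_scan, 0)
        assert not sino.data.any()

    def test_point_source_time_of_flight(self, desk_spec):
        """A-line peak lands at round(distance / c * fs) for an on-axis source."""
        grid = VoxelGrid(shape=(120, 64, 16), spacing_mm=(0.1, 0.2, 0.2), standoff_mm=30.0)
        scan = ScanConfig(step_mm=0.2, n_positions=1, sampling_rate_MHz=20.0,
                          subregion_elevation_mm=3.2)
        xe = desk_spec.element_lateral_mm(grid.extent_mm[1])
        e = 16
        xi = int(round(xe[e] / 0.2 - 0.5))
        zi = 99  # depth 30 + 9.95 = 39.95 mm
        ph = point_source_phantom(grid, zi, xi, 8)
        sino = simulate_frame(ph, desk_spec, scan, 0)
        depth = (zi + 0.5) * 0.1 + 30.0
        expected = depth / 1.5 * 20.0  # distance / c * fs
        peak = int(np.argmax(np.abs(sino.data[e])))
        assert abs(peak - expected) <= 1.0

    def test_spherical_spreading_amplitude_decay(self, desk_spec):
        """Peak A-line amplitude falls as 1/distance for an on-axis source.

        Depths are chosen on voxel centers whose time of flight lands on an
        integer sample (39.9 and 69.9 mm at 20 MHz), so sub-sample
        interpolation does not modulate the wavelet peak.
        """
        grid = VoxelGrid(shape=(280, 64, 16), spacing_mm=(0.2, 0.2, 0.2), standoff_mm=30.0)
        scan = ScanConfig(step_mm=0.2, n_positions=1, sampling_rate_MHz=20.0,
                          subregion_elevation_mm=3.2)
        xe = desk_spec.element_lateral_mm(grid.extent_mm[1])
        e = 16
        xi = int(round(xe[e] / 0.2 - 0.5))
        depths = (39.9, 69.9)
        peaks = []
        for depth in depths:
            zi = int(round((depth - 30.0) / 0.2 - 0.5))
            ph = point_source_phantom(grid, zi, xi, 8)
            sino = simulate_frame(ph, desk_spec, scan, 0)
            peaks.append(np.abs(sino.data[e]).max())
        assert peaks[0] / peaks[1] == pytest.approx(depths[1] / depths[0], rel=0.05)

    def test_linearity_and_amplitude_scaling(self, small_grid, desk_spec, single_frame_scan):
        rng = np.random.default_rng(0)
        a = np.zeros(small_grid.shape, dtype=np.float32)
        b = np.zeros(small_grid.shape, dtype=np.float32)
        idx = tuple(rng.integers(0, s, size=20) for s in small_grid.shape)
        a[idx] = rng.uniform(0.2, 1.0, 20)
        idx2 = tuple(rng.integers(0, s, size=20) for s in small_grid.shape)
        b[idx2] = rng.uniform(0.2, 1.0, 20)
        s_a = simulate_frame(VesselPhantom(small_grid, a), desk_spec, single_frame_scan, 0)
        s_b = simulate_frame(VesselPhantom(small_grid, b), desk_spec, single_frame_scan, 0)
        s_ab = simulate_frame(VesselPhantom(small_grid, a + b), desk_spec, single_frame_scan, 0)
        np.testing.assert_allclose(s_ab.data, s_a.data + s_b.data, atol=1e-5)
        s_3a = simulate_frame(VesselPhantom(small_grid, 3.0 * a), desk_spec, single_frame_scan, 0)
        np.testing.assert_allclose(s_3a.data, 3.0 * s_a.data, rtol=1e-4, atol=1e-6)

    def test_position_outside_scan_rejected(self, small_grid, desk_spec, single_frame_scan):
        ph = VesselPhantom(grid=small_grid, absorption=np.zeros(small_grid.shape))
        with pytest.raises(IndexError):
            simulate_frame(ph, desk_spec, single_frame_scan, 1)

    def test_aperture_exceeding_volume_rejected(self, small_grid, single_frame_scan):
        wide = TransducerSpec(n_elements=64, pitch_mm=0.4)  # 25.6 mm > 12.8 mm
        ph = VesselPhantom(grid=small_grid, absorption=np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="aperture"):
            simulate_frame(ph, wide, single_frame_scan, 0)


class TestSimulateScan:
    @pytest.fixture
    def scan8(self):
        return ScanConfig(step_mm=0.2, n_positions=8, sampling_rate_MHz=20.0,
                          subregion_elevation_mm=1.6)

    def test_single_position_matches_simulate_frame(self, small_grid, desk_spec,
                                                    single_frame_scan):
        ph = point_source_phantom(small_grid, 30, 32, 8)
        scan_list = simulate_scan(ph, desk_spec, single_frame_scan)
        frame = simulate_frame(ph, desk_spec, single_frame_scan, 0)
        assert len(scan_list) == 1
        np.testing.assert_array_equal(scan_list[0].data, frame.data)

    def test_position_indices_strictly_increasing(self, small_grid, desk_spec, scan8):
        ph = point_source_phantom(small_grid, 30, 32, 8)
        sinos = simulate_scan(ph, desk_spec, scan8)
        assert [s.position_index for s in sinos] == list(range(8))

    def test_elevation_mirror_symmetry(self, small_grid, desk_spec, scan8):
        """A phantom symmetric under elevation flip yields a palindromic scan."""
        a = np.zeros(small_grid.shape, dtype=np.float32)
        a[30, 32, 3] = 1.0
        a[30, 32, 12] = 1.0  # mirror of 3 in a 16-voxel axis
        ph = VesselPhantom(grid=small_grid, absorption=a)
        sinos = simulate_scan(ph, desk_spec, scan8)
        for k in range(len(sinos)):
            np.testing.assert_allclose(
                sinos[k].data, sinos[len(sinos) - 1 - k].data, atol=1e-6
            )

    def test_shift_equivariance_along_elevation(self, small_grid, desk_spec, scan8):
        """Translating the phantom by one scan step shifts the sinogram list."""
        a = np.zeros(small_grid.shape, dtype=np.float32)
        a[30, 32, 7] = 1.0
        shifted = np.roll(a, 1, axis=2)  # +0.2 mm = one step
        s0 = simulate_scan(VesselPhantom(small_grid, a), desk_spec, scan8)
        s1 = simulate_scan(VesselPhantom(small_grid, shifted), desk_spec, scan8)
        for k in range(1, len(s0) - 1):
            np.testing.assert_allclose(s1[k + 1].data, s0[k].data, atol=1e-6)

    def test_scan_exceeding_phantom_rejected(self, small_grid, desk_spec):
        scan = ScanConfig(step_mm=0.5, n_positions=10, sampling_rate_MHz=20.0,
                          subregion_elevation_mm=1.0)  # 5 mm > 3.2 mm extent
        ph = point_source_phantom(small_grid, 30, 32, 8)
        with pytest.raises(ValueError, match="extent"):
            simulate_scan(ph, desk_spec, scan)

    def test_undersampled_scan_rejected(self, small_grid, desk_spec):
        scan = ScanConfig(step_mm=0.2, n_positions=1, sampling_rate_MHz=8.0,
                          subregion_elevation_mm=1.0)
        ph = point_source_phantom(small_grid, 30, 32, 8)
        with pytest.raises(ValueError, match="sampling"):
            simulate_frame(ph, desk_spec, scan, 0)
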