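"""3D fully-dense U-net: parameter accounting, training loop, streaming loader."""

import numpy as np
import pytest

from pavol.grid import VoxelGrid
from pavol.network import (
    DESK_CONFIG,
    REFERENCE_CONFIG,
    NetworkConfig,
    TrainingConfig,
    build_network,
    count_trainable_parameters,
    enhance_volume,
    stream_batches,
    train,
)
from pavol.network.layers import Conv3d
from pavol.network.train import mse_loss
from pavol.recon import ReconVolume


def symbolic_parameter_count(cfg: NetworkConfig) -> int:
    """Independent layer-by-layer arithmetic for the trainable total.

    Mirrors the architecture contract: Conv(+BN) contributes k^3*cin*cout
    weights plus 2*cout batch-norm parameters (no conv bias); the final
    1x1x1 projection has a bias and no batch norm.
    """
    L, m = cfg.n_levels, cfg.layers_per_dense_block
    g = cfg.growths

    def dense(cin, gi):
        total = 0
        c = cin
        for _ in range(m):
            total += 27 * c * gi + 2 * gi
            c += gi
        return total, c

    p = 27 * 1 * cfg.init_channels + 2 * cfg.init_channels  # stem
    c = cfg.init_channels
    skips = []
    for i in range(L):
        dp, c = dense(c, g[i])
        p += dp
        if i < L - 1:
            skips.append(c)
            p += 8 * c * c + 2 * c  # 2x2x2 stride-2 down conv + BN
    for i in range(L - 2, -1, -1):
        s = skips[i]
        p += 8 * c * s + 2 * s  # transposed conv + BN
        dp, c2 = dense(2 * s, g[i])
        p += dp
        p += c2 * s + 2 * s  # 1x1x1 compression + BN
        c = s
    p += 27 * c * cfg.refine_channels + 2 * cfg.refine_channels  # refinement
    p += cfg.refine_channels + 1  # 1x1x1 projection with bias
    return p


TINY = NetworkConfig(n_levels=2, init_channels=4, growth_rate=(2, 4),
                     layers_per_dense_block=1, refine_channels=4)


class TestParameterCount:
    @pytest.mark.parametrize(
        "cfg",
        [
            TINY,
            DESK_CONFIG,
            REFERENCE_CONFIG,
            NetworkConfig(n_levels=3, init_channels=8, growth_rate=4,
                          layers_per_dense_block=2, refine_channels=8),
        ],
    )
    def test_count_matches_symbolic_oracle(self, cfg):
        model = build_network(cfg)
        assert count_trainable_parameters(model) == symbolic_parameter_count(cfg)

    def test_lone_conv_with_bias(self):
        assert Conv3d(1, 16, 3, bias=True).n_params() == 27 * 16 + 16

    def test_lone_pointwise_conv_without_bias(self):
        assert Conv3d(4, 4, 1).n_params() == 16

    def test_dense_block_channel_bookkeeping(self):
        """Inner layer k of a dense block consumes in + (k-1)*growth channels."""
        cfg = NetworkConfig(n_levels=2, init_channels=6, growth_rate=(5, 10),
                            layers_per_dense_block=3, refine_channels=4)
        model = build_network(cfg)
        blk = model.enc_blocks[0]
        for k, inner in enumerate(blk.inner):
            assert inner.conv.cin == 6 + k * 5


class TestForward:
    def test_zero_cube_gives_finite_output_of_same_shape(self):
        model = build_network(DESK_CONFIG, seed=0)
        x = np.zeros((1, 1, 16, 16, 16), dtype=np.float32)
        y = model.forward(x)
        assert y.shape == x.shape
        assert np.all(np.isfinite(y))

    def test_indivisible_input_rejected(self):
        cfg = NetworkConfig(n_levels=3, init_channels=4, growth_rate=2,
                            layers_per_dense_block=1, refine_channels=4)
        model = build_network(cfg)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 6, 6, 6), dtype=np.float32))

    def test_inference_is_deterministic(self):
        model = build_network(TINY, seed=1)
        x = np.random.default_rng(0).uniform(size=(2, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_checkpoint_round_trip(self, tmp_path):
        from pavol.network import EnhancerModel

        model = build_network(TINY, seed=2)
        x = np.random.default_rng(1).uniform(size=(1, 1, 8, 8, 8)).astype(np.float32)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = EnhancerModel.load(path)
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))


def _make_pairs(tmp_path, n, shape=(4, 4, 4), seed=0):
    rng = np.random.default_rng(seed)
    for i in range(n):
        a = rng.uniform(size=shape).astype(np.float32)
        np.save(tmp_path / f"c{i:03d}_input.npy", a)
        np.save(tmp_path / f"c{i:03d}_target.npy", a)


class TestStreamBatches:
    def test_batch_partition_sizes(self, tmp_path):
        _make_pairs(tmp_path, 10)
        sizes = [x.shape[0] for x, _ in stream_batches(tmp_path, 4, seed=0)]
        assert sizes == [4, 4, 2]

    def test_same_seed_reproduces_order(self, tmp_path):
        _make_pairs(tmp_path, 10)
        stream = stream_batches(tmp_path, 3, seed=5)
        first = [x.copy() for x, _ in stream]
        second = [x.copy() for x, _ in stream]
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_epoch_covers_every_identifier_once(self, tmp_path):
        _make_pairs(tmp_path, 7)
        stream = stream_batches(tmp_path, 2, seed=1)
        seen = []
        order = np.random.default_rng(1).permutation(7)
        for x, y in stream:
            seen.append(x.shape[0])
            np.testing.assert_array_equal(x, y)  # identity pairs stay aligned
        assert sum(seen) == 7
        assert sorted(stream.ids) == [f"c{i:03d}" for i in range(7)]
        assert order.size == 7

    def test_unpaired_file_rejected_with_identifier(self, tmp_path):
        _make_pairs(tmp_path, 3)
        np.save(tmp_path / "c999_input.npy", np.zeros((4, 4, 4), np.float32))
        with pytest.raises(ValueError, match="c999"):
            stream_batches(tmp_path, 2, seed=0)


class _ListStream:
    def __init__(self, batches):
        self.batches = batches

    def __iter__(self):
        return iter([(x.copy(), y.copy()) for x, y in self.batches])


class TestTraining:
    def test_identity_task_overfits(self, tmp_path):
        """Training target = input: the loss must fall well below its start."""
        rng = np.random.default_rng(0)
        batches = []
        for _ in range(2):
            x = rng.uniform(0, 1, size=(3, 1, 8, 8, 8)).astype(np.float32)
            batches.append((x, x))
        model = build_network(TINY, seed=0)
        tc = TrainingConfig(learning_rate=3e-3, batch_size=3, max_epochs=50,
                            patience=50 - 1, seed=0)
        model, hist = train(model, _ListStream(batches), _ListStream(batches[:1]), tc)
        assert hist["train_loss"][-1] < 0.1 * hist["train_loss"][0]

    def test_early_stopping_after_patience_epochs(self):
        """A frozen model's validation loss never improves after epoch 1, so
        training stops at epoch 1 + patience."""

        class _FrozenModel:
            def forward(self, x, training=False):
                return np.zeros_like(x)

            def backward(self, g):
                return g

            def parameters(self):
                return iter(())

            def state_arrays(self):
                return {}

            def load_state_arrays(self, state):
                pass

        rng = np.random.default_rng(1)
        x = rng.uniform(size=(2, 1, 8, 8, 8)).astype(np.float32)
        y = rng.uniform(size=(2, 1, 8, 8, 8)).astype(np.float32)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=2, max_epochs=10,
                            patience=2, seed=0)
        _, hist = train(_FrozenModel(), _ListStream([(x, y)]), _ListStream([(x, y)]), tc)
        assert hist["stopped_epoch"] == 1 + tc.patience

    def test_nan_input_aborts_with_diagnostic(self):
        x = np.full((1, 1, 8, 8, 8), np.nan, dtype=np.float32)
        model = build_network(TINY, seed=2)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=1, max_epochs=2,
                            patience=1, seed=0)
        with pytest.raises(FloatingPointError, match="loss"):
            train(model, _ListStream([(x, x)]), _ListStream([(x, x)]), tc)

    def test_training_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(split_ratio=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(patience=300, max_epochs=300)


class TestEnhanceVolume:
    def _vol(self, shape=(16, 16, 16), seed=0):
        rng = np.random.default_rng(seed)
        return ReconVolume(data=rng.uniform(size=shape).astype(np.float32),
                           grid=VoxelGrid(shape=shape), normalized=True)

    def test_single_cube_matches_direct_forward(self):
        model = build_network(TINY, seed=3)
        vol = self._vol()
        out = enhance_volume(model, vol, cube_size=16, overlap=4)
        direct = model.forward(vol.data[None, None])[0, 0]
        np.testing.assert_allclose(out.data, np.clip(direct, 0, 1), atol=1e-6)

    def test_repeat_runs_bit_identical(self):
        model = build_network(TINY, seed=4)
        vol = self._vol(shape=(16, 24, 24), seed=5)
        a = enhance_volume(model, vol, cube_size=16, overlap=4)
        b = enhance_volume(model, vol, cube_size=16, overlap=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_shape_matches_input(self):
        model = build_network(TINY, seed=6)
        vol = self._vol(shape=(16, 30, 22), seed=7)
        out = enhance_volume(model, vol, cube_size=16, overlap=4)
        assert out.data.shape == vol.data.shape

    def test_unnormalized_volume_rejected(self):
        model = build_network(TINY, seed=8)
        vol = self._vol()
        vol.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            enhance_volume(model, vol, cube_size=16, overlap=4)

    def test_incompatible_cube_size_rejected(self):
        cfg = NetworkConfig(n_levels=4, init_channels=4, growth_rate=2,
                            layers_per_dense_block=1, refine_channels=4)
        model = build_network(cfg)
        with pytest.raises(ValueError, match="divisible"):
            enhance_volume(model, self._vol(), cube_size=12, overlap=4)
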