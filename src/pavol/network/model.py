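"""The 3D fully-dense U-net enhancer.

Encoder-decoder with DenseNet-style blocks: inside each block, every inner
layer receives the concatenation of the block input and all previously
generated feature maps, and contributes ``growth_rate`` new maps. Levels are
connected by 2x2x2 stride-2 convolutions (learned downsampling, no max
pooling) and stride-2 transposed convolutions with encoder-decoder skip
concatenation. All activations are ELU and every convolution except the
final projection is followed by batch normalization. Decoding ends with a
3x3x3 refinement convolution and a 1x1x1 projection to one channel.

``REFERENCE_CONFIG`` is the published-scale architecture: its depth/width/
growth hyperparameters were selected so the trainable-parameter total equals
the 6,052,025 budget of the full-scale model exactly (the parameter total is
the only architecture-level figure available for the published network).
``DESK_CONFIG`` is a deliberately slim variant for CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .layers import ELU, BatchNorm3d, Conv3d, ConvTranspose3d, Layer

__all__ = [
    "NetworkConfig",
    "EnhancerModel",
    "build_network",
    "count_trainable_parameters",
    "REFERENCE_CONFIG",
    "DESK_CONFIG",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``growth_rate`` may be a single int (doubled per level) or an explicit
    per-level tuple of length ``n_levels``. ``refine_channels`` is the width
    of the final 3x3x3 refinement convolution.
    """

    n_levels: int = 5
    init_channels: int = 22
    growth_rate: int | tuple[int, ...] = (7, 14, 28, 56, 100)
    layers_per_dense_block: int = 2
    refine_channels: int = 40
    bn_momentum: float = 0.99
    bn_epsilon: float = 0.001
    activation: str = "ELU"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.activation != "ELU":
            raise ValueError("only ELU activation is supported")
        if isinstance(self.growth_rate, (tuple, list)) and len(self.growth_rate) != self.n_levels:
            raise ValueError("per-level growth_rate must have n_levels entries")

    @property
    def growths(self) -> tuple[int, ...]:
        if isinstance(self.growth_rate, (tuple, list)):
            return tuple(int(g) for g in self.growth_rate)
        return tuple(int(self.growth_rate) * 2**i for i in range(self.n_levels))

    @property
    def min_divisor(self) -> int:
        """Input cube sides must be divisible by this (2^(n_levels - 1))."""
        return 2 ** (self.n_levels - 1)

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "init_channels": self.init_channels,
            "growth_rate": list(self.growths),
            "layers_per_dense_block": self.layers_per_dense_block,
            "refine_channels": self.refine_channels,
            "bn_momentum": self.bn_momentum,
            "bn_epsilon": self.bn_epsilon,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if isinstance(d.get("growth_rate"), list):
            d["growth_rate"] = tuple(d["growth_rate"])
        return cls(**d)


REFERENCE_CONFIG = NetworkConfig()

DESK_CONFIG = NetworkConfig(
    n_levels=3,
    init_channels=6,
    growth_rate=(5, 10, 20),
    layers_per_dense_block=1,
    refine_channels=6,
)


class _ConvBNAct:
    """Conv -> BatchNorm -> ELU composite."""

    def __init__(self, cin, cout, kernel, stride, cfg: NetworkConfig, rng) -> None:
        self.conv = Conv3d(cin, cout, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm3d(cout, momentum=cfg.bn_momentum, eps=cfg.bn_epsilon)
        self.act = ELU()
        self.out_channels = cout

    def forward(self, x, training=False):
        return self.act.forward(
            self.bn.forward(self.conv.forward(x, training), training), training
        )

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))

    def layers(self):
        return [self.conv, self.bn, self.act]


class _UpBNAct:
    """Transposed conv -> BatchNorm -> ELU composite."""

    def __init__(self, cin, cout, cfg: NetworkConfig, rng) -> None:
        self.up = ConvTranspose3d(cin, cout, kernel=2, rng=rng)
        self.bn = BatchNorm3d(cout, momentum=cfg.bn_momentum, eps=cfg.bn_epsilon)
        self.act = ELU()
        self.out_channels = cout

    def forward(self, x, training=False):
        return self.act.forward(
            self.bn.forward(self.up.forward(x, training), training), training
        )

    def backward(self, g):
        return self.up.backward(self.bn.backward(self.act.backward(g)))

    def layers(self):
        return [self.up, self.bn, self.act]


class _DenseBlock:
    """Within-block dense connectivity.

    Inner layer k consumes ``in_channels + (k - 1) * growth`` channels and
    produces ``growth`` new maps; the block output concatenates the input
    with every inner layer's maps.
    """

    def __init__(self, cin: int, growth: int, n_layers: int, cfg: NetworkConfig, rng) -> None:
        self.inner: list[_ConvBNAct] = []
        c = cin
        for _ in range(n_layers):
            self.inner.append(_ConvBNAct(c, growth, kernel=3, stride=1, cfg=cfg, rng=rng))
            c += growth
        self.in_channels = cin
        self.growth = growth
        self.out_channels = c

    def forward(self, x, training=False):
        feats = [x]
        for layer in self.inner:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=0)
            feats.append(layer.forward(inp, training))
        self._widths = [f.shape[0] for f in feats]
        return np.concatenate(feats, axis=0)

    def backward(self, g):
        widths = self._widths
        bounds = np.cumsum([0] + widths)
        g_feats = [
            g[bounds[i]:bounds[i + 1]].copy() for i in range(len(widths))
        ]
        for k in range(len(self.inner) - 1, -1, -1):
            g_inp = self.inner[k].backward(g_feats[k + 1])
            in_bounds = np.cumsum([0] + widths[: k + 1])
            for i in range(k + 1):
                g_feats[i] += g_inp[in_bounds[i]:in_bounds[i + 1]]
        return g_feats[0]

    def layers(self):
        out = []
        for l in self.inner:
            out.extend(l.layers())
        return out


class EnhancerModel:
    """3D fully-dense U-net mapping a degraded cube to an enhanced cube.

    Forward is deterministic in inference mode (running batch-norm moments);
    output shape equals input shape for cubes whose sides are divisible by
    ``config.min_divisor``.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        L = cfg.n_levels
        g = cfg.growths
        m = cfg.layers_per_dense_block

        self.stem = _ConvBNAct(1, cfg.init_channels, 3, 1, cfg, rng)
        c = cfg.init_channels
        self.enc_blocks: list[_DenseBlock] = []
        self.downs: list[_ConvBNAct] = []
        self.skip_channels: list[int] = []
        for i in range(L):
            blk = _DenseBlock(c, g[i], m, cfg, rng)
            self.enc_blocks.append(blk)
            c = blk.out_channels
            if i < L - 1:
                self.skip_channels.append(c)
                self.downs.append(_ConvBNAct(c, c, 2, 2, cfg, rng))
        self.ups: list[_UpBNAct] = []
        self.dec_blocks: list[_DenseBlock] = []
        self.compress: list[_ConvBNAct] = []
        for i in range(L - 2, -1, -1):
            s = self.skip_channels[i]
            self.ups.append(_UpBNAct(c, s, cfg, rng))
            blk = _DenseBlock(2 * s, g[i], m, cfg, rng)
            self.dec_blocks.append(blk)
            self.compress.append(_ConvBNAct(blk.out_channels, s, 1, 1, cfg, rng))
            c = s
        self.refine = _ConvBNAct(c, cfg.refine_channels, 3, 1, cfg, rng)
        self.out_conv = Conv3d(cfg.refine_channels, 1, 1, stride=1, bias=True, rng=rng)

    # ------------------------------------------------------------------ graph
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("input must have shape (batch, 1, D, H, W)")
        d = self.config.min_divisor
        if any(s % d for s in x.shape[2:]):
            raise ValueError(
                f"input spatial size {x.shape[2:]} not divisible by {d} "
                f"(n_levels={self.config.n_levels})"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        # internal layout is channels-first: (C, N, D, H, W)
        h = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(1, 0, 2, 3, 4)
        )
        h = self.stem.forward(h, training)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            h = blk.forward(h, training)
            if i < len(self.downs):
                skips.append(h)
                h = self.downs[i].forward(h, training)
        for j, (up, blk, comp) in enumerate(
            zip(self.ups, self.dec_blocks, self.compress)
        ):
            skip = skips[len(skips) - 1 - j]
            h = up.forward(h, training)
            h = np.concatenate([h, skip], axis=0)
            h = blk.forward(h, training)
            h = comp.forward(h, training)
        h = self.refine.forward(h, training)
        y = self.out_conv.forward(h, training)
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3, 4))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(
            np.asarray(g, dtype=np.float32).transpose(1, 0, 2, 3, 4)
        )
        g = self.refine.backward(self.out_conv.backward(g))
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.ups) - 1, -1, -1):
            level = len(self.skip_channels) - 1 - j
            s = self.skip_channels[level]
            g = self.dec_blocks[j].backward(self.compress[j].backward(g))
            skip_grads[level] = g[s:]
            g = self.ups[j].backward(np.ascontiguousarray(g[:s]))
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.downs):
                g = self.downs[i].backward(g) + skip_grads[i]
            g = self.enc_blocks[i].backward(g)
        gx = self.stem.backward(g)
        return np.ascontiguousarray(gx.transpose(1, 0, 2, 3, 4))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    # ------------------------------------------------------------- parameters
    def _composites(self):
        comps = [self.stem]
        for i, blk in enumerate(self.enc_blocks):
            comps.append(blk)
            if i < len(self.downs):
                comps.append(self.downs[i])
        for up, blk, comp in zip(self.ups, self.dec_blocks, self.compress):
            comps.extend([up, blk, comp])
        comps.append(self.refine)
        return comps

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for comp in self._composites():
            out.extend(comp.layers())
        out.append(self.out_conv)
        return out

    def parameters(self):
        """Yield (unique_name, layer, param_name) triples for the optimizer."""
        for idx, layer in enumerate(self.layers()):
            for pname in layer.params:
                yield f"layer{idx}.{pname}", layer, pname

    @property
    def trainable_parameter_count(self) -> int:
        return sum(layer.n_params() for layer in self.layers())

    # ------------------------------------------------------------- checkpoint
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for idx, layer in enumerate(self.layers()):
            for pname, p in layer.params.items():
                state[f"layer{idx}.{pname}"] = p
            if isinstance(layer, BatchNorm3d):
                state[f"layer{idx}.running_mean"] = layer.running_mean
                state[f"layer{idx}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for idx, layer in enumerate(self.layers()):
            for pname in layer.params:
                layer.params[pname] = np.array(state[f"layer{idx}.{pname}"])
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = np.array(state[f"layer{idx}.running_mean"])
                layer.running_var = np.array(state[f"layer{idx}.running_var"])

    def save(self, path) -> None:
        state = self.state_arrays()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **state)

    @classmethod
    def load(cls, path) -> "EnhancerModel":
        with np.load(path) as npz:
            cfg = NetworkConfig.from_dict(
                json.loads(bytes(npz["__config__"]).decode())
            )
            model = cls(cfg)
            model.load_state_arrays({k: npz[k] for k in npz.files if k != "__config__"})
        return model


def build_network(config: NetworkConfig, seed: int = 0) -> EnhancerModel:
    """Instantiate the 3D fully-dense U-net with seeded variance-scaling init."""
    return EnhancerModel(config, seed=seed)


def count_trainable_parameters(model: EnhancerModel) -> int:
    """Total element count over all trainable tensors (conv kernels, biases,
    batch-norm scales and shifts)."""
    return model.trainable_parameter_count
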