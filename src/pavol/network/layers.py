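"""Minimal NumPy/Numba 3D convolutional layers with explicit backpropagation.

Implements exactly the layer set the volumetric enhancer needs: 3D
convolution (stride 1 "same", or kernel-sized stride for downsampling),
transposed convolution for upsampling, batch normalization, and ELU.

Tensors are laid out channels-first as ``(C, N, D, H, W)`` in float32: with
the channel axis leading, dense-block concatenation and channel splits are
contiguous slices. The convolution inner loops are JIT-compiled
(:mod:`._kernels`); batch normalization, activations and the optimizer are
plain vectorized NumPy.

Each layer caches what its backward pass needs; ``backward`` returns the
gradient with respect to the input and fills ``grads`` for the optimizer.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K

__all__ = ["Layer", "Conv3d", "ConvTranspose3d", "BatchNorm3d", "ELU"]


class Layer:
    """Base class: parameter and gradient dictionaries."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv3d(Layer):
    """3D convolution with cubic kernel, stride 1 ("same") or stride = kernel.

    Bias defaults to off because every convolution in the network is followed
    by batch normalization except the final projection.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        stride: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if stride == 1:
            if kernel % 2 != 1:
                raise ValueError("stride-1 convolutions need an odd kernel")
            self.pad = kernel // 2
        elif stride == kernel:
            self.pad = 0  # non-overlapping downsampling (e.g. 2x2x2 stride 2)
        else:
            raise ValueError(f"unsupported kernel/stride combination {kernel}/{stride}")
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel**3
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel, kernel)
        ).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        C, N, Dp, Hp, Wp = xp.shape
        Do, Ho, Wo = (Dp - k) // s + 1, (Hp - k) // s + 1, (Wp - k) // s + 1
        out = np.zeros((self.cout, N, Do, Ho, Wo), dtype=np.float32)
        K.conv3d_forward(xp, self.params["W"], out, s)
        if "b" in self.params:
            out += self.params["b"][:, None, None, None, None]
        if training:
            self._xp = xp
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        g = np.ascontiguousarray(g, dtype=np.float32)
        dW = np.zeros_like(self.params["W"])
        K.conv3d_backward_dw(g, xp, dW, s)
        dxp = np.zeros_like(xp)
        K.conv3d_backward_dx(g, self.params["W"], dxp, s)
        self.grads["W"] = dW
        if "b" in self.params:
            self.grads["b"] = g.sum(axis=(1, 2, 3, 4))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel = stride (non-overlapping upsampling)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int = 2,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, kernel
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / cin), size=(cin, cout, kernel, kernel, kernel)
        ).astype(np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.k
        x = np.ascontiguousarray(x, dtype=np.float32)
        C, N, D, H, W_ = x.shape
        out = np.zeros((self.cout, N, D * k, H * k, W_ * k), dtype=np.float32)
        K.convT3d_forward(x, self.params["W"], out)
        if training:
            self._x = x
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        g = np.ascontiguousarray(g, dtype=np.float32)
        dW = np.zeros_like(self.params["W"])
        K.convT3d_backward_dw(g, x, dW)
        dx = np.zeros_like(x)
        K.convT3d_backward_dx(g, self.params["W"], dx)
        self.grads["W"] = dW
        self._x = None
        return dx


class BatchNorm3d(Layer):
    """Batch normalization over (batch, spatial) per channel.

    Training uses batch statistics and updates the running moments with
    ``running = momentum * running + (1 - momentum) * batch``; inference uses
    the running moments, making the forward pass deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        C = x.shape[0]
        x2 = x.reshape(C, -1)
        if training:
            mean = x2.mean(axis=1)
            var = x2.var(axis=1)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        # y = gamma * (x - mean) * inv + beta  ==  a * x + b
        a = (self.params["gamma"] * inv_std).astype(np.float32)
        b = (self.params["beta"] - self.params["gamma"] * inv_std * mean).astype(
            np.float32
        )
        y = np.empty_like(x)
        K.scale_shift(x2, a, b, y.reshape(C, -1))
        if training:
            self._x = x
            self._mean = mean
            self._inv_std = inv_std
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, mean, inv_std = self._x, self._mean, self._inv_std
        C = x.shape[0]
        n = x.size // C
        g = np.ascontiguousarray(g, dtype=np.float32)
        g2 = g.reshape(C, -1)
        x2 = x.reshape(C, -1)
        s1 = np.empty(C, dtype=np.float32)  # sum g
        sx = np.empty(C, dtype=np.float32)  # sum g * x
        K.channel_sums(g2, x2, s1, sx)
        # sum g * xhat, with xhat = (x - mean) * inv_std
        s2 = inv_std * (sx - mean * s1)
        self.grads["gamma"] = s2.copy()
        self.grads["beta"] = s1.copy()
        gamma = self.params["gamma"]
        # dx = (inv/n) * (n * gamma * g - gamma * s1 - xhat * gamma * s2)
        A = inv_std * gamma
        Cc = -(inv_std**2) * gamma * s2 / n
        B = (inv_std / n) * (-gamma * s1) - Cc * mean
        dx = np.empty_like(x)
        K.affine_combine(
            g2, x2, A.astype(np.float32), B.astype(np.float32),
            Cc.astype(np.float32), dx.reshape(C, -1)
        )
        self._x = None
        return dx


class ELU(Layer):
    """Exponential linear unit, alpha = 1.

    Only the output is cached for backward: ELU is monotone with y > 0 iff
    x > 0, and its derivative is 1 for y > 0 else y + 1.
    """

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.empty_like(x)
        K.elu_forward(x, y)
        if training:
            self._y = y
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(g, dtype=np.float32)
        dx = np.empty_like(g)
        K.elu_backward(g, self._y, dx)
        self._y = None
        return dx
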