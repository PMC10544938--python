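"""Minimal convolutional network layers with explicit backpropagation.

A small, dependency-free layer set (conv, pooling, nearest upsampling,
pointwise nonlinearities, linear) sufficient for the encoder-decoder
generator and the fused discriminator of the occlusion-restoration model.
Arrays are NCHW float64. Each layer caches what its backward pass needs;
``backward`` returns the gradient w.r.t. the input and accumulates
parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, arbitrary stride, zero padding, He-initialised."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = {
            "W": rng.normal(0.0, scale, (out_ch, in_ch, k, k)),
            "b": np.zeros(out_ch),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        out = cols @ Wm.T + self.params["b"]
        self._cache = (x.shape, cols)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (xshape, cols) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        _, _, ho, wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] += (dflat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dflat.sum(axis=0)
        dcols = (dflat @ Wm).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky : ky + s * ho : s, kx : kx + s * wo : s] += dcols[
                    :, :, :, :, ky, kx
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class AvgPool2(Layer):
    """2x2 average pooling (inputs must have even spatial size)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        return (
            dout.repeat(2, axis=2).repeat(2, axis=3) / 4.0
        )


class UpsampleNearest2(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits against a constant target.

    Returns (loss, dloss/dz).
    """
    p = sigmoid(z)
    eps = 1e-12
    loss = float(
        -np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps))
    )
    dz = (p - target) / z.size
    return loss, dz


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.items = [
            (layer, key) for layer in layers for key in layer.params
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.items]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.items]
        self.t = 0

    def zero_grad(self):
        for layer, _ in self.items:
            layer.zero_grad()

    def step(self):
        self.t += 1
        for i, (layer, key) in enumerate(self.items):
            g = layer.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_state(layers: list[Layer]) -> dict:
    state = {}
    for i, layer in enumerate(layers):
        for k, v in layer.params.items():
            state[f"{i}.{k}"] = v.copy()
    return state


def load_state(layers: list[Layer], state: dict) -> None:
    for i, layer in enumerate(layers):
        for k in layer.params:
            layer.params[k][...] = state[f"{i}.{k}"]
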