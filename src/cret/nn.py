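"""Minimal convolutional building blocks with hand-written backward passes.

The trainable parts of the pipeline (the feature encoder, the 1x1
channel-matching head, and the optional image restorator) are small CNNs.
They are implemented directly on numpy with explicit forward/backward
passes and an Adam optimizer; gradients are exact (verified against finite
differences in the test suite), and everything is float64 so checkpoint
round-trips are bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

__all__ = ["conv2d", "conv2d_backward", "Conv2D", "TinyEncoder", "Restorator",
           "Adam", "l1_loss"]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C, H, W) -> (H*W, C*kh*kw) with zero 'same' padding (odd kernels)."""
    c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (C, H, W, kh, kw)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * kh * kw)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """'same'-padded 2D correlation: (Cin,H,W) x (Cout,Cin,kh,kw) -> (Cout,H,W)."""
    cout, cin, kh, kw = weight.shape
    if x.shape[0] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.shape[0]}")
    h, w = x.shape[1:]
    cols = _im2col(x, kh, kw)
    y = cols @ weight.reshape(cout, -1).T + bias[None, :]
    return y.T.reshape(cout, h, w)


def conv2d_backward(dy: np.ndarray, x: np.ndarray, weight: np.ndarray):
    """Gradients of :func:`conv2d` -> (dx, dweight, dbias)."""
    cout, cin, kh, kw = weight.shape
    h, w = x.shape[1:]
    cols = _im2col(x, kh, kw)
    dy_mat = dy.reshape(cout, h * w)
    dweight = (dy_mat @ cols).reshape(weight.shape)
    dbias = dy_mat.sum(axis=1)
    # dx = correlation of dy with the spatially flipped, channel-transposed kernel
    w_back = weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    dx = conv2d(dy, np.ascontiguousarray(w_back), np.zeros(cin))
    return dx, dweight, dbias


@dataclass
class Conv2D:
    weight: np.ndarray
    bias: np.ndarray

    @classmethod
    def init(cls, cin: int, cout: int, k: int, rng: np.random.Generator,
             zero: bool = False) -> "Conv2D":
        if zero:
            w = np.zeros((cout, cin, k, k))
        else:
            # He-normal, appropriate for ReLU nets
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), (cout, cin, k, k))
        return cls(weight=w, bias=np.zeros(cout))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return conv2d(x, self.weight, self.bias)


class _ParamNet:
    """Shared parameter/gradient bookkeeping for the small nets below."""

    layers: Dict[str, Conv2D]

    def parameters(self) -> List[np.ndarray]:
        out = []
        for name in sorted(self.layers):
            out.extend([self.layers[name].weight, self.layers[name].bias])
        return out

    def gradients(self) -> List[np.ndarray]:
        out = []
        for name in sorted(self.layers):
            out.extend([self.grads[name + ".weight"], self.grads[name + ".bias"]])
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        d = {}
        for name, layer in self.layers.items():
            d[name + ".weight"] = layer.weight
            d[name + ".bias"] = layer.bias
        return d

    def load_state_dict(self, d: Dict[str, np.ndarray]) -> None:
        for name, layer in self.layers.items():
            layer.weight = np.array(d[name + ".weight"], dtype=float)
            layer.bias = np.array(d[name + ".bias"], dtype=float)


class TinyEncoder(_ParamNet):
    """Four-layer residual CNN feature extractor for squeezed sinograms.

    First layer is 1x1 with nine input channels when the sinogram was
    unfolded (the nine channels already carry the 3x3 neighborhood), else
    3x3 with one channel.  No downsampling; the residual skip connects the
    first activation to the output, so features stay shape-aligned with
    the squeezed window.
    """

    def __init__(self, unfolded: bool = True, hidden: int = 32,
                 features: int = 32, seed: int = 0):
        if features != hidden:
            raise ValueError("residual skip requires features == hidden")
        rng = np.random.default_rng(seed)
        cin, k1 = (9, 1) if unfolded else (1, 3)
        self.unfolded = unfolded
        self.features = features
        self.layers = {
            "conv1": Conv2D.init(cin, hidden, k1, rng),
            "conv2": Conv2D.init(hidden, hidden, 3, rng),
            "conv3": Conv2D.init(hidden, hidden, 3, rng),
            "conv4": Conv2D.init(hidden, features, 3, rng),
        }
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray):
        h1 = self.layers["conv1"](x)
        a1 = np.maximum(h1, 0.0)
        h2 = self.layers["conv2"](a1)
        a2 = np.maximum(h2, 0.0)
        h3 = self.layers["conv3"](a2)
        a3 = np.maximum(h3, 0.0)
        y = self.layers["conv4"](a3) + a1
        cache = (x, h1, a1, h2, a2, h3, a3)
        return y, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        x, h1, a1, h2, a2, h3, a3 = cache
        da3, dw4, db4 = conv2d_backward(dy, a3, self.layers["conv4"].weight)
        dh3 = da3 * (h3 > 0)
        da2, dw3, db3 = conv2d_backward(dh3, a2, self.layers["conv3"].weight)
        dh2 = da2 * (h2 > 0)
        da1, dw2, db2 = conv2d_backward(dh2, a1, self.layers["conv2"].weight)
        da1 = da1 + dy  # residual skip
        dh1 = da1 * (h1 > 0)
        dx, dw1, db1 = conv2d_backward(dh1, x, self.layers["conv1"].weight)
        self.grads = {
            "conv1.weight": dw1, "conv1.bias": db1,
            "conv2.weight": dw2, "conv2.bias": db2,
            "conv3.weight": dw3, "conv3.bias": db3,
            "conv4.weight": dw4, "conv4.bias": db4,
        }
        return dx


class Restorator(_ParamNet):
    """Six-layer residual image-to-image CNN for optional post-restoration.

    The last convolution is zero-initialized, so a freshly built restorator
    is the identity map (plug-and-play contract: applying it changes
    nothing until it has been trained).
    """

    def __init__(self, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = {
            "conv1": Conv2D.init(1, hidden, 3, rng),
            "conv2": Conv2D.init(hidden, hidden, 3, rng),
            "conv3": Conv2D.init(hidden, hidden, 3, rng),
            "conv4": Conv2D.init(hidden, hidden, 3, rng),
            "conv5": Conv2D.init(hidden, hidden, 3, rng),
            "conv6": Conv2D.init(hidden, 1, 3, rng, zero=True),
        }
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray):
        acts = [x]
        pre = []
        h = x
        for name in ["conv1", "conv2", "conv3", "conv4", "conv5"]:
            z = self.layers[name](h)
            pre.append(z)
            h = np.maximum(z, 0.0)
            acts.append(h)
        y = self.layers["conv6"](h) + x
        return y, (acts, pre)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        acts, pre = cache
        grads = {}
        d, dw, db = conv2d_backward(dy, acts[5], self.layers["conv6"].weight)
        grads["conv6.weight"], grads["conv6.bias"] = dw, db
        for idx, name in zip(range(4, -1, -1),
                             ["conv5", "conv4", "conv3", "conv2", "conv1"]):
            d = d * (pre[idx] > 0)
            d, dw, db = conv2d_backward(d, acts[idx], self.layers[name].weight)
            grads[name + ".weight"], grads[name + ".bias"] = dw, db
        self.grads = grads
        return d + dy  # skip connection


@dataclass
class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    params: List[np.ndarray]
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: List[np.ndarray] = field(default_factory=list)
    v: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in self.params]
            self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its (sub)gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad
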