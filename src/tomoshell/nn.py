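"""A compact NumPy implementation of a 3D dense-block convolutional network.

The architecture follows the DenseNet pattern: a stem convolution, a stack of
dense blocks in which every layer (BN → ReLU → 3×3×3 conv) receives the
concatenation of all earlier feature maps, transition layers (BN → ReLU →
1×1×1 conv with channel compression, then 2× average pooling) between blocks,
and a BN → ReLU → global-average-pool → linear head.

Forward and backward passes are written explicitly (im2col convolutions with
analytic gradients), which keeps the training loop dependency-free, fully
deterministic under a seed, and small enough to train on single-cell volumes
on one CPU.  Batch statistics are exact (no momentum tricks beyond standard
running averages for inference).

All tensors are float32 in layout ``(N, C, D, H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Dense-block network hyperparameters.

    The desk-scale default (8 dense layers over 4 blocks, growth 4) trains in
    minutes on a CPU; a full-scale 82-layer configuration is expressible by
    raising ``total_layers`` and ``growth``.
    """

    n_blocks: int = 4
    total_layers: int = 8
    growth: int = 4
    compression: float = 0.5
    stem_channels: int = 8
    n_classes: int = 2
    task: str = "diagnosis"  # diagnosis (T1 vs H) or prognosis (T1 surv vs non-surv)

    def __post_init__(self) -> None:
        if self.total_layers % self.n_blocks != 0:
            raise ValueError(
                f"total_layers={self.total_layers} not divisible by "
                f"n_blocks={self.n_blocks}"
            )
        if not (0 < self.compression <= 1):
            raise ValueError("compression must lie in (0, 1]")
        if self.task not in ("diagnosis", "prognosis"):
            raise ValueError("task must be 'diagnosis' or 'prognosis'")

    @property
    def layers_per_block(self) -> int:
        return self.total_layers // self.n_blocks


class Conv3d:
    """Stride-1 'same' 3D convolution via im2col; odd kernel sizes only."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c = x.shape[:2]
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        # (N, C, D, H, W, k, k, k) -> (N*D*H*W, C*k^3)
        win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        return np.ascontiguousarray(win).reshape(-1, c * k**3)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols  # kept in eval mode too: saliency backprops after inference
        n, _, d, h, w = x.shape
        out = cols @ self.W.T + self.b
        return out.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._x_shape
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        self.dW[...] = dflat.T @ self._cols
        self.db[...] = dflat.sum(axis=0)
        # dx = full correlation of dout with spatially flipped kernels
        k = self.k
        w4 = self.W.reshape(self.c_out, self.c_in, k, k, k)
        w_flip = w4[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        wt = np.ascontiguousarray(w_flip).reshape(self.c_in, self.c_out * k**3)
        tmp = Conv3d.__new__(Conv3d)
        tmp.c_in, tmp.c_out, tmp.k = self.c_out, self.c_in, k
        cols_d = Conv3d._im2col(tmp, dout.astype(F32))
        dx = cols_d @ wt.T
        self._cols = None
        return dx.reshape(n, d, h, w, self.c_in).transpose(0, 4, 1, 2, 3)


class BatchNorm3d:
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(ivar)
        self._cache = (xhat, ivar, train, x.shape)
        return self._bc(self.gamma) * xhat + self._bc(self.beta)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, train, shape = self._cache
        axes = (0, 2, 3, 4)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self._bc(self.gamma * ivar)
        if not train:
            return dout * g
        m = dout.size / dout.shape[1]
        dxhat = dout * self._bc(self.gamma)
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * self._bc(ivar)
        return dx.astype(F32)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool3d:
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.f = factor
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f = self.f
        n, c, d, h, w = x.shape
        if d % f or h % f or w % f:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {f}")
        self._shape = x.shape
        return x.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(axis=(3, 5, 7))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f = self.f
        up = dout.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
        return (up / f**3).astype(F32)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class DenseBlock:
    """L dense layers; each sees the concatenation of all earlier features."""

    def __init__(self, c_in: int, n_layers: int, growth: int, rng: np.random.Generator):
        self.layers = []
        c = c_in
        for _ in range(n_layers):
            self.layers.append(
                Sequential(BatchNorm3d(c), ReLU(), Conv3d(c, growth, 3, rng))
            )
            c += growth
        self.c_in, self.c_out, self.growth = c_in, c, growth

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=True):
        feats = [x]
        for layer in self.layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1), train))
        self.out = np.concatenate(feats, axis=1)
        return self.out

    def backward(self, dout):
        g = self.growth
        splits = [self.c_in] + [g] * len(self.layers)
        bounds = np.cumsum([0] + splits)
        grads = [
            dout[:, bounds[i] : bounds[i + 1]].copy() for i in range(len(splits))
        ]
        for i in reversed(range(len(self.layers))):
            din = self.layers[i].backward(grads[i + 1])
            for j in range(i + 1):
                grads[j] += din[:, bounds[j] : bounds[j + 1]]
        return grads[0]


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, d, h, w = self._shape
        return (
            np.broadcast_to(dout[:, :, None, None, None], self._shape) / (d * h * w)
        ).astype(F32)


class Linear:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / c_in), (c_out, c_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


class DenseNet3D:
    """Dense-block classifier over ``(N, 1, D, H, W)`` volumes.

    Spatial extents must be divisible by ``2 ** n_blocks`` (one stem pool plus
    a transition pool after each non-final block).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.stem_channels
        self.stem = Sequential(Conv3d(1, c, 3, rng), AvgPool3d(2))
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Sequential] = []
        for b in range(config.n_blocks):
            block = DenseBlock(c, config.layers_per_block, config.growth, rng)
            self.blocks.append(block)
            c = block.c_out
            if b < config.n_blocks - 1:
                c_out = max(int(np.floor(c * config.compression)), 1)
                self.transitions.append(
                    Sequential(
                        BatchNorm3d(c), ReLU(), Conv3d(c, c_out, 1, rng), AvgPool3d(2)
                    )
                )
                c = c_out
        self.head = Sequential(BatchNorm3d(c), ReLU(), GlobalAvgPool())
        self.fc = Linear(c, config.n_classes, rng)

    # --- parameter plumbing -------------------------------------------------
    def parameters(self):
        params = list(self.stem.parameters())
        for b, block in enumerate(self.blocks):
            params += block.parameters()
            if b < len(self.transitions):
                params += self.transitions[b].parameters()
        params += self.head.parameters()
        params += self.fc.parameters()
        return params

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.parameters()]
        for bn in self._batchnorms():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (p, _), s in zip(params, state[: len(params)]):
            p[...] = s
        rest = state[len(params) :]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self):
        bns = []

        def collect(obj):
            if isinstance(obj, BatchNorm3d):
                bns.append(obj)
            elif isinstance(obj, Sequential):
                for l in obj.layers:
                    collect(l)
            elif isinstance(obj, DenseBlock):
                for l in obj.layers:
                    collect(l)

        collect(self.stem)
        for b, block in enumerate(self.blocks):
            collect(block)
            if b < len(self.transitions):
                collect(self.transitions[b])
        collect(self.head)
        return bns

    # --- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 4:
            x = x[:, None]
        h = self.stem.forward(x, train)
        for b, block in enumerate(self.blocks):
            h = block.forward(h, train)
            if b < len(self.transitions):
                h = self.transitions[b].forward(h, train)
        h = self.head.forward(h, train)
        return self.fc.forward(h, train)

    def backward(self, dlogits: np.ndarray):
        d = self.fc.backward(dlogits)
        d = self.head.backward(d)
        for b in reversed(range(len(self.blocks))):
            d = self.blocks[b].backward(d)
            if b > 0:
                d = self.transitions[b - 1].backward(d)
        return self.stem.backward(d)

    def backward_to_block(self, dlogits: np.ndarray, block_idx: int) -> np.ndarray:
        """Gradient of the loss w.r.t. the output of dense block ``block_idx``."""
        n = len(self.blocks)
        block_idx = block_idx % n
        d = self.fc.backward(dlogits)
        d = self.head.backward(d)
        for b in reversed(range(block_idx + 1, n)):
            d = self.blocks[b].backward(d)
            d = self.transitions[b - 1].backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax class probabilities, shape (N, n_classes)."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 4:
            x = x[:, None]
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = len(labels)
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, parameters, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.parameters = parameters
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in parameters]

    def step(self) -> None:
        for (p, g), v in zip(self.parameters, self.velocity):
            grad = g if self.weight_decay == 0 else g + self.weight_decay * p
            v *= self.momentum
            v -= self.lr * grad
            p += v


def cosine_annealing_lr(epoch: int, lr0: float, period: int) -> float:
    """Cosine-annealed learning rate with restart period ``period`` epochs."""
    t = epoch % period
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * t / period))


def grad_cam(
    net: DenseNet3D, volume: np.ndarray, class_idx: int, block: int = -1
) -> np.ndarray:
    """Gradient-weighted class activation map over the input spatial shape.

    Backpropagates the target-class logit to the feature maps of dense block
    ``block`` (last by default; earlier blocks give finer spatial
    resolution), weights each channel by its spatially averaged gradient,
    rectifies the weighted sum, trilinearly upsamples to the input shape, and
    max-normalizes to 1.  A constant input returns an all-zero map by
    convention (no spatial evidence to localize).
    """
    from scipy.ndimage import zoom

    x = np.asarray(volume, dtype=F32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim == 4:
        x = x[:, None]
    spatial = x.shape[2:]
    if np.ptp(x) == 0:
        return np.zeros(spatial, dtype=F32)
    logits = net.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[:, class_idx] = 1.0
    d_feats = net.backward_to_block(dlogits, block)
    feats = net.blocks[block].out  # (1, C, d, h, w)
    weights = d_feats.mean(axis=(2, 3, 4))  # (1, C)
    cam = np.maximum((weights[:, :, None, None, None] * feats).sum(axis=1), 0.0)[0]
    factors = [s / c for s, c in zip(spatial, cam.shape)]
    cam_up = zoom(cam, factors, order=1)
    # zoom can be off by one voxel on awkward ratios; pad/crop defensively
    pads = [(0, max(0, s - c)) for s, c in zip(spatial, cam_up.shape)]
    cam_up = np.pad(cam_up, pads)[: spatial[0], : spatial[1], : spatial[2]]
    peak = cam_up.max()
    if peak > 0:
        cam_up = cam_up / peak
    return cam_up.astype(F32)
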