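"""U-Net style encoder–decoder segmentation networks.

The topology follows the fixed nnU-Net-flavoured design used for both tasks:
four encoder blocks of double convolution (3×3 conv → instance norm → leaky
ReLU, twice) followed by 2×2 max-pooling, channels growing 32→64→128→256, a
512-channel bottleneck (64×64×512 for a 1024×1024 input), and a mirrored
decoder with 2×2 transposed-convolution upsampling and skip-connection
concatenation.  The vessel variant ends in a 5-class head, the lobule
variant in a 2-class head; the two differ only in that head.

Layers are implemented directly on NumPy with analytic forward/backward
passes (im2col convolutions), which keeps the package self-contained and is
fast enough for the desk-scale models exercised here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .wsi_patching import SIZE_DIVISOR, ClassPalette, LabelMask

__all__ = ["UNetConfig", "UNet", "build_model", "predict_labels",
           "save_checkpoint", "load_checkpoint"]

_LEAK = 0.01
_EPS = 1e-5


@dataclass(frozen=True)
class UNetConfig:
    """Network topology; the channel sequence is ``base_channels · 2^i``."""

    in_channels: int = 3
    base_channels: int = 32
    depth: int = 4
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid UNet configuration")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.depth

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** i for i in range(self.depth))


# ---------------------------------------------------------------------------
# layers (float32, NCHW)
# ---------------------------------------------------------------------------


class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}


class _Conv(_Layer):
    """3×3 (or 1×1) same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.pad = k, k // 2
        fan_in = cin * k * k
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        y = cols @ self.params["W"].T + self.params["b"]
        self._cols, self._xshape = cols, x.shape
        return np.ascontiguousarray(
            y.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._xshape
        k, p = self.k, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(B * H * W, self.cout)
        self.grads["W"] = (dyf.T @ self._cols).astype(np.float32)
        self.grads["b"] = dyf.sum(axis=0).astype(np.float32)
        dcols = (dyf @ self.params["W"]).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        del self._cols
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class _InstanceNorm(_Layer):
    """Per-sample, per-channel normalization over H×W with affine scale/shift."""

    def __init__(self, c: int):
        super().__init__()
        self.params["g"] = np.ones(c, dtype=np.float32)
        self.params["b"] = np.zeros(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mu) * self._inv
        return self.params["g"][None, :, None, None] * self._xhat + \
            self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["g"] = (dy * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dxhat = dy * self.params["g"][None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        del self._xhat, self._inv
        return dx.astype(np.float32)


class _LeakyReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, _LEAK * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._neg, _LEAK * dy, dy)
        del self._neg
        return out


class _MaxPool2(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        d = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(d, self._arg[..., None], dy[..., None], axis=-1)
        d = d.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(B, C, H, W)


class _UpConv(_Layer):
    """2×2 stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2)
        ).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        y = np.einsum("bihw,iokl->bohkwl", x, self.params["W"], optimize=True)
        y = y.reshape(B, -1, 2 * H, 2 * W)
        self._x = x
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, O, H2, W2 = dy.shape
        dyr = dy.reshape(B, O, H2 // 2, 2, W2 // 2, 2)
        self.grads["W"] = np.einsum(
            "bihw,bohkwl->iokl", self._x, dyr, optimize=True
        ).astype(np.float32)
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dx = np.einsum("bohkwl,iokl->bihw", dyr, self.params["W"], optimize=True)
        del self._x
        return dx.astype(np.float32)


class _DoubleConv(_Layer):
    """(3×3 conv → instance norm → leaky ReLU) × 2, padding 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            _Conv(cin, cout, 3, rng), _InstanceNorm(cout), _LeakyReLU(),
            _Conv(cout, cout, 3, rng), _InstanceNorm(cout), _LeakyReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class UNet:
    """Encoder–decoder segmentation network with skip connections."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.encoder_channels
        self.enc = []
        cin = config.in_channels
        for c in ch:
            self.enc.append(_DoubleConv(cin, c, rng))
            cin = c
        self.pools = [_MaxPool2() for _ in ch]
        self.bottleneck = _DoubleConv(ch[-1], config.bottleneck_channels, rng)
        self.ups, self.dec = [], []
        cin = config.bottleneck_channels
        for c in reversed(ch):
            self.ups.append(_UpConv(cin, c, rng))
            self.dec.append(_DoubleConv(2 * c, c, rng))
            cin = c
        self.head = _Conv(ch[0], config.n_classes, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _modules(self) -> list[_Layer]:
        mods: list[_Layer] = []
        for dc in [*self.enc, self.bottleneck, *self.dec]:
            mods.extend(dc.layers)
        mods.extend(self.ups)
        mods.append(self.head)
        return mods

    def parameters(self) -> list[tuple[_Layer, str]]:
        return [(m, k) for m in self._modules() for k in m.params]

    def n_parameters(self, include_head: bool = True) -> int:
        total = sum(m.params[k].size for m, k in self.parameters())
        if not include_head:
            total -= sum(v.size for v in self.head.params.values())
        return total

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": m.params[k]
                for i, m in enumerate(self._modules()) for k in m.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules()):
            for k in m.params:
                m.params[k] = state[f"{i}.{k}"].astype(np.float32).copy()

    # -- forward / backward ------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, H, W) input, "
                f"got {x.shape}"
            )
        H, W = x.shape[2:]
        if H % SIZE_DIVISOR or W % SIZE_DIVISOR:
            raise ValueError(f"input size {H}×{W} not divisible by {SIZE_DIVISOR}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 3, H, W) image batch → (B, n_classes, H, W) score maps."""
        self._check_input(x)
        x = x.astype(np.float32)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dscores: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the score maps through the net."""
        dx = self.head.backward(dscores.astype(np.float32))
        dskips = []
        for up, dec, c in zip(reversed(self.ups), reversed(self.dec),
                              reversed(self._skip_channels)):
            dcat = dec.backward(dx)
            dskips.append(dcat[:, :c])
            dx = up.backward(dcat[:, c:])
        dx = self.bottleneck.backward(dx)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dx = pool.backward(dx)
            dx = enc.backward(dx + dskip)

    __call__ = forward


def build_model(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialized network from a topology config."""
    return UNet(config, seed=seed)


def image_to_input(image: np.ndarray) -> np.ndarray:
    """H×W×3 uint8 image → (1, 3, H, W) float32 batch scaled to [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ValueError("expected an H×W×C image")
    return (arr.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]


def predict_labels(model: UNet, image: np.ndarray, palette: ClassPalette,
                   pixel_size_um: float) -> LabelMask:
    """Per-pixel argmax segmentation (ties break toward the lowest label)."""
    if image.shape[2] != model.config.in_channels:
        raise ValueError(
            f"image has {image.shape[2]} channels, model expects "
            f"{model.config.in_channels}"
        )
    if palette.n_classes != model.config.n_classes:
        raise ValueError("palette size does not match the model head")
    scores = model.forward(image_to_input(image))[0]
    return LabelMask(scores.argmax(axis=0).astype(np.uint8), palette,
                     pixel_size_um)


def save_checkpoint(path: str | Path, model: UNet) -> None:
    """Save weights with the topology config embedded."""
    path = Path(path)
    np.savez_compressed(path, __config__=json.dumps(asdict(model.config)),
                        **model.state_dict())


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(Path(path), allow_pickle=False) as data:
        config = UNetConfig(**json.loads(str(data["__config__"])))
        model = UNet(config)
        model.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"}
        )
    return model
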