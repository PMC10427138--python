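"""U-Net encoder–decoder for binary glottis segmentation.

Canonical layout: per level two 3x3 convolutions with ReLU, 2x2 max
pooling on the way down, nearest-neighbour upsampling + 3x3 convolution on
the way up, skip concatenation from encoder to decoder, channel count
doubling per level, and a final 1x1 convolution with a sigmoid producing a
per-pixel glottis probability.  ``micro`` (depth 3, 8 base channels) trains
on a CPU in minutes and is the default for tests and synthetic studies;
``full`` (depth 5, 32 base channels) is the production scale.

Implemented on the numpy layers in :mod:`glottiseg.nn`; forward and
backward passes are exact and deterministic under the init seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, MaxPool2x2, ReLU, UpsampleNearest2x, sigmoid

__all__ = ["UNetSpec", "UNet", "build_unet", "predict_mask", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters; input dims must divide by 2**depth."""

    depth: int = 3
    base_channels: int = 8
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (gray) or 3 (RGB)")

    @classmethod
    def micro(cls, in_channels: int = 1) -> "UNetSpec":
        return cls(depth=3, base_channels=8, in_channels=in_channels)

    @classmethod
    def full(cls, in_channels: int = 1) -> "UNetSpec":
        return cls(depth=5, base_channels=32, in_channels=in_channels)


class _ConvBlock:
    """Two 3x3 conv + ReLU pairs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1, self.r1 = Conv2d(cin, cout, 3, rng), ReLU()
        self.c2, self.r2 = Conv2d(cout, cout, 3, rng), ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d: np.ndarray) -> np.ndarray:
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def convs(self) -> list[Conv2d]:
        return [self.c1, self.c2]


class UNet:
    def __init__(self, spec: UNetSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 185]))
        d, c = spec.depth, spec.base_channels
        self.enc: list[_ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        cin = spec.in_channels
        for i in range(d):
            self.enc.append(_ConvBlock(cin, c * 2**i, rng))
            self.pools.append(MaxPool2x2())
            cin = c * 2**i
        self.bottom = _ConvBlock(cin, c * 2**d, rng)
        self.ups: list[UpsampleNearest2x] = []
        self.upconvs: list[Conv2d] = []
        self.uprelus: list[ReLU] = []
        self.dec: list[_ConvBlock] = []
        for i in reversed(range(d)):
            ch = c * 2 ** (i + 1)
            self.ups.append(UpsampleNearest2x())
            self.upconvs.append(Conv2d(ch, ch // 2, 3, rng))
            self.uprelus.append(ReLU())
            self.dec.append(_ConvBlock(ch, ch // 2, rng))
        self.head = Conv2d(c, 1, 1, rng)
        # background-prior bias: the glottis covers a small image fraction,
        # so start the sigmoid output low instead of at 0.5
        self.head.b[...] = -2.0

    # ---- passes ----

    def _check_dims(self, h: int, w: int) -> None:
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2**depth = {div}; pad or resize first"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, C) float32 in [0, 1] -> probabilities (N, H, W)."""
        if x.ndim == 3:
            x = x[..., None]
        self._check_dims(x.shape[1], x.shape[2])
        x = x.astype(np.float32, copy=False)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottom.forward(x)
        self._skip_ch = []
        for up, uc, ur, blk, skip in zip(self.ups, self.upconvs, self.uprelus, self.dec, reversed(skips)):
            x = ur.forward(uc.forward(up.forward(x)))
            self._skip_ch.append(skip.shape[-1])
            x = blk.forward(np.concatenate([skip, x], axis=-1))
        logits = self.head.forward(x)[..., 0]
        self._prob = sigmoid(logits)
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backprop from dL/d(probability); populates every layer's grads."""
        p = self._prob
        dlogits = (dprob * p * (1.0 - p)).astype(np.float32)
        d = self.head.backward(dlogits[..., None])
        dskips = []
        for blk, ur, uc, up, sch in zip(
            reversed(self.dec), reversed(self.uprelus), reversed(self.upconvs),
            reversed(self.ups), reversed(self._skip_ch),
        ):
            d = blk.backward(d)
            dskip, d = d[..., :sch], d[..., sch:]
            dskips.append(dskip)
            d = up.backward(uc.backward(ur.backward(d)))
        d = self.bottom.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = blk.backward(pool.backward(d) + dskip)

    # ---- parameters ----

    def _convs(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for blk in self.enc:
            convs += blk.convs()
        convs += self.bottom.convs()
        for uc, blk in zip(self.upconvs, self.dec):
            convs.append(uc)
            convs += blk.convs()
        convs.append(self.head)
        return convs

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for i, conv in enumerate(self._convs()):
            for name, p, g in conv.params():
                out.append((f"conv{i}.{name}", p, g))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.params()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.params():
            src = state[name]
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {p.shape}")
            p[...] = src

    def copy(self) -> "UNet":
        clone = UNet(self.spec, self.seed)
        clone.load_state(self.state_arrays())
        return clone


def build_unet(spec: UNetSpec, seed: int) -> UNet:
    """Randomly initialize a U-Net; identical seed gives identical weights."""
    return UNet(spec, seed)


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize the model's probability map at ``threshold``.

    `image` is a single frame, float in [0, 1] or uint8 in [0, 255].
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    prob = model.forward(img[None, ...])[0]
    return (prob >= threshold).astype(np.uint8)


@dataclass
class ModelCheckpoint:
    """Serialized weights + architecture + training provenance."""

    spec: UNetSpec
    state: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def to_model(self, seed: int = 0) -> UNet:
        model = UNet(self.spec, seed)
        model.load_state(self.state)
        return model

    @classmethod
    def from_model(cls, model: UNet, provenance: dict | None = None) -> "ModelCheckpoint":
        return cls(spec=model.spec, state=model.state_arrays(), provenance=provenance or {})


def save_checkpoint(ckpt: ModelCheckpoint, path: str | Path) -> None:
    meta = json.dumps({"spec": asdict(ckpt.spec), "provenance": ckpt.provenance})
    np.savez(Path(path), __meta__=np.array(meta), **ckpt.state)


def load_checkpoint(path: str | Path) -> ModelCheckpoint:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelCheckpoint(spec=UNetSpec(**meta["spec"]), state=state, provenance=meta["provenance"])
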