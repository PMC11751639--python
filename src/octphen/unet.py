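"""Trainable U-Net boundary segmentation (encoder-decoder with skip connections).

A contracting path of double 3x3 convolutions with 2x2 max pooling extracts
features; an expansive path of nearest-neighbour upsampling, convolution and
skip concatenation localises the retinal band; a 1-channel output conv gives
per-pixel logits trained with binary cross-entropy (Adam).  Runs on the numpy
engine in :mod:`octphen.nn`; training is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .thickness import SegmentationMask, postprocess_mask

__all__ = ["UNet", "train_unet"]


class _DoubleConv:
    def __init__(self, c_in, c_out, rng):
        self.c1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(c_out, c_out, 3, rng)
        self.r2 = nn.ReLU()

    def layers(self):
        return [self.c1, self.c2]

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))


class UNet:
    """U-Net over (H, W) grayscale inputs; H and W must be divisible by 2**depth.

    ``depth`` downsampling stages with ``base`` channels doubled per stage.
    """

    def __init__(self, depth: int = 4, base: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth, self.base, self.seed = depth, base, seed
        self.enc = []
        c_in = 1
        for d in range(depth):
            c_out = base * 2**d
            self.enc.append(_DoubleConv(c_in, c_out, rng))
            c_in = c_out
        self.pools = [nn.MaxPool2() for _ in range(depth)]
        self.bottom = _DoubleConv(c_in, c_in * 2, rng)
        self.ups = []
        self.dec = []
        c = c_in * 2
        for d in reversed(range(depth)):
            c_skip = base * 2**d
            self.ups.append((nn.Upsample2(), nn.Conv2d(c, c_skip, 3, rng), nn.ReLU()))
            self.dec.append(_DoubleConv(2 * c_skip, c_skip, rng))
            c = c_skip
        self.out = nn.Conv2d(base, 1, 1, rng)
        self.loss_history: list[float] = []

    def _all_layers(self):
        layers = []
        for blk in self.enc:
            layers += blk.layers()
        layers += self.bottom.layers()
        for _, conv, _ in self.ups:
            layers.append(conv)
        for blk in self.dec:
            layers += blk.layers()
        layers.append(self.out)
        return layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) in [0, 1] -> per-pixel logits (N, H, W)."""
        h = x[:, None, :, :].astype(np.float64)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottom.forward(h)
        self._split = []
        for (up, conv, relu), blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = relu.forward(conv.forward(up.forward(h)))
            self._split.append(skip.shape[1])
            h = blk.forward(np.concatenate([skip, h], axis=1))
        return self.out.forward(h)[:, 0, :, :]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out.backward(dlogits[:, None, :, :])
        dskips = []
        for (up, conv, relu), blk, cs in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._split)
        ):
            d = blk.backward(d)
            dskip, d = d[:, :cs], d[:, cs:]
            dskips.append(dskip)
            d = up.backward(conv.backward(relu.backward(d)))
        d = self.bottom.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = blk.backward(pool.backward(d) + dskip)

    # -- inference ---------------------------------------------------------- #

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, float)
        if images.ndim == 2:
            images = images[None]
        logits = self.forward(images)
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))

    def segment(self, image: np.ndarray) -> SegmentationMask:
        """Segment one B-scan: probability > 0.5, then per-column longest run."""
        p = self.predict_proba(image[None])[0]
        return postprocess_mask(p > 0.5)


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    epochs: int = 50,
    seed: int = 0,
    depth: int = 4,
    base: int = 16,
    lr: float = 1e-3,
    batch_size: int = 8,
) -> UNet:
    """Train a U-Net on labeled (image, mask) pairs with Adam + BCE.

    ``images``/``masks``: (n, H, W) arrays, images in [0, 1], masks binary.
    Deterministic given ``seed``; raises on non-finite loss.
    """
    images = np.asarray(images, float)
    masks = np.asarray(masks, float)
    if images.shape[0] < 1 or images.shape != masks.shape:
        raise ValueError("need matching (n, H, W) image and mask stacks")
    h, w = images.shape[1:]
    if h % 2**depth or w % 2**depth:
        raise ValueError(f"image dims must be divisible by 2**depth = {2**depth}")
    model = UNet(depth=depth, base=base, seed=seed)
    opt = nn.Adam(model._all_layers(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = images.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            logits = model.forward(images[idx])
            loss, dlogits = nn.bce_with_logits(logits, masks[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {len(model.loss_history)}"
                )
            model.backward(dlogits)
            opt.step()
            total += loss * idx.size
        model.loss_history.append(total / n)
    return model
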