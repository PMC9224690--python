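"""The modified 18-layer residual classifier.

Trunk: the canonical 18-layer residual architecture (7x7/stride-2 stem,
3x3 max pool, four stages of two residual units with two 3x3 convolutions
each, widths 64/128/256/512) adapted to a single input channel, producing
a 7x7x512 activation from a 224x224 greyscale input.

Head ("cam", default): the average pool and fully connected layers are
removed; the 7x7x512 activation is bilinearly upsampled to 86 x m x 512
(m = number of selected (ROI, modality) columns) and a 1x1 convolution
maps it to 86 x m x 2 class logits — one 2-way decision per feature-grid
cell.  Per-cell softmax over the 2 channels gives the class-activation
map used both for the patient-level score and for feature importance.

Head ("classic", ablation): standard global average pool + 2-way linear.
"""

from __future__ import annotations

import numpy as np

from ..features.names import N_FEATURES
from ..imaging import IMAGE_SIZE
from .layers import (
    BatchNorm2d,
    BilinearResize,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
)

TRUNK_OUT = (7, 7, 512)


class BasicBlock(Layer):
    """Residual unit: two 3x3 convolutions with identity (or 1x1) shortcut."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(3, 3, cin, cout, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(3, 3, cout, cout, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(1, 1, cin, cout, stride=stride, rng=rng)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None

    def params(self):
        mods = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2),
                ("bn2", self.bn2)]
        if self.down_conv is not None:
            mods += [("down_conv", self.down_conv), ("down_bn", self.down_bn)]
        return [(f"{m}.{n}", p) for m, mod in mods for n, p in mod.params()]

    def forward(self, x, train=True):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            identity = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            identity = x
        return self.relu2.forward(out + identity, train)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        d_main = self.bn2.backward(d)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        dx = self.conv1.backward(d_main)
        if self.down_conv is not None:
            dx = dx + self.down_conv.backward(self.down_bn.backward(d))
        else:
            dx = dx + d
        return dx


class CamModel:
    """18-layer residual trunk plus the upsampled activation head."""

    def __init__(self, m: int, head: str = "cam", seed: int = 0):
        if not 1 <= m <= 8:
            raise ValueError(f"m={m} outside the valid range 1..8")
        if head not in ("cam", "classic"):
            raise ValueError(f"unknown head {head!r}")
        self.m = m
        self.head = head
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(7, 7, 1, 64, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.relu = ReLU()
        self.maxpool = MaxPool2d(3, 2, 1)
        widths = (64, 128, 256, 512)
        self.stages = []
        cin = 64
        for si, w in enumerate(widths):
            stride = 1 if si == 0 else 2
            self.stages.append(
                [BasicBlock(cin, w, stride, rng), BasicBlock(w, w, 1, rng)]
            )
            cin = w
        if head == "cam":
            self.upsample = BilinearResize((7, 7), (N_FEATURES, m))
            # fan-in init: this conv is not followed by batch norm, so a
            # fan-out scale (2 outputs) would saturate the softmax at init
            self.head_conv = Conv2d(1, 1, 512, 2, bias=True, rng=rng, init="fan_in")
        else:
            self.avgpool = GlobalAvgPool()
            self.fc = Linear(512, 2, rng=rng)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[tuple[str, Param]]:
        mods = [("conv1", self.conv1), ("bn1", self.bn1)]
        for si, stage in enumerate(self.stages, start=1):
            for bi, block in enumerate(stage):
                mods.append((f"layer{si}.{bi}", block))
        if self.head == "cam":
            mods.append(("head_conv", self.head_conv))
        else:
            mods.append(("fc", self.fc))
        return [(f"{m}.{n}", p) for m, mod in mods for n, p in mod.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.params())

    @property
    def n_trunk_parameters(self) -> int:
        head = {"head_conv", "fc"}
        return sum(
            p.size for name, p in self.params() if name.split(".")[0] not in head
        )

    def zero_grad(self) -> None:
        for _, p in self.params():
            p.grad[:] = 0

    def layers(self):
        yield self.conv1
        yield self.bn1
        yield self.relu
        yield self.maxpool
        for stage in self.stages:
            for block in stage:
                yield block.conv1
                yield block.bn1
                yield block.relu1
                yield block.conv2
                yield block.bn2
                yield block.relu2
                if block.down_conv is not None:
                    yield block.down_conv
                    yield block.down_bn
        if self.head == "cam":
            yield self.upsample
            yield self.head_conv
        else:
            yield self.avgpool
            yield self.fc

    def batchnorm_layers(self):
        return (l for l in self.layers() if isinstance(l, BatchNorm2d))

    def clear_caches(self) -> None:
        for layer in self.layers():
            for attr in ("_cache", "_mask", "_x", "_shape"):
                if hasattr(layer, attr):
                    setattr(layer, attr, None)

    # -- forward / backward -------------------------------------------------

    def forward_trunk(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"expected {IMAGE_SIZE}x{IMAGE_SIZE} input, got {x.shape[1:3]}"
            )
        out = self.conv1.forward(x.astype(np.float32), train)
        out = self.relu.forward(self.bn1.forward(out, train), train)
        out = self.maxpool.forward(out, train)
        for stage in self.stages:
            for block in stage:
                out = block.forward(out, train)
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits: (N, 86, m, 2) for the cam head, (N, 2) for classic."""
        feat = self.forward_trunk(x, train)
        assert feat.shape[1:] == TRUNK_OUT
        if self.head == "cam":
            up = self.upsample.forward(feat, train)
            return self.head_conv.forward(up, train)
        pooled = self.avgpool.forward(feat, train)
        return self.fc.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        if self.head == "cam":
            d = self.head_conv.backward(dlogits)
            d = self.upsample.backward(d)
        else:
            d = self.fc.backward(dlogits)
            d = self.avgpool.backward(d)
        for stage in reversed(self.stages):
            for block in reversed(stage):
                d = block.backward(d)
        d = self.maxpool.backward(d)
        d = self.bn1.backward(self.relu.backward(d))
        self.conv1.backward(d)

    # -- inference helpers ---------------------------------------------------

    def cell_probabilities(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Per-cell class probabilities (N, 86, m, 2), evaluation mode."""
        if self.head != "cam":
            raise ValueError("cell probabilities require the cam head")
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        outs = []
        for k in range(0, len(x), batch_size):
            logits = self.forward(x[k : k + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=axis, keepdims=True)).astype(np.float64)


def build_model(m: int, head: str = "cam", seed: int = 0) -> CamModel:
    """A freshly initialized model for an 86 x m feature grid."""
    return CamModel(m=m, head=head, seed=seed)
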