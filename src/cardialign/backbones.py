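"""Classifier backbones adapted to single-channel log-Mel spectrograms.

Input orientation is (B, 1, T, F): time is the image height, frequency the
width, and the band partition always slices the last axis.  Every backbone
ends in global average pooling, so variable-length (padded) batches map to
exactly two logits per sample.

``resnet18`` keeps the standard stem (7x7 kernel, stride 2, padding 3) with
a single input channel and a two-unit linear head.  ``mobilenetv2`` and
``densenet121`` receive the same single-channel stem adaptation.
``smallcnn`` is a three-block desk-scale CNN used as a test fixture — it is
small enough to train on a CPU in minutes and is never a stand-in for the
full-scale backbones in protocol claims.

All weights are randomly initialized from ``init_seed``; no pretraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import (Module, Conv2d, Linear, BatchNorm2d, ReLU, Sequential,
                       Tensor, global_avg_pool, max_pool2d, relu)
from .features import SpectrogramBatch

__all__ = ["BackboneSpec", "build_backbone", "penultimate_features",
           "save_checkpoint", "load_checkpoint", "BACKBONE_NAMES"]

BACKBONE_NAMES = ("smallcnn", "resnet18", "mobilenetv2", "densenet121")


@dataclass
class BackboneSpec:
    name: str = "smallcnn"
    in_channels: int = 1
    n_classes: int = 2
    init_seed: int = 0

    def __post_init__(self):
        if self.in_channels != 1:
            raise ValueError("spectrogram backbones take a single input channel")
        if self.n_classes != 2:
            raise ValueError("clinical outcome prediction is binary (2 classes)")


class _Backbone(Module):
    """Shared head contract: forward = fc(features(x))."""

    feature_dim: int

    def features(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))


class SmallCNN(_Backbone):
    """Three stride-2 conv blocks + global average pool + linear head."""

    feature_dim = 32

    def __init__(self, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.body = Sequential(
            Conv2d(1, 8, 3, rng, stride=2, padding=1), ReLU(),
            Conv2d(8, 16, 3, rng, stride=2, padding=1), ReLU(),
            Conv2d(16, 32, 3, rng, stride=2, padding=1), ReLU(),
        )
        self.fc = Linear(32, n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        return global_avg_pool(self.body(x))


class _BasicBlock(Module):
    def __init__(self, rng, cin, cout, stride=1):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, stride=1, padding=1, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(relu(self.bn1(self.conv1(x)))))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return relu(ad.add(out, identity))


class ResNet18(_Backbone):
    feature_dim = 512

    def __init__(self, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.conv1 = Conv2d(1, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = BatchNorm2d(64)
        blocks = []
        cin = 64
        for cout, stride in ((64, 1), (64, 1), (128, 2), (128, 1),
                             (256, 2), (256, 1), (512, 2), (512, 1)):
            blocks.append(_BasicBlock(rng, cin, cout, stride))
            cin = cout
        self.blocks = blocks
        self.fc = Linear(512, n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        x = max_pool2d(x, kernel=3, stride=2, padding=1)
        for b in self.blocks:
            x = b(x)
        return global_avg_pool(x)


def _relu6(x: Tensor) -> Tensor:
    return ad.sub(relu(x), relu(ad.sub(x, Tensor(6.0))))


class _InvertedResidual(Module):
    def __init__(self, rng, cin, cout, stride, expand):
        super().__init__()
        hidden = cin * expand
        self.use_res = stride == 1 and cin == cout
        self.expand = expand
        if expand != 1:
            self.pw = Conv2d(cin, hidden, 1, rng, bias=False)
            self.pw_bn = BatchNorm2d(hidden)
        self.dw = Conv2d(hidden, hidden, 3, rng, stride=stride, padding=1,
                         bias=False, depthwise=True)
        self.dw_bn = BatchNorm2d(hidden)
        self.proj = Conv2d(hidden, cout, 1, rng, bias=False)
        self.proj_bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.expand != 1:
            h = _relu6(self.pw_bn(self.pw(h)))
        h = _relu6(self.dw_bn(self.dw(h)))
        h = self.proj_bn(self.proj(h))
        return ad.add(h, x) if self.use_res else h


class MobileNetV2(_Backbone):
    feature_dim = 1280
    _cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
            (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]

    def __init__(self, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.stem = Conv2d(1, 32, 3, rng, stride=2, padding=1, bias=False)
        self.stem_bn = BatchNorm2d(32)
        blocks = []
        cin = 32
        for t, c, n, s in self._cfg:
            for i in range(n):
                blocks.append(_InvertedResidual(rng, cin, c, s if i == 0 else 1, t))
                cin = c
        self.blocks = blocks
        self.head = Conv2d(cin, 1280, 1, rng, bias=False)
        self.head_bn = BatchNorm2d(1280)
        self.fc = Linear(1280, n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        x = _relu6(self.stem_bn(self.stem(x)))
        for b in self.blocks:
            x = b(x)
        x = _relu6(self.head_bn(self.head(x)))
        return global_avg_pool(x)


class _DenseLayer(Module):
    def __init__(self, rng, cin, growth):
        super().__init__()
        self.bn1 = BatchNorm2d(cin)
        self.conv1 = Conv2d(cin, 4 * growth, 1, rng, bias=False)
        self.bn2 = BatchNorm2d(4 * growth)
        self.conv2 = Conv2d(4 * growth, growth, 3, rng, padding=1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(relu(self.bn1(x)))
        h = self.conv2(relu(self.bn2(h)))
        return ad.concat([x, h], axis=1)


class _Transition(Module):
    def __init__(self, rng, cin, cout):
        super().__init__()
        self.bn = BatchNorm2d(cin)
        self.conv = Conv2d(cin, cout, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return ad.avg_pool2d(self.conv(relu(self.bn(x))), 2)


class DenseNet121(_Backbone):
    feature_dim = 1024
    _block_cfg = (6, 12, 24, 16)
    _growth = 32

    def __init__(self, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.stem = Conv2d(1, 64, 7, rng, stride=2, padding=3, bias=False)
        self.stem_bn = BatchNorm2d(64)
        layers: list[Module] = []
        c = 64
        for bi, n in enumerate(self._block_cfg):
            for _ in range(n):
                layers.append(_DenseLayer(rng, c, self._growth))
                c += self._growth
            if bi != len(self._block_cfg) - 1:
                layers.append(_Transition(rng, c, c // 2))
                c //= 2
        self.layers = layers
        self.bn_final = BatchNorm2d(c)
        self.fc = Linear(c, n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        x = relu(self.stem_bn(self.stem(x)))
        x = max_pool2d(x, kernel=3, stride=2, padding=1)
        for layer in self.layers:
            x = layer(x)
        return global_avg_pool(relu(self.bn_final(x)))


_BUILDERS = {"smallcnn": SmallCNN, "resnet18": ResNet18,
             "mobilenetv2": MobileNetV2, "densenet121": DenseNet121}


def build_backbone(spec: BackboneSpec) -> _Backbone:
    """Construct a backbone with weights seeded from ``spec.init_seed``."""
    if spec.name not in _BUILDERS:
        raise ValueError(
            f"unknown backbone {spec.name!r}; valid names: {BACKBONE_NAMES}")
    rng = np.random.default_rng(spec.init_seed)
    model = _BUILDERS[spec.name](rng, spec.n_classes)
    model.spec = spec  # type: ignore[attr-defined]
    return model


def penultimate_features(model, batch: SpectrogramBatch | Tensor) -> np.ndarray:
    """Per-sample representation h before the final linear layer."""
    if not isinstance(model, _Backbone):
        raise TypeError("model does not expose a penultimate feature stage")
    X = batch if isinstance(batch, Tensor) else Tensor(batch.X)
    with ad.no_grad():
        return model.features(X).data


def save_checkpoint(model: _Backbone, path: str | Path,
                    run_config: dict | None = None):
    """Self-describing checkpoint: weights + backbone spec + run config."""
    meta = {"spec": asdict(model.spec), "run_config": run_config or {}}
    np.savez(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[_Backbone, dict]:
    data = np.load(str(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = build_backbone(BackboneSpec(**meta["spec"]))
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta.get("run_config", {})
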