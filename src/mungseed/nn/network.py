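"""Network specification and assembly.

A :class:`NetworkSpec` is an ordered list of bottleneck stages (expansion
factor t, output channels c, repeats n, first-repeat stride s) plus stem and
head widths. The stock configuration is the standard MobileNetV2 stage table
(stem 32 @ stride 2, seven bottleneck stages totalling 17 blocks, 1x1 head to
1280, global average pool, 1x1 conv classifier). ``variant='hp'`` builds the
same topology with DMS and ECA blocks inside every bottleneck and Mish in
place of ReLU6 everywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .blocks import ConvBNAct, InvertedResidual
from .core import Module
from .layers import AdaptiveAvgPool2d, Conv2d

__all__ = ["StageConfig", "NetworkSpec", "SeedClassifier", "build_network",
           "mobilenet_v2_spec", "small_spec"]


@dataclass(frozen=True)
class StageConfig:
    t: int  # expansion factor
    c: int  # output channels
    n: int  # bottleneck repeats
    s: int  # stride of the first repeat

    def __post_init__(self):
        if self.t < 1:
            raise ValueError(f"expansion factor must be >= 1, got {self.t}")
        if self.n < 1:
            raise ValueError(f"repeat count must be >= 1, got {self.n}")
        if self.s not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.s}")


# The stock MobileNetV2 stage table: 17 bottlenecks in 7 stages.
MOBILENET_V2_STAGES: tuple[StageConfig, ...] = (
    StageConfig(1, 16, 1, 1),
    StageConfig(6, 24, 2, 2),
    StageConfig(6, 32, 3, 2),
    StageConfig(6, 64, 4, 2),
    StageConfig(6, 96, 3, 1),
    StageConfig(6, 160, 3, 2),
    StageConfig(6, 320, 1, 1),
)


@dataclass(frozen=True)
class NetworkSpec:
    stages: tuple[StageConfig, ...]
    n_classes: int = 8
    variant: str = "baseline"  # 'baseline' (stock MobileNetV2) or 'hp'
    input_size: int = 224
    in_channels: int = 3
    stem_channels: int = 32
    head_channels: int = 1280
    dms_pooled_size: int = 5

    def __post_init__(self):
        if not self.stages:
            raise ValueError("stage list must not be empty")
        if self.variant not in ("baseline", "hp"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes < 1:
            raise ValueError("need at least one class")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        data = json.loads(text)
        data["stages"] = tuple(StageConfig(**s) for s in data["stages"])
        return cls(**data)


def mobilenet_v2_spec(n_classes: int = 8, variant: str = "baseline",
                      input_size: int = 224) -> NetworkSpec:
    """The full-size stage table with a k-class head."""
    return NetworkSpec(stages=MOBILENET_V2_STAGES, n_classes=n_classes,
                       variant=variant, input_size=input_size)


def small_spec(n_classes: int = 8, variant: str = "hp",
               input_size: int = 32) -> NetworkSpec:
    """A narrow three-stage preset for CPU-scale smoke training.

    Same block types and wiring as the full network (bottlenecks, DMS, ECA,
    Mish), scaled to train in minutes on one core at 32x32 input.
    """
    return NetworkSpec(
        stages=(StageConfig(1, 16, 1, 1), StageConfig(6, 24, 2, 2),
                StageConfig(6, 32, 2, 2)),
        n_classes=n_classes, variant=variant, input_size=input_size,
        stem_channels=16, head_channels=128,
    )


class SeedClassifier(Module):
    """Image classifier assembled from a :class:`NetworkSpec`.

    ``features`` is the stem convolution, the bottleneck sequence and the 1x1
    head convolution; a global average pool and a 1x1 convolution map the
    head features to class logits.
    """

    def __init__(self, spec: NetworkSpec, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        act = "mish" if spec.variant == "hp" else "relu6"
        features: list[Module] = [
            ConvBNAct(spec.in_channels, spec.stem_channels, 3, stride=2,
                      activation=act, rng=rng)
        ]
        c_in = spec.stem_channels
        for stage in spec.stages:
            for i in range(stage.n):
                stride = stage.s if i == 0 else 1
                features.append(InvertedResidual(
                    c_in, stage.c, stage.t, stride, variant=spec.variant,
                    dms_pooled_size=spec.dms_pooled_size, rng=rng))
                c_in = stage.c
        features.append(ConvBNAct(c_in, spec.head_channels, 1, activation=act, rng=rng))
        self.features = features
        self.pool = AdaptiveAvgPool2d(1)
        self.classifier = Conv2d(spec.head_channels, spec.n_classes, 1, bias=True, rng=rng)
        self._feature_outputs: list[np.ndarray] | None = None

    @property
    def n_bottlenecks(self) -> int:
        return len(self.features) - 2

    def forward(self, x, keep_features: bool = False):
        outputs = [] if keep_features else None
        for layer in self.features:
            x = layer.forward(x)
            if keep_features:
                outputs.append(x)
        self._feature_outputs = outputs
        x = self.pool.forward(x)
        x = self.classifier.forward(x)
        return x.reshape(x.shape[0], -1)  # (N, k) logits

    def backward(self, grad_logits, to_feature: int | None = None):
        """Backpropagate logit gradients.

        With ``to_feature`` set, stops early and returns the gradient with
        respect to the *output* of ``features[to_feature]``; otherwise
        propagates to the network input and returns that gradient.
        """
        g = grad_logits.reshape(grad_logits.shape + (1, 1))
        g = self.classifier.backward(g)
        g = self.pool.backward(g)
        last = -1 if to_feature is None else to_feature
        for i in range(len(self.features) - 1, last, -1):
            g = self.features[i].backward(g)
        return g


def build_network(spec: NetworkSpec, seed: int = 0) -> SeedClassifier:
    """Construct a freshly initialised classifier from a spec."""
    return SeedClassifier(spec, rng=np.random.default_rng(seed))
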