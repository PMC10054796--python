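"""Backbone registry for the attention pipeline.

Every backbone is a :class:`~fundcam.nn.Network` whose classification head
is global average pooling followed by a linear layer with one logit per
disease class (multi-label: independent sigmoids at prediction time).  The
default attention *target layer* is the activation of the last
convolutional block, whose K output maps are the ``A^k`` that Grad-CAM
weights and sums.

Registered backbones:

``tiny_cnn``
    Two conv/ReLU/pool blocks + GAP head.  Small enough that its analytic
    gradients are routinely cross-checked against finite differences in the
    test suite; the default for all desk-scale runs.
``vgg16`` / ``vgg19``
    The standard 13/16-conv-layer VGG stacks (3x3 kernels, 2x2 max pools)
    with the fully connected stack replaced by GAP, preserving spatial
    attribution.
``resnet50``
    The 50-layer bottleneck residual architecture (projection shortcuts,
    no batch normalisation — biases take its place in this engine).

Pretrained ImageNet weights are not shipped; requesting them raises.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, GlobalAvgPool, Linear, MaxPool2d, Network, ReLU, Residual

__all__ = [
    "BACKBONES",
    "UnknownBackboneError",
    "PretrainedWeightsUnavailableError",
    "build_backbone",
    "forward_with_features",
    "grad_score_wrt_features",
]


class UnknownBackboneError(KeyError):
    """Requested backbone name is not in the registry."""


class PretrainedWeightsUnavailableError(RuntimeError):
    """Pretrained weights were requested but none are shipped."""


def build_tiny_cnn(n_classes: int, input_size: tuple[int, int] = (32, 32),
                   channels: tuple[int, int] = (8, 16),
                   rng: np.random.Generator | None = None) -> Network:
    rng = rng or np.random.default_rng(0)
    c1, c2 = channels
    # no max pooling: GAP handles any spatial size, and keeping the head
    # path (GAP + linear) smooth makes feature-map gradients exactly
    # finite-difference checkable (max pooling is nondifferentiable at ties)
    blocks = [
        ("conv1", Conv2d(3, c1, 3, pad=1, rng=rng)),
        ("relu1", ReLU()),
        ("conv2", Conv2d(c1, c2, 3, pad=1, rng=rng)),
        ("relu2", ReLU()),
        ("gap", GlobalAvgPool()),
        ("fc", Linear(c2, n_classes, rng=rng)),
    ]
    return Network(blocks, target_layer="relu2", input_size=input_size,
                   n_classes=n_classes, name="tiny_cnn")


_VGG_CFGS = {
    "vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"],
    "vgg19": [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"],
}


def build_vgg(name: str, n_classes: int, input_size: tuple[int, int] = (224, 224),
              rng: np.random.Generator | None = None) -> Network:
    rng = rng or np.random.default_rng(0)
    blocks: list = []
    in_ch, ci, pi = 3, 0, 0
    last_relu = ""
    for item in _VGG_CFGS[name]:
        if item == "M":
            pi += 1
            blocks.append((f"pool{pi}", MaxPool2d(2)))
        else:
            ci += 1
            blocks.append((f"conv{ci}", Conv2d(in_ch, item, 3, pad=1, rng=rng)))
            last_relu = f"relu{ci}"
            blocks.append((last_relu, ReLU()))
            in_ch = item
    blocks.append(("gap", GlobalAvgPool()))
    blocks.append(("fc", Linear(in_ch, n_classes, rng=rng)))
    return Network(blocks, target_layer=last_relu, input_size=input_size,
                   n_classes=n_classes, name=name)


def _bottleneck(in_ch: int, mid: int, out_ch: int, stride: int,
                rng: np.random.Generator) -> Residual:
    body = [
        Conv2d(in_ch, mid, 1, rng=rng), ReLU(),
        Conv2d(mid, mid, 3, stride=stride, pad=1, rng=rng), ReLU(),
        Conv2d(mid, out_ch, 1, rng=rng),
    ]
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = [Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)]
    return Residual(body, shortcut)


def build_resnet50(n_classes: int, input_size: tuple[int, int] = (224, 224),
                   rng: np.random.Generator | None = None) -> Network:
    rng = rng or np.random.default_rng(0)
    blocks: list = [
        ("conv1", Conv2d(3, 64, 7, stride=2, pad=3, rng=rng)),
        ("relu1", ReLU()),
        ("pool1", MaxPool2d(3, stride=2, pad=1)),
    ]
    in_ch = 64
    stage_cfg = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
    last = ""
    for si, (mid, out_ch, reps, stride) in enumerate(stage_cfg, start=1):
        for ri in range(reps):
            last = f"res{si}_{ri + 1}"
            blocks.append((last, _bottleneck(in_ch, mid, out_ch,
                                             stride if ri == 0 else 1, rng)))
            in_ch = out_ch
    blocks.append(("gap", GlobalAvgPool()))
    blocks.append(("fc", Linear(in_ch, n_classes, rng=rng)))
    return Network(blocks, target_layer=last, input_size=input_size,
                   n_classes=n_classes, name="resnet50")


BACKBONES = {
    "tiny_cnn": build_tiny_cnn,
    "vgg16": lambda n_classes, input_size=(224, 224), rng=None: build_vgg("vgg16", n_classes, input_size, rng),
    "vgg19": lambda n_classes, input_size=(224, 224), rng=None: build_vgg("vgg19", n_classes, input_size, rng),
    "resnet50": build_resnet50,
}


def build_backbone(name: str, n_classes: int, input_size: tuple[int, int] | None = None,
                   pretrained: bool = False, seed: int = 0) -> Network:
    """Construct a registered backbone with freshly initialised weights."""
    if name not in BACKBONES:
        raise UnknownBackboneError(
            f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}")
    if pretrained:
        raise PretrainedWeightsUnavailableError(
            f"no pretrained weights are shipped for {name!r}")
    rng = np.random.default_rng(seed)
    kwargs = {"rng": rng}
    if input_size is not None:
        kwargs["input_size"] = tuple(input_size)
    return BACKBONES[name](n_classes, **kwargs)


def forward_with_features(model: Network, image: np.ndarray):
    """Feature maps ``A^k`` at the target layer plus class logits ``y^c``.

    Accepts one image ``(3, H, W)`` or a batch; single images return
    unbatched ``(K, W, H)`` features and ``(C,)`` scores.
    """
    single = np.asarray(image).ndim == 3
    feats, logits = model.forward_with_features(image)
    if single:
        return feats[0], logits[0]
    return feats, logits


def grad_score_wrt_features(model: Network, image: np.ndarray, class_index: int) -> np.ndarray:
    """Analytic gradient ``d y^c / d A^k`` at the target layer."""
    single = np.asarray(image).ndim == 3
    g = model.class_gradient(image, class_index, wrt="features")
    return g[0] if single else g
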