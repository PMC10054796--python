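"""A named-block feed-forward network with class-score gradient queries.

The network is an ordered list of ``(name, Layer)`` blocks ending in a
classification head (global average pooling + linear).  One block is
designated the *target layer*: its output is the stack of feature maps
``A^k`` that class-activation mapping operates on.  By convention this is
the activation of the last convolutional block.

Class scores are pre-sigmoid logits ``y^c`` (one independent score per
label; the multi-label head applies a sigmoid only at prediction time).
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer

__all__ = ["Network"]


class Network:
    def __init__(self, blocks: list[tuple[str, Layer]], target_layer: str,
                 input_size: tuple[int, int], n_classes: int, name: str = "net") -> None:
        names = [n for n, _ in blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        if target_layer not in names:
            raise ValueError(f"unknown target layer {target_layer!r}")
        self.blocks = blocks
        self.target_layer = target_layer
        self.input_size = tuple(input_size)
        self.n_classes = n_classes
        self.name = name
        self._outputs: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ forward
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Run a batch ``(N, 3, H, W)`` through all blocks; return logits ``(N, C)``."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[2:] != self.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != model input_size {self.input_size}")
        self._outputs = {"__input__": x}
        for name, layer in self.blocks:
            x = layer.forward(x)
            self._outputs[name] = x
        return x

    def forward_with_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(feature maps A^k at the target layer, logits)``."""
        logits = self.forward(x)
        return self._outputs[self.target_layer], logits

    def forward_from(self, block_name: str, features: np.ndarray) -> np.ndarray:
        """Recompute logits from a (possibly perturbed) copy of a block's output.

        Used by finite-difference checks of the feature-map gradients.
        """
        names = [n for n, _ in self.blocks]
        start = names.index(block_name) + 1
        x = features
        for name, layer in self.blocks[start:]:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        return 1.0 / (1.0 + np.exp(-logits))

    # ----------------------------------------------------------------- backward
    def backward(self, grad_logits: np.ndarray, upto: str | None = None,
                 guided: bool = False) -> np.ndarray:
        """Backpropagate ``d loss / d logits`` through the cached forward pass.

        Stops at (and returns the gradient of) the output of block ``upto``;
        with ``upto=None`` the gradient with respect to the input image is
        returned.  Parameter gradients accumulate along the way.
        """
        g = grad_logits
        names = [n for n, _ in self.blocks]
        stop = names.index(upto) if upto is not None else -1
        for i in range(len(self.blocks) - 1, stop, -1):
            g = self.blocks[i][1].backward(g, guided=guided)
        return g

    def class_gradient(self, x: np.ndarray, class_index: int, wrt: str = "features",
                       guided: bool = False) -> np.ndarray:
        """Gradient of the class logit ``y^c`` summed over the batch.

        ``wrt="features"`` returns ``d y^c / d A^k`` at the target layer
        (shape ``(N, K, W, H)``); ``wrt="input"`` returns the image-space
        gradient, optionally under the guided-backprop ReLU rule.
        """
        if not 0 <= class_index < self.n_classes:
            raise IndexError(f"class index {class_index} out of range [0, {self.n_classes})")
        logits = self.forward(x)
        seed = np.zeros_like(logits)
        seed[:, class_index] = 1.0
        self.zero_grad()
        upto = self.target_layer if wrt == "features" else None
        return self.backward(seed, upto=upto, guided=guided)

    # ---------------------------------------------------------------- parameters
    def layers(self):
        for _, block in self.blocks:
            yield from block.iter_layers()

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def parameters(self):
        """Yield ``(layer, key)`` handles for every trainable array."""
        for layer in self.layers():
            for key in layer.params:
                yield layer, key

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [layer.params[k].copy() for layer, k in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        handles = list(self.parameters())
        if len(state) != len(handles):
            raise ValueError("state length mismatch")
        for (layer, key), arr in zip(handles, state):
            if layer.params[key].shape != arr.shape:
                raise ValueError("state shape mismatch")
            layer.params[key] = arr.copy()

    def clone(self) -> "Network":
        return copy.deepcopy(self)
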