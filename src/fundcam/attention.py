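"""Grad-CAM, guided backpropagation and Guided-Grad-CAM attention maps.

Given a convolutional network with feature maps :math:`A^k` at a chosen
layer and a class logit :math:`y^c`, the class-activation machinery is

.. math::

    w^c_k = \\frac{1}{Z} \\sum_{i=1}^{W} \\sum_{j=1}^{H}
        \\frac{\\partial y^c}{\\partial A^k_{ij}}, \\qquad Z = W \\cdot H

    I^c_{\\text{Grad-CAM}} = \\mathrm{ReLU}\\Big(\\sum_k w^c_k A^k\\Big)

Guided backpropagation replaces every ReLU's backward rule so that, in
addition to the usual gating on positive forward activations, negative
incoming gradients are dropped; the resulting image-resolution saliency
multiplied elementwise with the (bilinearly upsampled) Grad-CAM map gives
Guided-Grad-CAM.  For multi-label images the per-class maps are combined
by a plain mean over the selected classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import Network

__all__ = [
    "GradCamMap",
    "gradcam_weights",
    "gradcam_map",
    "compute_gradcam",
    "guided_backprop",
    "guided_gradcam",
    "aggregate_maps",
    "attention_map_for_classes",
    "upsample_map",
]


@dataclass
class GradCamMap:
    values: np.ndarray  # W x H nonnegative, feature resolution
    class_index: int


def gradcam_weights(grads: np.ndarray) -> np.ndarray:
    """Channel weights ``w^c_k``: spatial mean of ``d y^c / d A^k``.

    ``grads`` is ``(K, W, H)``; the normaliser ``Z`` is the map area
    ``W*H``, making each weight a global average of its channel gradient.
    """
    grads = np.asarray(grads, dtype=np.float64)
    if grads.ndim != 3 or grads.size == 0:
        raise ValueError("expected a non-empty (K, W, H) gradient array")
    return grads.mean(axis=(1, 2))


def gradcam_map(features: np.ndarray, weights: np.ndarray,
                class_index: int = 0) -> GradCamMap:
    """ReLU of the ``w``-weighted channel sum of the feature maps."""
    features = np.asarray(features, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if features.ndim != 3 or weights.shape != (features.shape[0],):
        raise ValueError(
            f"weights length {weights.shape} must match K={features.shape[0]} channels")
    raw = np.tensordot(weights, features, axes=1)
    return GradCamMap(values=np.maximum(raw, 0.0), class_index=class_index)


def compute_gradcam(model: Network, image: np.ndarray, class_index: int) -> GradCamMap:
    """End-to-end Grad-CAM for one image and class at the target layer."""
    x = np.asarray(image)[None] if np.asarray(image).ndim == 3 else np.asarray(image)
    feats, _ = model.forward_with_features(x)
    grads = model.class_gradient(x, class_index, wrt="features")
    return gradcam_map(feats[0], gradcam_weights(grads[0]), class_index)


def guided_backprop(model: Network, image: np.ndarray, class_index: int,
                    reduce_channels: bool = False) -> np.ndarray:
    """Image-space gradient of ``y^c`` under the guided-ReLU backward rule.

    Returns a ``(3, H, W)`` array, or its channelwise max when
    ``reduce_channels`` is set (a single-channel intensity for masking).
    For models without ReLUs this is exactly the standard gradient.
    """
    x = np.asarray(image)[None] if np.asarray(image).ndim == 3 else np.asarray(image)
    g = model.class_gradient(x, class_index, wrt="input", guided=True)[0]
    return g.max(axis=0) if reduce_channels else g


def upsample_map(values: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling of a feature-resolution map to image resolution."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape == tuple(image_size):
        return values
    return resize(values, image_size, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def guided_gradcam(gbp: np.ndarray, cam: GradCamMap | np.ndarray,
                   image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Elementwise product of guided backprop and (upsampled) Grad-CAM."""
    gbp = np.asarray(gbp, dtype=np.float64)
    cam_values = cam.values if isinstance(cam, GradCamMap) else np.asarray(cam)
    target = tuple(image_size) if image_size is not None else gbp.shape[-2:]
    cam_up = upsample_map(cam_values, target)
    if gbp.shape[-2:] != cam_up.shape:
        raise ValueError(f"saliency {gbp.shape} and upsampled CAM {cam_up.shape} disagree")
    return gbp * cam_up


def aggregate_maps(maps: list[np.ndarray], class_subset: list[int] | None = None) -> np.ndarray:
    """Mean of per-class maps over a class subset (``Z`` = subset size)."""
    if class_subset is not None:
        maps = [maps[c] for c in class_subset]
    if not maps:
        raise ValueError("cannot aggregate an empty class subset")
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    return stack.mean(axis=0)


def attention_map_for_classes(model: Network, image: np.ndarray, classes: list[int],
                              source: str = "gradcam") -> np.ndarray:
    """Aggregate attention map over ``classes`` at image resolution.

    ``source='gradcam'`` upsamples each class's Grad-CAM map;
    ``source='guided_gradcam'`` multiplies it with guided backprop first.
    """
    if not classes:
        raise ValueError("need at least one class to build an attention map")
    image = np.asarray(image)
    img_size = image.shape[-2:] if image.ndim == 3 else image.shape[1:3]
    per_class = []
    for c in classes:
        cam = compute_gradcam(model, image, c)
        if source == "gradcam":
            per_class.append(upsample_map(cam.values, img_size))
        elif source == "guided_gradcam":
            gbp = guided_backprop(model, image, c, reduce_channels=True)
            per_class.append(guided_gradcam(gbp, cam, img_size))
        else:
            raise ValueError(f"unknown attention source {source!r}")
    return aggregate_maps(per_class)
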