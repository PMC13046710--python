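"""Grad-CAM saliency maps on the image branch.

For a target class ``c`` the class score (its logit) is
backpropagated to the activations ``A`` of the last 2-D convolution;
each channel's weight is the spatial mean of that gradient, and the
heatmap is the ReLU of the weighted channel sum:

    alpha_k = mean_{x,y} dS_c / dA_k(x, y)
    cam     = ReLU( sum_k alpha_k A_k )

The raw map lives on the last conv layer's grid; it is bilinearly
upsampled to the input resolution and max-normalized to [0, 1] when
nonzero.  Only the 2-D branch is inspected: the handcrafted-feature
branch has no spatial layout to visualize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn.layers import Conv2D
from .nn.model import SDNetModel

__all__ = ["GradCAMHeatmap", "grad_cam", "overlay_heatmap"]


@dataclass(frozen=True)
class GradCAMHeatmap:
    raw: np.ndarray         # map on the conv-layer grid
    upsampled: np.ndarray   # map at input resolution, in [0, 1]
    target_class: int


def grad_cam(model: SDNetModel, image: np.ndarray,
             features: np.ndarray | None, target_class: int) -> GradCAMHeatmap:
    """Saliency of ``target_class`` for one image (and feature vector)."""
    if model.branch2d is None:
        raise ValueError("Grad-CAM needs a model with a 2-D branch")
    k = model.config.num_classes
    if not 0 <= target_class < k:
        raise ValueError(f"target_class must lie in [0, {k})")

    imgs = np.asarray(image, dtype=np.float32)[None]
    feats = None
    if model.branch1d is not None:
        feats = np.asarray(features, dtype=np.float32)[None]

    # Forward in inference mode, capturing the last conv2d activation.
    layers = model.branch2d.layers
    conv_idx = max(i for i, l in enumerate(layers) if isinstance(l, Conv2D))
    x = imgs
    activation = None
    for i, layer in enumerate(layers):
        x = layer.forward(x, train=False)
        if i == conv_idx:
            activation = x
    branch2d_out = x

    outs = [branch2d_out]
    if model.branch1d is not None:
        outs.append(model.branch1d.forward(feats[:, :, None], train=False))
    fused = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
    model.head.forward(fused, train=False)

    # Backpropagate the class logit to the captured activation.
    dlogits = np.zeros((1, k), dtype=np.float32)
    dlogits[0, target_class] = 1.0
    dfused = model.head.backward(dlogits)
    grad = dfused[:, : model.flatten2d]
    for layer in reversed(layers[conv_idx + 1:]):
        grad = layer.backward(grad)

    a = activation[0]          # (h, w, C)
    g = grad[0]
    weights = g.mean(axis=(0, 1))
    cam = np.maximum((a * weights).sum(axis=-1), 0.0)

    up = resize(cam, imgs.shape[1:3], order=1, anti_aliasing=False,
                preserve_range=True)
    up = np.maximum(up, 0.0)
    if up.max() > 0:
        up = up / up.max()
    return GradCAMHeatmap(raw=cam, upsampled=up, target_class=target_class)


def overlay_heatmap(image: np.ndarray, heatmap: GradCAMHeatmap,
                    alpha: float = 0.5) -> np.ndarray:
    """Blend the heatmap (red channel) over an RGB image for export."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    hm = heatmap.upsampled
    color = np.stack([hm, 0.2 * hm, 1.0 - hm], axis=-1)
    return np.clip((1 - alpha) * img + alpha * color, 0.0, 1.0)
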