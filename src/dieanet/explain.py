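"""Gradient-weighted class activation mapping (Grad-CAM).

For a chosen convolutional stage, the gradient of the target-class logit is
averaged per channel into weights, the weighted channel sum of the
activations is rectified, upsampled to the input resolution and min–max
normalized to [0,1].  An all-zero map (e.g. a frozen head with zero
gradients) stays all-zero rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.transform import resize

from .autodiff import Tensor
from .zoo import StagedClassifier

__all__ = ["Heatmap", "grad_cam", "save_heatmap"]


@dataclass
class Heatmap:
    values: np.ndarray               # H×W in [0,1]
    overlay: np.ndarray              # H×W×3 uint8 composite
    target_layer: str
    target_class: int


def normalize_map(cam: np.ndarray) -> np.ndarray:
    """Min–max to [0,1]; idempotent; an all-constant map becomes all-zero."""
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def grad_cam(model: StagedClassifier, image: np.ndarray, target_class: int,
             target_layer: str | None = None) -> Heatmap:
    """Compute a Grad-CAM heatmap for one image.

    image: 3×S×S float32 (the network's input scaling) or S×S×3 uint8.
    target_layer: a stage name of the model (default: the last stage before
    the pooling head — after the attention block when one is present).
    """
    if image.ndim == 3 and image.shape[2] == 3 and image.dtype == np.uint8:
        rgb = image
        x = image.transpose(2, 0, 1).astype(np.float32) / 127.5 - 1.0
    else:
        x = np.asarray(image, dtype=np.float32)
        rgb = np.clip((x.transpose(1, 2, 0) + 1.0) * 127.5, 0, 255).astype(np.uint8)
    if target_layer is None:
        target_layer = model.stage_names[-1]
    if target_layer not in model.stage_names:
        raise ValueError(f"layer {target_layer!r} not found; valid layers: "
                         f"{model.stage_names}")

    model.eval()
    model.cache_activations = True
    try:
        logits = model(Tensor(x[None], requires_grad=True))
        logits.backward(np.eye(logits.data.shape[1])[[target_class]])
    finally:
        model.cache_activations = False
    act_t = model.activation_cache[target_layer]
    acts = act_t.data[0]                                        # C×h×w
    grads = (act_t.grad[0] if act_t.grad is not None
             else np.zeros_like(acts))
    weights = grads.mean(axis=(1, 2))                           # GAP of gradients
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = resize(cam, rgb.shape[:2], order=1, mode="edge", anti_aliasing=False)
    cam = normalize_map(cam)

    heat = (np.stack([cam, np.zeros_like(cam), 1.0 - cam], axis=-1) * 255).astype(np.uint8)
    overlay = (0.55 * rgb.astype(float) + 0.45 * heat.astype(float)).astype(np.uint8)
    return Heatmap(values=cam, overlay=overlay,
                   target_layer=target_layer, target_class=target_class)


def save_heatmap(hm: Heatmap, gray_path, overlay_path=None) -> None:
    Image.fromarray((hm.values * 255).astype(np.uint8), mode="L").save(gray_path)
    if overlay_path is not None:
        Image.fromarray(hm.overlay).save(overlay_path, quality=90)
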