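"""Grad-CAM class-localisation maps for the tilt classifier.

For a class score y^c and the activations A^k of a tapped convolutional
layer, each feature map's weight is the spatial mean of dy^c/dA^k
(alpha_k = (1/Z) sum_ij dy^c/dA^k_ij with Z the number of spatial
positions), and the localisation map is the rectified weighted sum
L^c = ReLU(sum_k alpha_k A^k).  The map lives at the tapped layer's
spatial resolution; for display it is min-max normalised, upsampled
bilinearly and alpha-blended over the input image.

Activations are channels-last: (H, W, K) per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .harness import _normalize
from .nn import Network
from .stimuli import RenderedImage

__all__ = [
    "GradCamWeights",
    "HeatMap",
    "Overlay",
    "gradcam_weights",
    "gradcam_map",
    "gradcam",
    "heatmap_overlay",
]

CLASS_INDEX = {"C1": 0, "C2": 1}


@dataclass(frozen=True)
class GradCamWeights:
    """Per-feature-map weights alpha_k for one class, plus the spatial
    normalisation factor Z."""

    alpha: np.ndarray  # (K,)
    Z: int


@dataclass(frozen=True)
class HeatMap:
    """Rectified class-localisation map at the tapped layer's resolution."""

    L: np.ndarray  # (H, W), all entries >= 0
    layer_id: str
    class_id: str

    def __post_init__(self) -> None:
        if self.L.ndim != 2:
            raise ValueError("heat map must be 2-D")
        if not np.all(np.isfinite(self.L)) or np.any(self.L < 0):
            raise ValueError("heat map entries must be finite and non-negative")


@dataclass(frozen=True)
class Overlay:
    """A heat map blended over its source image."""

    pixels: np.ndarray  # (H, W, 3) uint8
    degenerate: bool    # True when the map had zero range (uniform wash)
    layer_id: str
    class_id: str


def gradcam_weights(activations: np.ndarray, gradients: np.ndarray) -> GradCamWeights:
    """alpha_k = spatial mean of the class-score gradient on feature map k."""
    if activations.shape != gradients.shape:
        raise ValueError(
            f"activations {activations.shape} and gradients {gradients.shape} "
            "must share a shape"
        )
    if activations.ndim != 3:
        raise ValueError("expected (H, W, K) activations for one image")
    h, w, _ = activations.shape
    z = h * w
    alpha = gradients.sum(axis=(0, 1)) / z
    return GradCamWeights(alpha=alpha.astype(np.float64), Z=z)


def gradcam_map(weights: GradCamWeights, activations: np.ndarray,
                layer_id: str = "", class_id: str = "") -> HeatMap:
    """L = ReLU(sum_k alpha_k * A^k)."""
    if activations.ndim != 3 or activations.shape[2] != weights.alpha.shape[0]:
        raise ValueError(
            f"activations {activations.shape} do not match "
            f"{weights.alpha.shape[0]} feature-map weights"
        )
    pre = np.tensordot(activations.astype(np.float64), weights.alpha, axes=([2], [0]))
    return HeatMap(L=np.maximum(pre, 0.0), layer_id=layer_id, class_id=class_id)


def gradcam(
    model: Network,
    image: RenderedImage | np.ndarray,
    class_id: str,
    layer_id: str | None = None,
    downscale: int = 2,
) -> HeatMap:
    """End-to-end Grad-CAM for one image and one class.

    The class score is the pre-softmax logit of ``class_id``.  The
    default tap is the model's last registered tap point (deepest
    convolutional block).
    """
    if class_id not in CLASS_INDEX:
        raise ValueError(f"class_id must be C1 or C2, got {class_id!r}")
    layer_id = layer_id or model.tap_points[-1]
    x = _image_to_input(image, downscale)
    logits, taps = model.forward(x, taps=[layer_id])
    dlogits = np.zeros_like(logits)
    dlogits[0, CLASS_INDEX[class_id]] = 1.0
    grads = model.backward(dlogits, grad_taps=[layer_id])
    weights = gradcam_weights(taps[layer_id][0], grads[layer_id][0])
    return gradcam_map(weights, taps[layer_id][0], layer_id=layer_id, class_id=class_id)


def _image_to_input(image: RenderedImage | np.ndarray, downscale: int) -> np.ndarray:
    if isinstance(image, RenderedImage):
        pix = image.pixels
        if downscale > 1:
            h, w = pix.shape[0] // downscale, pix.shape[1] // downscale
            pix = np.asarray(
                image.to_pil().resize((w, h), Image.Resampling.BOX), dtype=np.uint8
            )
        return _normalize(pix[None])
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[None]
    return arr.astype(np.float32)


def heatmap_overlay(
    heatmap: HeatMap,
    image: RenderedImage,
    alpha: float = 0.45,
    cmap: str = "jet",
) -> Overlay:
    """Blend a (min-max normalised, bilinearly upsampled) map over an image.

    A map with zero range — all entries equal, including the all-zero
    case — produces a uniform colour wash and is flagged ``degenerate``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    L = heatmap.L
    rng_ = float(L.max() - L.min())
    degenerate = rng_ == 0.0
    norm = np.zeros_like(L, dtype=np.float64) if degenerate else (L - L.min()) / rng_
    h, w = image.pixels.shape[:2]
    up = Image.fromarray((norm * 255).astype(np.uint8), mode="L").resize(
        (w, h), Image.Resampling.BILINEAR
    )
    colored = colormaps[cmap](np.asarray(up, dtype=np.float64) / 255.0)[..., :3]
    blended = (1 - alpha) * image.pixels.astype(np.float64) + alpha * 255.0 * colored
    return Overlay(
        pixels=np.clip(blended, 0, 255).astype(np.uint8),
        degenerate=degenerate,
        layer_id=heatmap.layer_id,
        class_id=heatmap.class_id,
    )
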