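"""Grad-CAM saliency for the lightweight classifier.

The original gradient-weighted class-activation formulation: channel weights
are the spatial means of the target-class logit's gradient at a conv unit's
(pooled) output; the map is the rectified channel-weighted activation sum,
min-max normalized to [0, 1].  A constant raw map normalizes to all zeros
rather than dividing by zero.  Maps can be produced for every conv unit
(layer panel) and scored for enrichment inside a known lesion mask.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ConfigError
from .train_harness import LABEL_TO_INDEX, TrainedModel

__all__ = ["SaliencyMap", "gradcam", "layer_panel", "mask_enrichment",
           "deepest_spatial_layer", "save_overlay"]


@dataclass
class SaliencyMap:
    heatmap: np.ndarray  # 2-D, values in [0, 1]
    target_layer: str  # "Conv1" .. "ConvN"
    target_class: str  # "GIST" or "leiomyoma"
    native_side: int
    upsampled: bool
    metadata: dict = field(default_factory=dict)


def _resolve_layer(model: TrainedModel, target_layer: str) -> str:
    """Map a 'ConvK' label to the unit's pooled-output tap."""
    name = target_layer.strip().lower().replace("conv", "")
    try:
        k = int(name)
    except ValueError:
        raise ConfigError(f"unknown layer {target_layer!r}; expected 'Conv1'..'ConvN'")
    if not 1 <= k <= model.spec.depth:
        raise ConfigError(
            f"layer {target_layer!r} out of range for a {model.spec.depth}-unit model"
        )
    return f"Unit{k}"


def _prepare(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None, None]
    elif img.ndim == 3:
        img = img[None]
    if img.ndim != 4 or img.shape[0] != 1:
        raise ConfigError(f"expected one grayscale image, got shape {np.shape(image)}")
    return img


def gradcam(
    model: TrainedModel,
    image: np.ndarray,
    target_layer: str = "Conv7",
    target_class: str = "GIST",
    upsample: bool = True,
) -> SaliencyMap:
    """Saliency map of ``target_class`` at one conv unit for one raw image
    (intensities in [0, 1]; the model's own normalization is applied)."""
    if target_class not in LABEL_TO_INDEX:
        raise ConfigError(f"unknown class {target_class!r}")
    tap = _resolve_layer(model, target_layer)
    x = model.stats.apply(_prepare(image)).astype(np.float32)
    net = model.net
    logits = net.forward(x, train=False, taps=(tap,))
    dy = np.zeros_like(logits)
    dy[0, LABEL_TO_INDEX[target_class]] = 1.0
    net.backward(dy)
    act = net.activations[tap][0]  # (C, h, w)
    grad = net.grads[tap][0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    lo, hi = float(cam.min()), float(cam.max())
    cam = np.zeros_like(cam) if hi - lo < 1e-12 else (cam - lo) / (hi - lo)
    native_side = cam.shape[0]
    if upsample:
        side = x.shape[-1]
        cam = resize(cam, (side, side), order=1, mode="edge", anti_aliasing=False)
        cam = np.clip(cam, 0.0, 1.0)
    return SaliencyMap(
        heatmap=cam.astype(np.float64),
        target_layer=f"Conv{tap.removeprefix('Unit')}",
        target_class=target_class,
        native_side=native_side,
        upsampled=upsample,
        metadata={"logits": logits[0].tolist(), "model_trained": model.trained},
    )


def layer_panel(
    model: TrainedModel,
    image: np.ndarray,
    target_class: str = "GIST",
    upsample: bool = False,
) -> list[SaliencyMap]:
    """One saliency map per conv unit, shallow to deep, same target class."""
    return [
        gradcam(model, image, f"Conv{k}", target_class, upsample=upsample)
        for k in range(1, model.spec.depth + 1)
    ]


def deepest_spatial_layer(model: TrainedModel, min_side: int = 3) -> str:
    """The deepest conv unit whose pooled map still has spatial extent.

    Chains that end at side 1 (the canonical family) produce a constant
    final-unit map after upsampling, so localization claims are made at the
    deepest unit with at least ``min_side`` pixels per side — CONV6 (side 3)
    for the canonical model."""
    from .archnet import shape_chain

    chain = shape_chain(model.spec)
    for k in range(len(chain), 0, -1):
        if chain[k - 1].side_post_pool >= min_side:
            return f"Conv{k}"
    return "Conv1"


def mask_enrichment(smap: SaliencyMap, lesion_mask: np.ndarray) -> tuple[float, float]:
    """Mean heat density inside vs outside the lesion mask.

    The mask is resized (nearest) to the heatmap side if needed.  Returns
    (inside_mean, outside_mean); either is nan for an empty region.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    if mask.shape != smap.heatmap.shape:
        mask = resize(mask.astype(float), smap.heatmap.shape, order=0) > 0.5
    inside = float(smap.heatmap[mask].mean()) if mask.any() else float("nan")
    outside = float(smap.heatmap[~mask].mean()) if (~mask).any() else float("nan")
    return inside, outside


def save_overlay(image: np.ndarray, smap: SaliencyMap, path, cmap: str = "jet",
                 alpha: float = 0.4) -> None:
    """Export the heatmap blended over the grayscale image as a PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from PIL import Image

    img = np.asarray(image, dtype=float)
    img = np.squeeze(img)
    heat = smap.heatmap
    if heat.shape != img.shape:
        heat = resize(heat, img.shape, order=1, mode="edge")
    colored = matplotlib.colormaps[cmap](heat)[..., :3]
    gray = np.repeat(img[..., None], 3, axis=2)
    blend = np.clip((1 - alpha) * gray + alpha * colored, 0, 1)
    Image.fromarray((blend * 255).astype(np.uint8)).save(path)
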