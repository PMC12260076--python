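"""Reference segmentation backbone, pixel-wise loss, and overlap metrics.

The framework is backbone-agnostic: anything exposing the ``Segmenter``
forward contract (image batch → per-pixel class scores at input resolution)
can be plugged in and registered by name.  A compact U-Net ships as the
reference backbone: strided-convolution encoder, transposed-convolution
decoder with skip connections, and a 1×1 head producing L-class logits.

Evaluation uses the Dice score 2|A∩B| / (|A|+|B|) and the Jaccard index
|A∩B| / |A∪B| (intersection-over-union) between the predicted and reference
foreground sets; both are 1 by convention when prediction and reference are
simultaneously empty, which keeps averages stable on degenerate toy cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "Segmenter",
    "UNet",
    "build_unet",
    "register_backbone",
    "get_backbone",
    "seg_loss",
    "predict_masks",
    "dice_score",
    "jaccard_index",
    "METRICS",
]


@dataclass
class UNet:
    """Small U-Net; forward: (N,C,H,W) images → (N,L,H,W) class scores."""

    image_size: int
    in_channels: int
    label_count: int
    base_width: int
    depth: int
    act: str = "lrelu"
    dtype: object = np.float64

    def __post_init__(self):
        if self.label_count < 2:
            raise ValueError("label_count must be >= 2")
        if self.image_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^{self.depth}")
        self.widths = [min(self.base_width * 2 ** i, 8 * self.base_width)
                       for i in range(self.depth)]

    def init_params(self, rng: np.random.Generator) -> dict:
        params = {}
        c_in = self.in_channels
        for i, w in enumerate(self.widths):
            params[f"enc{i}.w"] = Tensor(nn.kaiming_conv_init(
                rng, (w, c_in, 4, 4), c_in * 16, self.dtype), requires_grad=True)
            params[f"enc{i}.b"] = Tensor(np.zeros(w, dtype=self.dtype), requires_grad=True)
            c_in = w
        for i in range(self.depth):
            w_out = self.widths[self.depth - 2 - i] if i < self.depth - 1 else self.base_width
            c_dec = c_in if i == 0 else c_in + self.widths[self.depth - 1 - i]
            params[f"dec{i}.w"] = Tensor(nn.kaiming_conv_init(
                rng, (c_dec, w_out, 4, 4), c_dec * 16, self.dtype), requires_grad=True)
            params[f"dec{i}.b"] = Tensor(np.zeros(w_out, dtype=self.dtype), requires_grad=True)
            c_in = w_out
        params["head.w"] = Tensor(nn.kaiming_conv_init(
            rng, (self.label_count, c_in, 1, 1), c_in, self.dtype), requires_grad=True)
        params["head.b"] = Tensor(np.zeros(self.label_count, dtype=self.dtype),
                                  requires_grad=True)
        return params

    def forward(self, images: Tensor, params: dict) -> Tensor:
        h = images
        feats = []
        for i in range(self.depth):
            h = nn.conv2d(h, params[f"enc{i}.w"], params[f"enc{i}.b"], 2, 1)
            h = nn.activation(h, self.act)
            feats.append(h)
        for i in range(self.depth):
            if i > 0:
                h = ad.concat([h, feats[self.depth - 1 - i]], axis=1)
            h = nn.conv_transpose2d(h, params[f"dec{i}.w"], params[f"dec{i}.b"], 2, 1)
            h = nn.activation(h, self.act)
        return nn.conv2d(h, params["head.w"], params["head.b"], 1, 0)


# minimal plug-in registry mirroring the framework's model-agnostic design
_BACKBONES = {"unet": UNet}


def register_backbone(name: str, cls) -> None:
    _BACKBONES[name] = cls


def get_backbone(name: str):
    try:
        return _BACKBONES[name]
    except KeyError:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(_BACKBONES)}")


Segmenter = UNet  # the reference implementation of the Segmenter contract


def build_unet(image_size: int, channels: int = 1, label_count: int = 2,
               base_width: int = 8, depth: int = 3, act: str = "lrelu",
               dtype=np.float64) -> UNet:
    return UNet(image_size, channels, label_count, base_width, depth, act, dtype)


def seg_loss(scores: Tensor, masks: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between softmaxed scores and labels."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    n, L, h, w = scores.shape
    if masks.shape != (n, h, w):
        raise ValueError("scores and masks shapes disagree")
    if masks.min() < 0 or masks.max() >= L:
        raise ValueError("mask label outside [0, L)")
    lse = ad.logsumexp(scores, axis=1)                      # (N,H,W)
    # score of the correct class per pixel, gathered by flat index
    ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    flat = ((ni * L + masks) * h + hi) * w + wi
    correct = ad.gather_flat(scores, flat)                  # (N,H,W)
    return ad.mean(ad.sub(lse, correct))


def predict_masks(scores: Tensor | np.ndarray) -> np.ndarray:
    """Per-pixel argmax over class scores; ties go to the lowest class index."""
    arr = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    return np.argmax(arr, axis=1)


def _binary_sets(pred, gt, positive_label):
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and reference masks have different shapes")
    return pred == positive_label, gt == positive_label


def dice_score(pred_mask, gt_mask, positive_label: int = 1) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both sets are empty."""
    a, b = _binary_sets(pred_mask, gt_mask, positive_label)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def jaccard_index(pred_mask, gt_mask, positive_label: int = 1) -> float:
    """|A∩B| / |A∪B|; 1.0 when both sets are empty."""
    a, b = _binary_sets(pred_mask, gt_mask, positive_label)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


METRICS = {"dice": dice_score, "jaccard": jaccard_index}
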