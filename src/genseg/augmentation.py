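"""Mask augmentation for reverse (mask-first) data generation.

The generative pipeline starts from a real annotated mask, perturbs it
geometrically, and only then synthesizes the matching image.  The operators
here — rotation, flipping, translation and optional elastic deformation —
therefore act on integer label masks and must preserve label semantics:
every warp uses nearest-neighbour sampling and fills vacated pixels with the
background label 0, so no operator ever invents a label outside the input
label set plus background.

A paired variant applying identical sampled parameters to image and mask is
provided for classical-augmentation baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "flip_mask",
    "rotate_mask",
    "translate_mask",
    "elastic_deform_mask",
    "augment_mask",
    "augment_pair",
]


@dataclass
class ElasticConfig:
    alpha: float = 4.0   # displacement magnitude, px
    sigma: float = 3.0   # Gaussian smoothing of the displacement field, px


@dataclass
class AugmentConfig:
    """Ranges and probabilities for the random mask-augmentation sequence.

    Defaults: rotations in (-15°, 15°), both flips with probability 0.5,
    translations up to 10% of the side, elastic off.  Vessel-style tasks are
    orientation-sensitive and work best with small rotations (-5°, 5°).
    """

    rotation_range: tuple = (-15.0, 15.0)
    flip_horizontal_p: float = 0.5
    flip_vertical_p: float = 0.5
    translate_fraction: float = 0.1
    elastic: ElasticConfig | None = None
    enabled_ops: tuple = ("rotate", "flip", "translate")
    randomize_order: bool = True

    def validate(self):
        lo, hi = self.rotation_range
        if lo > hi:
            raise ValueError("rotation_range lo must be <= hi")
        for p in (self.flip_horizontal_p, self.flip_vertical_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if not 0.0 <= self.translate_fraction < 1.0:
            raise ValueError("translate_fraction must lie in [0, 1)")
        for op in self.enabled_ops:
            if op not in ("rotate", "flip", "translate", "elastic"):
                raise ValueError(f"unknown augmentation op {op!r}")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(enabled_ops=())


def flip_mask(mask: np.ndarray, axis: str) -> np.ndarray:
    """Mirror the mask; pixel (r,c) → (r, W-1-c) horizontally, (H-1-r, c) vertically."""
    if axis == "horizontal":
        return mask[:, ::-1].copy()
    if axis == "vertical":
        return mask[::-1, :].copy()
    raise ValueError(f"unknown flip axis {axis!r}")


def rotate_mask(mask: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate about the image center, nearest-neighbour, background fill."""
    if angle_degrees % 360 == 0:
        return mask.copy()
    return ndimage.rotate(mask, angle_degrees, reshape=False, order=0,
                          mode="constant", cval=0, prefilter=False)


def translate_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift by whole pixels; out-of-frame content is dropped, vacated pixels are 0."""
    h, w = mask.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError("shift magnitude must be smaller than the image size")
    out = np.zeros_like(mask)
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def _displacement_field(shape, alpha: float, sigma: float, rng: np.random.Generator):
    dy = ndimage.gaussian_filter(rng.standard_normal(shape), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.standard_normal(shape), sigma) * alpha
    return dy, dx


def elastic_deform_mask(mask: np.ndarray, alpha: float, sigma: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth random warp: Gaussian-filtered noise scaled by ``alpha``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return mask.copy()
    dy, dx = _displacement_field(mask.shape, alpha, sigma, rng)
    yy, xx = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    return ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0,
                                   prefilter=False)


def _sample_ops(config: AugmentConfig, rng: np.random.Generator):
    """Draw the concrete operator sequence for one augmentation call."""
    ops = []
    for name in config.enabled_ops:
        if name == "rotate":
            angle = rng.uniform(*config.rotation_range)
            ops.append(("rotate", {"angle": angle}))
        elif name == "flip":
            if rng.uniform() < config.flip_horizontal_p:
                ops.append(("flip", {"axis": "horizontal"}))
            if rng.uniform() < config.flip_vertical_p:
                ops.append(("flip", {"axis": "vertical"}))
        elif name == "translate":
            ops.append(("translate", {}))  # magnitude sampled at apply time (needs H, W)
        elif name == "elastic":
            if config.elastic is None:
                raise ValueError("elastic enabled but no ElasticConfig given")
            ops.append(("elastic", {"alpha": config.elastic.alpha,
                                    "sigma": config.elastic.sigma}))
    if config.randomize_order and len(ops) > 1:
        ops = [ops[i] for i in rng.permutation(len(ops))]
    return ops


def _apply_op(mask, name, kw, config, rng):
    if name == "rotate":
        return rotate_mask(mask, kw["angle"])
    if name == "flip":
        return flip_mask(mask, kw["axis"])
    if name == "translate":
        h, w = mask.shape
        max_dy = int(round(config.translate_fraction * h))
        max_dx = int(round(config.translate_fraction * w))
        dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy else 0
        dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx else 0
        return translate_mask(mask, dy, dx)
    if name == "elastic":
        return elastic_deform_mask(mask, kw["alpha"], kw["sigma"], rng)
    raise ValueError(name)


def augment_mask(mask: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Apply the enabled operators, in random order, with sampled parameters."""
    config.validate()
    out = mask
    for name, kw in _sample_ops(config, rng):
        out = _apply_op(out, name, kw, config, rng)
    return out.copy() if out is mask else out


def augment_pair(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator):
    """Baseline-style paired augmentation: identical sampled parameters are
    applied to both the image and the mask (image warps use linear sampling,
    mask warps nearest-neighbour)."""
    config.validate()
    img, m = image, mask
    for name, kw in _sample_ops(config, rng):
        if name == "translate":
            h, w = m.shape
            max_dy = int(round(config.translate_fraction * h))
            max_dx = int(round(config.translate_fraction * w))
            dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy else 0
            dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx else 0
            m = translate_mask(m, dy, dx)
            img = np.stack([translate_mask(img[:, :, c], dy, dx)
                            for c in range(img.shape[2])], axis=2)
        elif name == "flip":
            m = flip_mask(m, kw["axis"])
            img = np.stack([flip_mask(img[:, :, c], kw["axis"])
                            for c in range(img.shape[2])], axis=2)
        elif name == "rotate":
            m = rotate_mask(m, kw["angle"])
            img = ndimage.rotate(img, kw["angle"], axes=(0, 1), reshape=False,
                                 order=1, mode="constant", cval=0.0)
        elif name == "elastic":
            seed_state = rng.bit_generator.state
            m = elastic_deform_mask(m, kw["alpha"], kw["sigma"], rng)
            rng.bit_generator.state = seed_state
            dy, dx = _displacement_field(m.shape, kw["alpha"], kw["sigma"], rng)
            yy, xx = np.meshgrid(np.arange(m.shape[0]), np.arange(m.shape[1]),
                                 indexing="ij")
            coords = np.stack([yy + dy, xx + dx])
            img = np.stack([ndimage.map_coordinates(img[:, :, c], coords, order=1,
                                                    mode="constant", cval=0.0)
                            for c in range(img.shape[2])], axis=2)
    return np.clip(img, -1.0, 1.0), m
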