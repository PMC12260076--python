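"""Three-level optimization: GAN training, segmentation training, and
architecture search, solved jointly by differentiating through one-step
"virtual" updates.

The nesting is: (level 1) the generator weights G and discriminator weights
H play a minimax game on the role-swapped training pairs; (level 2) the
segmenter weights S are trained on generated pairs D̂(G*, A) plus γ-weighted
real pairs; (level 3) the architecture weights A are chosen to minimize the
segmenter's validation loss.  Each inner optimum is approximated by a single
gradient step kept differentiable:

    G' = G − η_g ∇_G L_gan(G, A, H)          (descent on the minimax loss)
    H' = H + η_h ∇_H L_gan(G, A, H)          (ascent)
    S' = S − η_s ∇_S [L_seg(S, D̂(G')) + γ L_seg(S, D_tr)]
    A  ← A − η_a ∇_A L_seg(S', D_val)

The architecture hypergradient ∇_A L_seg(S', D_val) is computed by reverse-
mode differentiation through both virtual steps, which contracts the cross
second derivatives −η_g ∇²_{A,G} L_gan and −η_s ∇²_{G',S} L_seg exactly
(the "exact-unrolled" mode).  A cheaper first-order mode skips the GAN
virtual step's second derivative.  Only the G'→S' path carries the
hypergradient; H' contributes none, and augmentation randomness is frozen
within an iteration so the gradient is well defined.

Committed (actual) parameter updates use stateful optimizers, while the
virtual steps use plain gradient steps exactly as written above — the
hypergradient derivation assumes plain steps, and separating the two is
standard practice in unrolled architecture search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, grad
from .augmentation import AugmentConfig, augment_mask
from .fixtures import SegDataset
from .genmodel import (ArchWeights, Discriminator, SearchableGenerator,
                       adversarial_losses_from_scores, build_discriminator,
                       build_searchable_generator, discriminator_scores,
                       gan_losses, generate_image, minimax_gan_objective)
from .segmodel import METRICS, get_backbone, predict_masks, seg_loss

__all__ = [
    "OptimSettings",
    "MLOConfig",
    "ModelConfig",
    "TrainState",
    "BatchSet",
    "build_models",
    "draw_batches",
    "virtual_gan_step",
    "synthesize_training_set",
    "virtual_seg_step",
    "architecture_gradient",
    "unrolled_validation_loss",
    "mlo_iteration",
    "load_checkpoint",
    "train_genseg",
    "train_separate",
    "train_vanilla",
]


@dataclass
class OptimSettings:
    kind: str = "adam"          # adam | rmsprop | sgd
    lr: float = 1e-5
    betas: tuple = (0.5, 0.999)
    momentum: float = 0.0
    weight_decay: float = 0.0

    def build(self, params: dict):
        if self.kind == "adam":
            return nn.Adam(params, self.lr, self.betas, self.weight_decay)
        if self.kind == "rmsprop":
            return nn.RMSprop(params, self.lr, momentum=self.momentum,
                              weight_decay=self.weight_decay)
        if self.kind == "sgd":
            return nn.SGD(params, self.lr, momentum=self.momentum,
                          weight_decay=self.weight_decay)
        raise ValueError(f"unknown optimizer {self.kind!r}")


@dataclass
class MLOConfig:
    """Scalars of the trilevel solver.

    Defaults follow the reference training recipe: γ = 1, a 5000-iteration
    budget, RMSprop (lr 1e-5, momentum 0.9, weight decay 1e-3) for the
    segmenter, Adam (lr 1e-5, betas (0.5, 0.999), weight decay 1e-3) for
    generator and discriminator, Adam (lr 1e-4, weight decay 1e-5) for the
    architecture logits, and plateau-based learning-rate reduction with
    patience 2 in max mode on the validation metric.  ``toy()`` returns the
    desk-scale configuration used for the synthetic-shape studies.
    """

    gamma: float = 1.0
    eta_g: float = 1e-3
    eta_h: float = 1e-3
    eta_s: float = 1e-3
    eta_a: float = 1e-4
    iterations: int = 5000
    batch_size: int = 4
    generated_per_real: float = 1.0
    hypergradient_mode: str = "exact-unrolled"   # exact-unrolled | first-order
    metric: str = "dice"
    seed: int = 0
    dtype: str = "float64"
    opt_g: OptimSettings = field(default_factory=lambda: OptimSettings(
        "adam", 1e-5, (0.5, 0.999), weight_decay=1e-3))
    opt_h: OptimSettings = field(default_factory=lambda: OptimSettings(
        "adam", 1e-5, (0.5, 0.999), weight_decay=1e-3))
    opt_s: OptimSettings = field(default_factory=lambda: OptimSettings(
        "rmsprop", 1e-5, momentum=0.9, weight_decay=1e-3))
    opt_a: OptimSettings = field(default_factory=lambda: OptimSettings(
        "adam", 1e-4, (0.5, 0.999), weight_decay=1e-5))
    plateau_patience: int = 2

    def validate(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        for name in ("eta_g", "eta_h", "eta_s", "eta_a"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.hypergradient_mode not in ("exact-unrolled", "first-order"):
            raise ValueError("unknown hypergradient mode")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {sorted(METRICS)}")

    @property
    def np_dtype(self):
        return np.float64 if self.dtype == "float64" else np.float32

    @classmethod
    def toy(cls, iterations: int = 300, seed: int = 0) -> "MLOConfig":
        """Desk-scale settings for 32×32 synthetic-shape tasks.

        Learning rates are scaled up to suit tiny networks and short
        budgets; the trade-off γ = 1 and the optimizer families are kept.
        """
        return cls(
            gamma=1.0, eta_g=0.05, eta_h=0.05, eta_s=0.05, eta_a=0.02,
            iterations=iterations, batch_size=4, seed=seed, dtype="float32",
            opt_g=OptimSettings("adam", 2e-3, (0.5, 0.999), weight_decay=1e-4),
            opt_h=OptimSettings("adam", 2e-3, (0.5, 0.999), weight_decay=1e-4),
            opt_s=OptimSettings("rmsprop", 2e-3, momentum=0.9, weight_decay=1e-4),
            opt_a=OptimSettings("adam", 2e-2, (0.5, 0.999), weight_decay=1e-5),
            plateau_patience=20,
        )


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the three models."""

    image_size: int = 32
    channels: int = 1
    label_count: int = 2
    gen_depth: int = 3
    gen_width: int = 8
    skip: bool = True
    disc_width: int = 8
    disc_layers: int = 2
    conditional_disc: bool = True
    seg_backbone: str = "unet"
    seg_depth: int = 3
    seg_width: int = 8
    act: str = "lrelu"


@dataclass
class Models:
    gen: SearchableGenerator
    disc: Discriminator
    seg: object


def build_models(cfg: ModelConfig, dtype=np.float64):
    gen, arch = build_searchable_generator(
        cfg.image_size, cfg.channels, cfg.gen_depth, cfg.gen_width, cfg.skip,
        cfg.label_count, act=cfg.act, dtype=dtype)
    disc = build_discriminator(cfg.image_size, cfg.channels, cfg.label_count,
                               cfg.disc_width, cfg.disc_layers,
                               cfg.conditional_disc, act=cfg.act, dtype=dtype)
    backbone = get_backbone(cfg.seg_backbone)
    seg = backbone(cfg.image_size, cfg.channels, cfg.label_count,
                   cfg.seg_width, cfg.seg_depth, act=cfg.act, dtype=dtype)
    return gen, arch, disc, seg


@dataclass
class TrainState:
    g_params: dict
    h_params: dict
    s_params: dict
    arch: ArchWeights
    iteration: int = 0
    history: list = field(default_factory=list)
    val_history: list = field(default_factory=list)
    best_metric: float = -np.inf
    best_checkpoint: dict | None = None

    def record_validation(self, metric: float):
        self.val_history.append({"iteration": self.iteration, "val_metric": metric})
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_checkpoint = {
                "s": {k: v.data.copy() for k, v in self.s_params.items()},
                "g": {k: v.data.copy() for k, v in self.g_params.items()},
                "logits": self.arch.logits.data.copy(),
                "iteration": self.iteration,
                "val_metric": metric,
            }

    def best_s_params(self) -> dict:
        if self.best_checkpoint is None:
            return self.s_params
        return {k: Tensor(v, requires_grad=True)
                for k, v in self.best_checkpoint["s"].items()}

    def save_checkpoint(self, path) -> None:
        """Persist the best checkpoint (S and G weights, logits, metadata)
        as an .npz archive; the key layout is stable across runs:
        ``s/<name>``, ``g/<name>``, ``logits``, ``iteration``, ``val_metric``."""
        if self.best_checkpoint is None:
            raise ValueError("no checkpoint recorded yet")
        ck = self.best_checkpoint
        arrays = {f"s/{k}": v for k, v in ck["s"].items()}
        arrays.update({f"g/{k}": v for k, v in ck["g"].items()})
        arrays["logits"] = ck["logits"]
        arrays["iteration"] = np.array(ck["iteration"])
        arrays["val_metric"] = np.array(ck["val_metric"])
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **arrays)


def load_checkpoint(path) -> dict:
    """Inverse of :meth:`TrainState.save_checkpoint`."""
    with np.load(path) as data:
        ck = {"s": {}, "g": {},
              "logits": data["logits"],
              "iteration": int(data["iteration"]),
              "val_metric": float(data["val_metric"])}
        for key in data.files:
            if key.startswith("s/"):
                ck["s"][key[2:]] = data[key]
            elif key.startswith("g/"):
                ck["g"][key[2:]] = data[key]
    return ck


@dataclass
class BatchSet:
    """Concrete arrays for one solver iteration (randomness pre-drawn)."""

    gan_images: Tensor          # real images for the GAN level (N,C,H,W)
    gan_masks: np.ndarray       # their masks (GAN inputs, role-swapped)
    seg_images: Tensor          # real images for the segmentation level
    seg_masks: np.ndarray
    val_images: Tensor
    val_masks: np.ndarray
    synth_masks: np.ndarray     # augmented masks for D̂ (frozen per iteration)


def _stack(dataset: SegDataset, idx, dtype):
    imgs = np.stack([dataset[i].image.transpose(2, 0, 1) for i in idx]).astype(dtype)
    masks = np.stack([dataset[i].mask for i in idx])
    return Tensor(imgs), masks


def draw_batches(d_tr: SegDataset, d_val: SegDataset, config: MLOConfig,
                 aug_config: AugmentConfig, rng: np.random.Generator) -> BatchSet:
    dtype = config.np_dtype
    bs = min(config.batch_size, len(d_tr))
    bv = min(config.batch_size, len(d_val))
    gan_idx = rng.choice(len(d_tr), size=bs, replace=False)
    seg_idx = rng.choice(len(d_tr), size=bs, replace=False)
    val_idx = rng.choice(len(d_val), size=bv, replace=False)
    gan_images, gan_masks = _stack(d_tr, gan_idx, dtype)
    seg_images, seg_masks = _stack(d_tr, seg_idx, dtype)
    val_images, val_masks = _stack(d_val, val_idx, dtype)
    n_gen = max(1, int(round(config.generated_per_real * bs)))
    src_idx = rng.choice(len(d_tr), size=n_gen, replace=n_gen > len(d_tr))
    synth_masks = np.stack([augment_mask(d_tr[i].mask, aug_config, rng)
                            for i in src_idx])
    return BatchSet(gan_images, gan_masks, seg_images, seg_masks,
                    val_images, val_masks, synth_masks)


# -- virtual one-step updates ------------------------------------------

def _check_finite(grads: dict, what: str):
    for k, g in grads.items():
        if not np.all(np.isfinite(g.data)):
            raise FloatingPointError(f"non-finite gradient in {what} ({k})")


def virtual_gan_step(gen: SearchableGenerator, disc: Discriminator,
                     g_params: dict, h_params: dict, arch: ArchWeights,
                     batch: BatchSet, eta_g: float, eta_h: float,
                     create_graph: bool = True):
    """One differentiable descent step of G and ascent step of H on the
    minimax GAN objective; G' retains its functional dependence on A."""
    fake = generate_image(gen, arch, batch.gan_masks, g_params)
    l_gan = minimax_gan_objective(disc, h_params,
                                  (batch.gan_images, batch.gan_masks),
                                  (fake, batch.gan_masks))
    names = list(g_params)
    g_grads = grad(l_gan, [g_params[k] for k in names], create_graph=create_graph)
    _check_finite(dict(zip(names, g_grads)), "virtual GAN step (G)")
    g1 = {k: ad.sub(g_params[k], ad.mul(Tensor(eta_g), gk))
          for k, gk in zip(names, g_grads)}
    h_names = list(h_params)
    h_grads = grad(l_gan, [h_params[k] for k in h_names])
    _check_finite(dict(zip(h_names, h_grads)), "virtual GAN step (H)")
    h1 = {k: ad.add(h_params[k], ad.mul(Tensor(eta_h), hk))
          for k, hk in zip(h_names, h_grads)}
    return g1, h1, l_gan


def synthesize_training_set(gen: SearchableGenerator, arch: ArchWeights,
                            g_params: dict, train_masks: np.ndarray,
                            aug_config: AugmentConfig | None = None,
                            rng: np.random.Generator | None = None,
                            alphas_override=None):
    """Build the generated set D̂: augment each mask, then synthesize images.

    Returns (images Tensor (N,C,H,W), masks (N,H,W)).  When ``aug_config``
    is None the masks are used as-is (augmentation already applied, or
    disabled).  Images keep the generator graph, so gradients can flow from
    segmentation losses back to G (and through G' to A).
    """
    masks = np.asarray(train_masks)
    if masks.ndim == 2:
        masks = masks[None]
    if aug_config is not None and aug_config.enabled_ops:
        if rng is None:
            raise ValueError("augmentation requires an rng")
        masks = np.stack([augment_mask(m, aug_config, rng) for m in masks])
    images = generate_image(gen, arch, masks, g_params, alphas_override)
    return images, masks


def virtual_seg_step(seg, s_params: dict, d_hat, d_tr, gamma: float,
                     eta_s: float, create_graph: bool = True):
    """One differentiable descent step of S on L_seg(S, D̂) + γ L_seg(S, D_tr)."""
    hat_images, hat_masks = d_hat
    loss = seg_loss(seg.forward(hat_images, s_params), hat_masks)
    if gamma != 0.0:
        tr_images, tr_masks = d_tr
        loss = ad.add(loss, ad.mul(Tensor(gamma),
                                   seg_loss(seg.forward(tr_images, s_params), tr_masks)))
    names = list(s_params)
    s_grads = grad(loss, [s_params[k] for k in names], create_graph=create_graph)
    _check_finite(dict(zip(names, s_grads)), "virtual segmentation step")
    s1 = {k: ad.sub(s_params[k], ad.mul(Tensor(eta_s), gk))
          for k, gk in zip(names, s_grads)}
    return s1, loss


def unrolled_validation_loss(gen, disc, seg, g_params, h_params, s_params,
                             arch: ArchWeights, batch: BatchSet,
                             config: MLOConfig, synth_alphas=None):
    """Validation loss after the unrolled virtual steps, as a graph node.

    exact-unrolled: A → ∇_G L_gan → G' → D̂ → ∇_S → S' → L_val, the stated
    hypergradient chain.  The synthesis-time mixture weights are frozen at
    ``synth_alphas`` (default: the current α as a constant), so A influences
    the loss only through the GAN virtual step — with η_g = 0 the
    architecture gradient is identically zero, as the chain requires.

    first-order: the GAN virtual step is detached and α enters the
    synthesis forward directly instead, so ∇_A flows through one virtual
    step only (a cheaper, different approximation).
    """
    first_order = config.hypergradient_mode == "first-order"
    if synth_alphas is None:
        synth_alphas = arch.alphas() if first_order else Tensor(arch.alphas_data())
    if first_order:
        g1 = g_params  # committed weights; α enters the synthesis forward
    else:
        g1, _, _ = virtual_gan_step(gen, disc, g_params, h_params, arch, batch,
                                    config.eta_g, config.eta_h, create_graph=True)
    d_hat = synthesize_training_set(gen, arch, g1, batch.synth_masks,
                                    alphas_override=synth_alphas)
    s1, _ = virtual_seg_step(seg, s_params, d_hat,
                             (batch.seg_images, batch.seg_masks),
                             config.gamma, config.eta_s, create_graph=True)
    return seg_loss(seg.forward(batch.val_images, s1), batch.val_masks)


def architecture_gradient(gen, disc, seg, g_params, h_params, s_params,
                          arch: ArchWeights, batch: BatchSet,
                          config: MLOConfig) -> Tensor:
    """∇_A L_seg(S', D_val) through the virtual steps (the chain above)."""
    if not arch.logits.requires_grad:
        raise ValueError("architecture logits are detached; cannot take the "
                         "hypergradient (was the architecture discretized?)")
    l_val = unrolled_validation_loss(gen, disc, seg, g_params, h_params,
                                     s_params, arch, batch, config)
    return grad(l_val, arch.logits)


# -- the outer loop -----------------------------------------------------

def _commit_grads(loss, params: dict):
    names = list(params)
    gs = grad(loss, [params[k] for k in names])
    return dict(zip(names, gs))


def mlo_iteration(state: TrainState, batch: BatchSet, config: MLOConfig,
                  gen, disc, seg, optimizers) -> TrainState:
    """One full solver iteration.

    In order: the virtual GAN step (G', H'), synthetic-set construction
    D̂(G'), the virtual segmentation step S', the architecture update
    A ← A − η_a ∇_A L_seg(S', D_val), and finally the committed updates of
    G, H and S with the stateful optimizers.  The whole iteration shares a
    single unrolled graph: the committed discriminator/segmenter updates
    reuse the virtual-step gradients (evaluated at the same point), and the
    committed generator update takes the non-saturating generator loss
    computed from the same discriminator scores.
    """
    opt_g, opt_h, opt_s, opt_a = optimizers
    exact = config.hypergradient_mode == "exact-unrolled"

    # level 1: adversarial forward, shared by virtual and committed updates
    fake = generate_image(gen, state.arch, batch.gan_masks, state.g_params)
    p_real = discriminator_scores(disc, state.h_params, batch.gan_images,
                                  batch.gan_masks)
    p_fake = discriminator_scores(disc, state.h_params, fake, batch.gan_masks)
    l_d, l_g = adversarial_losses_from_scores(p_real, p_fake)
    if not (np.isfinite(l_d.item()) and np.isfinite(l_g.item())):
        raise FloatingPointError("non-finite adversarial loss")
    l_gan = ad.neg(l_d)
    g_names = list(state.g_params)
    g_grads = grad(l_gan, [state.g_params[k] for k in g_names], create_graph=exact)
    _check_finite(dict(zip(g_names, g_grads)), "virtual GAN step (G)")
    if exact:
        g1 = {k: ad.sub(state.g_params[k], ad.mul(Tensor(config.eta_g), gk))
              for k, gk in zip(g_names, g_grads)}
        synth_alphas = Tensor(state.arch.alphas_data())
    else:
        g1 = state.g_params
        synth_alphas = state.arch.alphas()
    h_grads = _commit_grads(l_d, state.h_params)   # descent on L_d = ascent on L_gan
    g_commit = _commit_grads(l_g, state.g_params)  # non-saturating committed G loss

    # level 2: synthetic pairs from the virtually updated generator
    d_hat = synthesize_training_set(gen, state.arch, g1, batch.synth_masks,
                                    alphas_override=synth_alphas)

    # level 2→3: virtual segmentation step, kept differentiable
    s_names = list(state.s_params)
    seg_obj = seg_loss(seg.forward(d_hat[0], state.s_params), d_hat[1])
    if config.gamma != 0.0:
        seg_obj = ad.add(seg_obj, ad.mul(
            Tensor(config.gamma),
            seg_loss(seg.forward(batch.seg_images, state.s_params), batch.seg_masks)))
    if not np.isfinite(seg_obj.item()):
        raise FloatingPointError("non-finite segmentation loss")
    s_grads = grad(seg_obj, [state.s_params[k] for k in s_names], create_graph=True)
    _check_finite(dict(zip(s_names, s_grads)), "virtual segmentation step")
    s1 = {k: ad.sub(state.s_params[k], ad.mul(Tensor(config.eta_s), gk))
          for k, gk in zip(s_names, s_grads)}

    # level 3: validation loss and the architecture hypergradient
    l_val = seg_loss(seg.forward(batch.val_images, s1), batch.val_masks)
    arch_grad = grad(l_val, state.arch.logits)
    if config.eta_a > 0:
        opt_a.step({"logits": arch_grad})

    # committed updates
    opt_h.step(h_grads)
    opt_g.step(g_commit)
    opt_s.step({k: g.detach() for k, g in zip(s_names, s_grads)})

    state.iteration += 1
    state.history.append({
        "iteration": state.iteration,
        "loss_d": l_d.item(),
        "loss_g": l_g.item(),
        "loss_seg": seg_obj.item(),
        "loss_val": l_val.item(),
        "arch_grad_norm": float(np.linalg.norm(arch_grad.data)),
    })
    return state


def _validate(seg, s_params, d_val: SegDataset, metric: str, dtype) -> float:
    metric_fn = METRICS[metric]
    imgs = Tensor(d_val.images().astype(dtype))
    with ad.no_grad():
        scores = seg.forward(imgs, s_params)
    preds = predict_masks(scores)
    return float(np.mean([metric_fn(p, m) for p, m in zip(preds, d_val.masks())]))


def _epoch_length(d_tr: SegDataset, config: MLOConfig) -> int:
    return max(1, int(np.ceil(len(d_tr) / min(config.batch_size, len(d_tr)))))


def _init_all(config: MLOConfig, model_cfg: ModelConfig):
    dtype = config.np_dtype
    gen, arch, disc, seg = build_models(model_cfg, dtype=dtype)
    rng = np.random.default_rng(config.seed)
    g_params = gen.init_params(rng)
    h_params = disc.init_params(rng)
    s_params = seg.init_params(rng)
    return gen, arch, disc, seg, g_params, h_params, s_params, rng


def _write_log(log_path, state: TrainState):
    if log_path is None:
        return
    path = Path(log_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in state.history:
            fh.write(json.dumps(row) + "\n")
        for row in state.val_history:
            fh.write(json.dumps(row) + "\n")


def train_genseg(d_tr: SegDataset, d_val: SegDataset, config: MLOConfig,
                 model_cfg: ModelConfig | None = None,
                 aug_config: AugmentConfig | None = None,
                 log_path=None) -> TrainState:
    """End-to-end trilevel training; returns the best-validation checkpoint state."""
    config.validate()
    if len(d_tr) == 0 or len(d_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    model_cfg = model_cfg or ModelConfig(image_size=d_tr[0].mask.shape[0],
                                         label_count=d_tr.label_count)
    aug_config = aug_config if aug_config is not None else AugmentConfig()
    gen, arch, disc, seg, g_params, h_params, s_params, rng = _init_all(config, model_cfg)
    state = TrainState(g_params, h_params, s_params, arch)
    optimizers = (config.opt_g.build(g_params), config.opt_h.build(h_params),
                  config.opt_s.build(s_params),
                  replace(config.opt_a, lr=config.eta_a).build({"logits": arch.logits}))
    scheduler = nn.ReduceLROnPlateau(optimizers[2], patience=config.plateau_patience)
    epoch_len = _epoch_length(d_tr, config)
    for it in range(config.iterations):
        batch = draw_batches(d_tr, d_val, config, aug_config, rng)
        state = mlo_iteration(state, batch, config, gen, disc, seg, optimizers)
        if (it + 1) % epoch_len == 0 or it == config.iterations - 1:
            metric = _validate(seg, s_params, d_val, config.metric, config.np_dtype)
            state.record_validation(metric)
            scheduler.step(metric)
    _write_log(log_path, state)
    state.models = (gen, disc, seg)  # type: ignore[attr-defined]
    return state


def train_separate(d_tr: SegDataset, d_val: SegDataset, config: MLOConfig,
                   model_cfg: ModelConfig | None = None,
                   aug_config: AugmentConfig | None = None,
                   log_path=None) -> TrainState:
    """Two-phase baseline: train the GAN to completion, freeze it, then
    train the segmenter on its outputs.  The architecture is never updated:
    the logits stay at initialization (uniform α)."""
    config.validate()
    if len(d_tr) == 0 or len(d_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    model_cfg = model_cfg or ModelConfig(image_size=d_tr[0].mask.shape[0],
                                         label_count=d_tr.label_count)
    aug_config = aug_config if aug_config is not None else AugmentConfig()
    gen, arch, disc, seg, g_params, h_params, s_params, rng = _init_all(config, model_cfg)
    init_logits = arch.logits.data.copy()
    state = TrainState(g_params, h_params, s_params, arch)
    opt_g = config.opt_g.build(g_params)
    opt_h = config.opt_h.build(h_params)
    opt_s = config.opt_s.build(s_params)
    scheduler = nn.ReduceLROnPlateau(opt_s, patience=config.plateau_patience)
    epoch_len = _epoch_length(d_tr, config)
    half = max(1, config.iterations // 2)

    # phase 1: GAN alone on the role-swapped pairs
    for _ in range(half):
        batch = draw_batches(d_tr, d_val, config, aug_config, rng)
        fake = generate_image(gen, arch, batch.gan_masks, g_params)
        l_d, l_g = gan_losses(disc, h_params,
                              (batch.gan_images, batch.gan_masks),
                              (fake, batch.gan_masks))
        opt_h.step(_commit_grads(l_d, h_params))
        opt_g.step(_commit_grads(l_g, g_params))
        state.iteration += 1
        state.history.append({"iteration": state.iteration, "phase": 1,
                              "loss_d": l_d.item(), "loss_g": l_g.item()})

    # phase 2: freeze (G, A); generate D̂ once per epoch; train S
    d_hat_cache = None
    for it in range(config.iterations - half):
        if it % epoch_len == 0:
            masks = np.stack([augment_mask(p.mask, aug_config, rng) for p in d_tr])
            with ad.no_grad():
                imgs, msks = synthesize_training_set(gen, arch, g_params, masks)
            d_hat_cache = (imgs.detach(), msks)
        batch = draw_batches(d_tr, d_val, config, aug_config, rng)
        bs = min(config.batch_size, d_hat_cache[1].shape[0])
        sel = rng.choice(d_hat_cache[1].shape[0], size=bs, replace=False)
        hat_imgs = Tensor(d_hat_cache[0].data[sel])
        seg_obj = seg_loss(seg.forward(hat_imgs, s_params), d_hat_cache[1][sel])
        if config.gamma != 0.0:
            seg_obj = ad.add(seg_obj, ad.mul(
                Tensor(config.gamma),
                seg_loss(seg.forward(batch.seg_images, s_params), batch.seg_masks)))
        opt_s.step(_commit_grads(seg_obj, s_params))
        state.iteration += 1
        state.history.append({"iteration": state.iteration, "phase": 2,
                              "loss_seg": seg_obj.item()})
        if (it + 1) % epoch_len == 0 or it == config.iterations - half - 1:
            metric = _validate(seg, s_params, d_val, config.metric, config.np_dtype)
            state.record_validation(metric)
            scheduler.step(metric)
    assert np.array_equal(arch.logits.data, init_logits)
    _write_log(log_path, state)
    state.models = (gen, disc, seg)  # type: ignore[attr-defined]
    return state


def train_vanilla(d_tr: SegDataset, d_val: SegDataset, config: MLOConfig,
                  model_cfg: ModelConfig | None = None,
                  log_path=None) -> TrainState:
    """No-augmentation comparator: the same backbone trained on the real
    pairs only (the γ-term of the segmentation objective), same budget,
    same per-epoch validation and checkpointing."""
    config.validate()
    if len(d_tr) == 0 or len(d_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    model_cfg = model_cfg or ModelConfig(image_size=d_tr[0].mask.shape[0],
                                         label_count=d_tr.label_count)
    gen, arch, disc, seg, g_params, h_params, s_params, rng = _init_all(config, model_cfg)
    state = TrainState(g_params, h_params, s_params, arch)
    opt_s = config.opt_s.build(s_params)
    scheduler = nn.ReduceLROnPlateau(opt_s, patience=config.plateau_patience)
    epoch_len = _epoch_length(d_tr, config)
    for it in range(config.iterations):
        bs = min(config.batch_size, len(d_tr))
        idx = rng.choice(len(d_tr), size=bs, replace=False)
        imgs, masks = _stack(d_tr, idx, config.np_dtype)
        loss = seg_loss(seg.forward(imgs, s_params), masks)
        opt_s.step(_commit_grads(loss, s_params))
        state.iteration += 1
        state.history.append({"iteration": state.iteration, "loss_seg": loss.item()})
        if (it + 1) % epoch_len == 0 or it == config.iterations - 1:
            metric = _validate(seg, s_params, d_val, config.metric, config.np_dtype)
            state.record_validation(metric)
            scheduler.step(metric)
    _write_log(log_path, state)
    state.models = (gen, disc, seg)  # type: ignore[attr-defined]
    return state
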