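"""Mask-to-image generator with a searchable multi-branch architecture.

The generator is an encoder–decoder in the Pix2Pix style, but every
convolutional block is a *cell*: a set of K candidate operators (strided
convolutions in the encoder, transposed convolutions in the decoder, default
pool kernel/stride/padding 4-2-1, 6-2-2 and 8-2-3) whose outputs are mixed
by per-cell selection weights α.  Because each candidate satisfies
``kernel - 2*padding = stride``, all K branches of a cell map any input to
the same output shape, so the α-weighted sum is well defined and the cell
output is linear in α.  The α vectors are the architecture **A**: they are
produced from unconstrained logits by a per-cell softmax and are the
variables optimized by the outer level of the trilevel solver.  After
search, discretization keeps only the strongest operator per cell.

A fixed patch-style convolutional discriminator (optionally conditioned on
the input mask) and the adversarial cross-entropy losses complete the GAN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "CandidateOp",
    "CellSpec",
    "ArchWeights",
    "SearchableGenerator",
    "Discriminator",
    "DEFAULT_POOL",
    "normalize_alphas",
    "cell_forward",
    "build_searchable_generator",
    "generate_image",
    "build_discriminator",
    "discriminator_scores",
    "gan_losses",
    "adversarial_losses_from_scores",
    "minimax_gan_objective",
    "discretize_architecture",
    "one_hot_masks",
]

# kernel/stride/padding triples; k - 2p = s = 2 for every member, so all
# candidates in a cell agree on output shape (×1/2 down, ×2 up).
DEFAULT_POOL = ((4, 2, 1), (6, 2, 2), (8, 2, 3))


@dataclass(frozen=True)
class CandidateOp:
    kind: str        # "conv" | "upconv"
    kernel: int
    stride: int
    padding: int

    def __post_init__(self):
        if self.kind not in ("conv", "upconv"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.kind}{self.kernel}{self.stride}{self.padding}"


@dataclass
class CellSpec:
    """K shape-compatible candidates plus the cell's fixed post-block."""

    candidates: tuple
    in_channels: int
    out_channels: int
    norm: str = "instance"      # "instance" | "none"
    act: str = "lrelu"          # see nn.activation

    def __post_init__(self):
        if len(self.candidates) < 1:
            raise ValueError("a cell needs at least one candidate")
        strides = {c.stride for c in self.candidates}
        deltas = {c.kernel - 2 * c.padding for c in self.candidates}
        kinds = {c.kind for c in self.candidates}
        if len(strides) != 1 or len(kinds) != 1:
            raise ValueError("candidates must share stride and kind")
        if deltas != strides:
            raise ValueError("candidates must satisfy kernel - 2*padding = stride")

    @property
    def K(self) -> int:
        return len(self.candidates)


@dataclass
class ArchWeights:
    """Per-cell operator-selection weights, parameterized by free logits."""

    logits: Tensor   # (n_cells, K)

    @property
    def n_cells(self) -> int:
        return self.logits.shape[0]

    @property
    def K(self) -> int:
        return self.logits.shape[1]

    def alphas(self) -> Tensor:
        return normalize_alphas(self.logits)

    def alphas_data(self) -> np.ndarray:
        return normalize_alphas(self.logits).data

    @classmethod
    def uniform(cls, n_cells: int, K: int, dtype=np.float64) -> "ArchWeights":
        return cls(Tensor(np.zeros((n_cells, K), dtype=dtype), requires_grad=True))


def normalize_alphas(logits) -> Tensor:
    """Per-cell softmax: each row lies in (0,1) and sums to one."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("architecture logits must be finite")
    shifted = ad.sub(logits, Tensor(np.max(logits.data, axis=-1, keepdims=True)))
    e = ad.exp(shifted)
    return ad.div(e, ad.sum_(e, axis=-1, keepdims=True))


def discretize_architecture(arch: ArchWeights) -> ArchWeights:
    """One-hot on each cell's argmax α; ties resolved to the lowest index."""
    a = arch.alphas_data()
    onehot = np.zeros_like(a)
    onehot[np.arange(a.shape[0]), np.argmax(a, axis=1)] = 1.0
    # logits reproducing the one-hot exactly under softmax are infinite;
    # store a saturated representation and flag it
    logits = np.where(onehot > 0, 0.0, -np.inf)
    out = ArchWeights(Tensor(logits, requires_grad=False))
    out._onehot = onehot  # type: ignore[attr-defined]
    return out


def _arch_alphas(arch: ArchWeights) -> Tensor:
    onehot = getattr(arch, "_onehot", None)
    if onehot is not None:
        return Tensor(onehot)
    return arch.alphas()


# -- cells --------------------------------------------------------------

def _branch_params(rng, spec: CellSpec, op: CandidateOp, dtype):
    if op.kind == "conv":
        shape = (spec.out_channels, spec.in_channels, op.kernel, op.kernel)
        fan_in = spec.in_channels * op.kernel * op.kernel
    else:
        shape = (spec.in_channels, spec.out_channels, op.kernel, op.kernel)
        fan_in = spec.in_channels * op.kernel * op.kernel
    w = nn.kaiming_conv_init(rng, shape, fan_in, dtype)
    b = np.zeros(spec.out_channels, dtype=dtype)
    return w, b


def init_cell_params(rng, spec: CellSpec, prefix: str, dtype=np.float64) -> dict:
    params = {}
    for k, op in enumerate(spec.candidates):
        w, b = _branch_params(rng, spec, op, dtype)
        params[f"{prefix}.op{k}.w"] = Tensor(w, requires_grad=True)
        params[f"{prefix}.op{k}.b"] = Tensor(b, requires_grad=True)
    return params


def cell_forward(x: Tensor, cell: CellSpec, alphas: Tensor, params: dict,
                 prefix: str = "cell") -> Tensor:
    """α-weighted sum of the K candidate branch outputs.

    Each branch is (conv | transposed conv) → optional instance norm →
    activation; the mixture is taken over full branch outputs, so a one-hot
    α collapses the cell to the single retained operator exactly.
    """
    if alphas.shape[-1] != cell.K:
        raise ValueError("alpha length does not match the number of candidates")
    y = None
    for k, op in enumerate(cell.candidates):
        w = params[f"{prefix}.op{k}.w"]
        b = params[f"{prefix}.op{k}.b"]
        if op.kind == "conv":
            h = nn.conv2d(x, w, b, op.stride, op.padding)
        else:
            h = nn.conv_transpose2d(x, w, b, op.stride, op.padding)
        if cell.norm == "instance":
            h = nn.instance_norm(h)
        h = nn.activation(h, cell.act)
        term = ad.mul(alphas[k].reshape(1, 1, 1, 1), h)
        y = term if y is None else ad.add(y, term)
    return y


# -- the generator ------------------------------------------------------

@dataclass
class SearchableGenerator:
    """Encoder of strided-conv cells, decoder of transposed-conv cells.

    With ``skip`` on, each decoder cell receives the mirrored encoder
    feature concatenated on channels (U-Net / Pix2Pix convention).  The last
    decoder cell omits normalization and squashes to [-1, 1] with tanh.
    """

    image_size: int
    label_count: int
    out_channels: int
    depth: int
    base_width: int
    skip: bool
    encoder_cells: list
    decoder_cells: list
    act: str = "lrelu"
    dtype: object = np.float64

    @property
    def n_cells(self) -> int:
        return len(self.encoder_cells) + len(self.decoder_cells)

    def init_params(self, rng: np.random.Generator) -> dict:
        params = {}
        for i, spec in enumerate(self.encoder_cells):
            params.update(init_cell_params(rng, spec, f"enc{i}", self.dtype))
        for i, spec in enumerate(self.decoder_cells):
            params.update(init_cell_params(rng, spec, f"dec{i}", self.dtype))
        return params

    def forward(self, mask_onehot: Tensor, params: dict, alphas: Tensor) -> Tensor:
        feats = []
        h = mask_onehot
        for i, spec in enumerate(self.encoder_cells):
            h = cell_forward(h, spec, alphas[i], params, f"enc{i}")
            feats.append(h)
        n_enc = len(self.encoder_cells)
        for i, spec in enumerate(self.decoder_cells):
            if self.skip and i > 0:
                h = ad.concat([h, feats[n_enc - 1 - i]], axis=1)
            h = cell_forward(h, spec, alphas[n_enc + i], params, f"dec{i}")
        return ad.tanh(h)


def build_searchable_generator(image_size: int, channels: int = 1, depth: int = 3,
                               base_width: int = 8, skip: bool = True,
                               label_count: int = 2, pool=DEFAULT_POOL,
                               act: str = "lrelu", norm: str = "instance",
                               dtype=np.float64):
    """Construct the generator structure and fresh uniform ArchWeights."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if image_size % (2 ** depth) != 0:
        raise ValueError(f"image_size {image_size} not divisible by 2^{depth}")
    conv_ops = tuple(CandidateOp("conv", k, s, p) for k, s, p in pool)
    up_ops = tuple(CandidateOp("upconv", k, s, p) for k, s, p in pool)

    widths = [min(base_width * (2 ** i), 8 * base_width) for i in range(depth)]
    enc, dec = [], []
    c_in = label_count
    for i in range(depth):
        enc.append(CellSpec(conv_ops, c_in, widths[i], norm=norm, act=act))
        c_in = widths[i]
    for i in range(depth):
        c_out = widths[depth - 2 - i] if i < depth - 1 else channels
        c_dec_in = c_in if i == 0 else c_in + (widths[depth - 1 - i] if skip else 0)
        last = i == depth - 1
        dec.append(CellSpec(up_ops, c_dec_in if skip else c_in, c_out,
                            norm="none" if last else norm,
                            act="identity" if last else act))
        c_in = c_out
    gen = SearchableGenerator(image_size, label_count, channels, depth, base_width,
                              skip, enc, dec, act=act, dtype=dtype)
    arch = ArchWeights.uniform(gen.n_cells, len(pool), dtype=dtype)
    return gen, arch


def one_hot_masks(masks: np.ndarray, label_count: int, dtype=np.float64) -> Tensor:
    """(N,H,W) integer masks → (N,L,H,W) one-hot channels."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.min() < 0 or masks.max() >= label_count:
        raise ValueError("mask contains labels outside the configured set")
    eye = np.eye(label_count, dtype=dtype)
    return Tensor(eye[masks].transpose(0, 3, 1, 2))


def generate_image(generator: SearchableGenerator, arch: ArchWeights,
                   mask, params: dict, alphas_override: Tensor | None = None) -> Tensor:
    """Synthesize image(s) for integer mask(s); deterministic in (params, A, mask).

    ``alphas_override`` substitutes an explicit mixture-weight tensor for
    the architecture's own (used by the trilevel solver to freeze the
    synthesis-time mixture at its current value within one iteration).
    """
    x = one_hot_masks(np.asarray(mask), generator.label_count, generator.dtype)
    alphas = alphas_override if alphas_override is not None else _arch_alphas(arch)
    return generator.forward(x, params, alphas)


# -- discriminator ------------------------------------------------------

@dataclass
class Discriminator:
    """Fixed patch-style convolutional classifier.

    Conditional mode concatenates the one-hot mask to the image channels, so
    the critic judges (image, mask) consistency rather than appearance
    alone.  Outputs per-patch probabilities in (0,1).
    """

    image_size: int
    in_channels: int
    label_count: int
    base_width: int
    n_layers: int
    conditional: bool = True
    act: str = "lrelu"
    dtype: object = np.float64

    def init_params(self, rng: np.random.Generator) -> dict:
        params = {}
        c_in = self.in_channels + (self.label_count if self.conditional else 0)
        w = self.base_width
        for i in range(self.n_layers):
            shape = (w, c_in, 4, 4)
            params[f"d{i}.w"] = Tensor(nn.kaiming_conv_init(
                rng, shape, c_in * 16, self.dtype), requires_grad=True)
            params[f"d{i}.b"] = Tensor(np.zeros(w, dtype=self.dtype), requires_grad=True)
            c_in, w = w, w * 2
        params["head.w"] = Tensor(nn.kaiming_conv_init(
            rng, (1, c_in, 1, 1), c_in, self.dtype), requires_grad=True)
        params["head.b"] = Tensor(np.zeros(1, dtype=self.dtype), requires_grad=True)
        return params

    def forward(self, images: Tensor, mask_onehot, params: dict) -> Tensor:
        h = images
        if self.conditional:
            if mask_onehot is None:
                raise ValueError("conditional discriminator requires the mask")
            h = ad.concat([h, mask_onehot], axis=1)
        for i in range(self.n_layers):
            h = nn.conv2d(h, params[f"d{i}.w"], params[f"d{i}.b"], stride=2, padding=1)
            h = nn.activation(h, self.act)
        logits = nn.conv2d(h, params["head.w"], params["head.b"], stride=1, padding=0)
        return ad.sigmoid(logits)


def build_discriminator(image_size: int, channels: int = 1, label_count: int = 2,
                        base_width: int = 8, n_layers: int = 2,
                        conditional: bool = True, act: str = "lrelu",
                        dtype=np.float64) -> Discriminator:
    return Discriminator(image_size, channels, label_count, base_width,
                         n_layers, conditional, act, dtype)


def discriminator_scores(disc: Discriminator, params: dict, images: Tensor,
                         masks: np.ndarray | None) -> Tensor:
    onehot = None
    if disc.conditional:
        onehot = one_hot_masks(masks, disc.label_count, disc.dtype)
    return disc.forward(images, onehot, params)


# -- adversarial losses -------------------------------------------------

_EPS = 1e-12


def adversarial_losses_from_scores(p_real: Tensor, p_fake: Tensor):
    """(L_d, L_g) from discriminator probabilities.

    L_d = -(mean log p_real + mean log(1 - p_fake)) / 2, the average of the
    real-as-real and fake-as-fake cross-entropy terms; L_g is the
    non-saturating generator loss -mean log p_fake.
    """
    if p_real.size == 0 or p_fake.size == 0:
        raise ValueError("empty batch")
    real_term = ad.neg(ad.mean(ad.log(ad.add(p_real, Tensor(_EPS)))))
    fake_term = ad.neg(ad.mean(ad.log(ad.add(ad.sub(Tensor(1.0), p_fake), Tensor(_EPS)))))
    l_d = ad.mul(Tensor(0.5), ad.add(real_term, fake_term))
    l_g = ad.neg(ad.mean(ad.log(ad.add(p_fake, Tensor(_EPS)))))
    return l_d, l_g


def gan_losses(disc: Discriminator, disc_params: dict, real_pairs, fake_pairs):
    """Adversarial losses for batches of (images, masks) pairs.

    ``real_pairs``/``fake_pairs`` are (images Tensor (N,C,H,W), masks array)
    tuples; fake images should come from :func:`generate_image` so the
    generator graph is retained.
    """
    real_images, real_masks = real_pairs
    fake_images, fake_masks = fake_pairs
    p_real = discriminator_scores(disc, disc_params, real_images, real_masks)
    p_fake = discriminator_scores(disc, disc_params, fake_images, fake_masks)
    return adversarial_losses_from_scores(p_real, p_fake)


def minimax_gan_objective(disc: Discriminator, disc_params: dict, real_pairs, fake_pairs):
    """The single minimax objective L_gan = -L_d.

    The generator takes a descent step and the discriminator an ascent step
    on this same quantity in the virtual one-step updates of the trilevel
    solver.
    """
    l_d, _ = gan_losses(disc, disc_params, real_pairs, fake_pairs)
    return ad.neg(l_d)
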