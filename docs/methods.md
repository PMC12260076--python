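# Methods

## The model

`genseg` trains a segmentation network in the ultra low-data regime (tens
of annotated pairs) by generating auxiliary image–mask pairs whose
usefulness is optimized *end to end*: the generator is updated so that a
segmenter trained on its outputs performs well on held-out real data.

Generation is mask-first ("reverse"): a real annotated mask **M** is
perturbed by simple geometric augmentations into **M̂**, and a conditional
generator with weights **G** and architecture weights **A** synthesizes the
matching image **Î**(M̂, G, A). The pair (Î, M̂) is a synthetic training
example. Three nested optimization levels tie everything together:

1. **GAN level.** On the role-swapped training pairs (mask as input, image
   as output), the generator and a fixed-architecture patch discriminator
   **H** play the usual minimax game with cross-entropy:
   G*(A), H* = argmin_G argmax_H L_gan(G, A, H, D_gan).
2. **Segmentation level.** The segmenter **S** minimizes pixel-wise
   cross-entropy on generated data D̂(G*(A)) plus γ-weighted real data:
   S*(A) = argmin_S L_seg(S, D̂) + γ·L_seg(S, D_tr), with γ = 1 by default.
3. **Architecture level.** A is chosen to minimize the validation loss
   L_seg(S*(A), D_val).

### The searchable generator

The generator is an encoder–decoder in the Pix2Pix style whose every block
is a *cell*: K = 3 parallel candidate operators — strided convolutions
(encoder) or transposed convolutions (decoder) with kernel/stride/padding
4-2-1, 6-2-2, 8-2-3 — mixed by per-cell selection weights α produced from
free logits by a softmax. Because every candidate satisfies
k − 2p = s = 2, all branches of a cell map a given input to the same output
shape (×½ down, ×2 up), so the mixture y = Σ_k α_k o_k(x) is well defined
and linear in α. Each branch is conv → instance norm → leaky-ReLU
(encoder) / ReLU (decoder); the last decoder cell omits the norm and
squashes to [−1, 1] with tanh. Mirrored encoder/decoder cells are joined
by skip connections (on by default). Masks enter as one-hot label
channels. After search, `discretize_architecture` retains the argmax
operator per cell (ties to the lowest index); the discretized forward is
bit-identical to the corresponding single-branch network.

Choices the underlying formulation leaves open, resolved here:

- α is parameterized as a per-cell softmax over logits — values in (0, 1)
  summing to 1, keeping the mixture convex and differentiable.
- The discriminator is a small patch-style convolutional classifier,
  conditioned on the mask by channel concatenation (an unconditional switch
  exists). Conditioning lets the critic judge image–mask consistency.
- No reconstruction (L1) term is added: the adversarial objective is pure
  cross-entropy.

### The solver

Each inner optimum is approximated by one differentiable ("virtual")
gradient step:

    G' = G − η_g ∇_G L_gan        H' = H + η_h ∇_H L_gan
    S' = S − η_s ∇_S [L_seg(S, D̂(G')) + γ L_seg(S, D_tr)]
    A ← A − η_a ∇_A L_seg(S', D_val)

The architecture hypergradient is the chain
(∂G'/∂A)(∂S'/∂G')(∂L/∂S') with ∂G'/∂A = −η_g ∇²_{A,G} L_gan and
∂S'/∂G' = −η_s ∇²_{G',S}[L_seg(S, D̂(G')) + γ L_seg(S, D_tr)]. It is
evaluated exactly by reverse-mode differentiation through both virtual
steps ("exact-unrolled" mode, the default). Three scoping rules make the
implemented gradient exactly this chain and nothing more:

- the discriminator's virtual step H' contributes no path;
- augmentation randomness is frozen within an iteration, so D̂ is a
  deterministic function of (G', masks);
- the synthesis-time mixture weights are frozen at their current values
  inside the unrolled objective (a constant ᾱ), so A influences the
  validation loss only through ∇_G L_gan. Consequently η_g = 0 or η_s = 0
  makes the architecture gradient identically zero — a useful structural
  check, verified in the tests.

A cheaper **first-order** mode skips the GAN virtual step and instead lets
α enter the synthesis forward directly; it is provided for speed and is not
used by the acceptance checks.

**Virtual vs committed updates.** The derivation above assumes plain
gradient steps, so the virtual updates use η_g, η_h, η_s as written. The
*committed* parameter updates of each iteration use stateful optimizers:
RMSprop for S (momentum 0.9), Adam (β = (0.5, 0.999)) for G, H and for the
architecture logits, with plateau-based learning-rate reduction (patience
2, max mode) on the validation metric. The committed discriminator and
segmenter updates reuse the virtual-step gradients (evaluated at the same
point); the committed generator update uses the non-saturating generator
loss −E log D(fake), the standard stabilization of the minimax objective in
conditional image synthesis. One generated pair per real training mask is
drawn per step (1:1 ratio; configurable).

Training runs a fixed iteration budget with per-epoch validation; the
checkpoint with the best validation Dice (or Jaccard) is returned. The
returned metric always equals the running maximum of the validation
history.

The segmenter's virtual update is gradient *descent* on its objective, as
the update formula above states; the segmenter minimizes, only the
discriminator ascends.

### Baselines

- **Separate**: the GAN is trained alone for half the budget and frozen;
  the segmenter then trains on pairs generated once per epoch plus
  γ-weighted real data. The architecture logits never move — α stays
  uniform.
- **Vanilla**: the same segmentation backbone trained on the real pairs
  only, same budget and checkpointing.

## Mask augmentation

Rotation (default range ±15°; ±5° recommended for orientation-sensitive
vessel-like structures), horizontal/vertical flips (p = 0.5 each), integer
translations (up to 10% of the side), and optional elastic deformation
(Gaussian-smoothed displacement noise, magnitude α px, smoothing σ px),
applied in a uniformly random order. All mask warps use nearest-neighbour
sampling and background fill 0, so the label set never grows: these
decisions preserve integer label semantics where the formulation is
silent. A paired variant applies identical sampled parameters to image and
mask for classical-augmentation baselines.

## The numerical core

No automatic-differentiation framework is a dependency; the package ships
its own reverse-mode engine over numpy (`genseg.autodiff`). Backward
passes are built from the engine's own differentiable primitives, so
gradients of gradients — the cross second derivatives in the hypergradient
— are exact to machine precision. Convolution, transposed convolution,
padding and slicing all reduce to one gather/scatter primitive pair plus a
batched matrix product, which keeps the higher-order correctness argument
small. Gradient-check tests run in double precision with smooth (tanh)
activations; training uses single precision with leaky-ReLU networks (the
leaky-ReLU branch selector is piecewise-constant, so its second derivative
is zero almost everywhere and the unrolled gradients remain exact).

## The synthetic data generator

Real applications segment lesions, fluid pockets and vessels in noisy,
textured medical images with only tens of annotated pairs. The fixture
module emulates this at desk scale with three mask families — unions of
random ellipses (lesion-like), annuli (fluid-pocket-like), random binary
branching trees rasterized and dilated (vessel-like) — rendered to images
as: per-region base levels separated by a configurable contrast, plus a
smooth random texture field re-centered within foreground and background
(so the noiseless fg−bg mean gap equals the contrast exactly; a single
global rescale keeps the noiseless image inside [−1, 1] without clipping),
plus Gaussian pixel noise. Defaults — 32×32 pixels, contrast 0.5, noise
SD 0.3, texture amplitude 0.25 — are chosen so that a U-Net trained on ten
pairs reaches a mid-range Dice (~0.6), the regime where augmentation
matters, mirroring the difficulty of the real ultra-low-data tasks.

An out-of-domain variant shifts image appearance only (intensity bias,
contrast delta via the known masks, rotation of the texture residual);
masks are preserved exactly.

What the generator does *not* emulate: anatomical shape priors, imaging
physics (speckle, attenuation, modality-specific artifacts), annotation
noise, and class imbalance beyond binary foreground/background. Passing
tests on these fixtures demonstrates the optimization machinery and the
direction of the method's effect, not clinical performance.

## Study conditions and problem sizes

The desk-scale study uses 10 training / 5 validation / 30 test pairs at
32×32 (blob task), 300 solver iterations, batch size 4, three seeds, and
the `MLOConfig.toy()` learning rates (virtual rates 0.05; committed rates
2e-3 for G/H/S, 2e-2 for the logits) — scaled for tiny single-precision
networks while keeping γ = 1 and the optimizer families of the reference
recipe. `MLOConfig()` defaults carry the reference recipe itself (5000
iterations, rates 1e-5/1e-4). Gradient-check instances use ≤200-parameter
generator/segmenter networks on 8×8 inputs, a reduced candidate pool
(2-2-0, 4-2-1, 6-2-2) and double precision.

## Known limitations

- The numpy engine is single-threaded and keeps whole graphs in memory;
  it is sized for desk-scale studies, not full-resolution imagery.
- GAN image quality after a few hundred iterations at 32×32 is crude; the
  measured benefit of the end-to-end method comes from tailored, diverse
  (mask, image) supervision rather than photorealism.
- The validation split has 5 pairs in the toy study, so per-epoch
  validation metrics (and checkpoint selection) are noisy.
- Binary segmentation is the tested path; multi-label inputs are supported
  structurally but not exercised by the study.
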