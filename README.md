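# genseg

End-to-end generative augmentation for semantic segmentation in ultra
low-data regimes.

## The problem

Training a segmentation network needs dense pixel-level annotation, which
in medical imaging is expensive enough that realistic datasets often hold
only tens of labelled image–mask pairs. Classical augmentation and
off-the-shelf generative models can manufacture extra pairs, but they are
trained *separately* from the segmenter, so nothing guarantees the
synthetic data actually helps the downstream task.

`genseg` closes that loop. A mask-to-image generator — whose multi-branch
architecture is itself learnable — is trained jointly with the segmentation
model through three nested optimization levels, so that segmentation
performance on held-out real data directly steers both the generator's
weights and its architecture.

## The method in brief

Generation is mask-first: a real annotated mask **M** is geometrically
augmented into **M̂** (rotation, flips, translation, optional elastic
deformation), then a conditional generator with weights **G** and
architecture weights **A** synthesizes the matching image **Î**(M̂, G, A).
Three levels are solved jointly:

1. **G\*(A), H\*** = argmin_G argmax_H *L*_gan(G, A, H, D_gan) — a
   conditional GAN on the role-swapped training pairs;
2. **S\*(A)** = argmin_S *L*_seg(S, D̂(G\*(A))) + γ·*L*_seg(S, D_tr) — the
   segmenter trains on generated plus γ-weighted real pairs (γ = 1);
3. min_A *L*_seg(S\*(A), D_val) — the architecture minimizes validation
   loss.

Each inner optimum is approximated by a one-step "virtual" update kept
differentiable (G′ = G − η_g∇_G L_gan, S′ = S − η_s∇_S[·]), and the
architecture gradient is the exact chain
(∂G′/∂A)(∂S′/∂G′)(∂L/∂S′), involving the cross second derivatives
−η_g∇²_{A,G}L_gan and −η_s∇²_{G′,S}[·]. Every cell of the generator mixes
K = 3 candidate (up-)convolutions (kernel/stride/padding 4-2-1, 6-2-2,
8-2-3) with softmax weights α; after search, the strongest operator per
cell can be retained. Evaluation uses the Dice score 2|A∩B|/(|A|+|B|) or
the Jaccard index |A∩B|/|A∪B|.

The package runs entirely on synthetic 2-D data: a fixtures module draws
lesion-like (blob), ring-like and vessel-like (branching-tree) masks and
renders noisy textured images from them, with an out-of-domain shift knob.
The numerical core is a small numpy reverse-mode autodiff engine with
higher-order gradients, so the hypergradient is exact (verified against
finite differences in the test suite). See `docs/methods.md` for the full
account.

## Worked example

Train the end-to-end method and the no-augmentation baseline on a
desk-scale blob task (10 training / 5 validation / 30 test pairs, 32×32):

```python
import numpy as np
from genseg import (ShapeDatasetConfig, generate_shape_dataset,
                    MLOConfig, train_genseg, train_vanilla, evaluate)

d_tr  = generate_shape_dataset(ShapeDatasetConfig(n=10, image_size=32, seed=100))
d_val = generate_shape_dataset(ShapeDatasetConfig(n=5,  image_size=32, seed=101,
                                                  split="validation"))
d_te  = generate_shape_dataset(ShapeDatasetConfig(n=30, image_size=32, seed=102,
                                                  split="test"))

for name, trainer in [("vanilla", train_vanilla), ("genseg", train_genseg)]:
    scores = []
    for seed in (0, 1, 2):
        state = trainer(d_tr, d_val, MLOConfig.toy(iterations=300, seed=seed))
        res = evaluate(state.models[2], state.best_s_params(), d_te, "dice")
        scores.append(res["mean"])
    print(f"{name}: mean test Dice {np.mean(scores):.3f}")
```

Output from this exact script:

```
vanilla: mean test Dice 0.608
genseg: mean test Dice 0.674
```

The numbers are mean Dice overlap between predicted and reference
foreground over the 30 test pairs, averaged over three training seeds:
with only ten real pairs, training on tailored generated pairs alongside
the real ones lifts test Dice by about seven points over the identical
backbone trained on real pairs alone. `train_separate` runs the two-phase
comparator (generator trained first, then frozen); on the same splits it
reaches 0.642, between the two — the end-to-end coupling, not generation
per se, provides the extra edge.

The same experiment, plus an out-of-domain evaluation and CSV/JSON
reports, is available from the command line:

```
genseg simulate --kind blob --n 50 --size 64 --seed 7 --out data/
genseg evaluate run.yaml        # methods, seeds, OOD shift in run.yaml
genseg report runs/experiment/summary.json
```

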