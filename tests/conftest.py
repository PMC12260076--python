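"""Shared fixtures: tiny datasets and models reused across the suite."""

import numpy as np
import pytest

from genseg.augmentation import AugmentConfig
from genseg.fixtures import ShapeDatasetConfig, generate_shape_dataset
from genseg.mlo import MLOConfig, ModelConfig, build_models, draw_batches


@pytest.fixture(scope="session")
def tiny_datasets():
    """16×16 blob datasets small enough for exhaustive checks."""
    d_tr = generate_shape_dataset(ShapeDatasetConfig(
        n=4, image_size=16, seed=11, noise_sd=0.1))
    d_val = generate_shape_dataset(ShapeDatasetConfig(
        n=3, image_size=16, seed=12, noise_sd=0.1, split="validation"))
    return d_tr, d_val


@pytest.fixture(scope="session")
def toy_datasets():
    """The 32×32 desk-scale study splits (10 train / 5 val / 30 test)."""
    d_tr = generate_shape_dataset(ShapeDatasetConfig(n=10, image_size=32, seed=100))
    d_val = generate_shape_dataset(ShapeDatasetConfig(
        n=5, image_size=32, seed=101, split="validation"))
    d_te = generate_shape_dataset(ShapeDatasetConfig(
        n=30, image_size=32, seed=102, split="test"))
    return d_tr, d_val, d_te


def small_model_cfg(image_size=16, act="tanh"):
    """Sub-thousand-parameter models for gradient checks (smooth activations)."""
    return ModelConfig(image_size=image_size, gen_depth=2, gen_width=2,
                       disc_width=2, disc_layers=1, seg_depth=2, seg_width=2,
                       act=act)


@pytest.fixture()
def tiny_setup(tiny_datasets):
    """Built models + one drawn batch on the 16×16 data (double precision)."""
    d_tr, d_val = tiny_datasets
    cfg = MLOConfig.toy(iterations=1, seed=0)
    cfg.dtype = "float64"
    cfg.batch_size = 2
    gen, arch, disc, seg = build_models(small_model_cfg(), dtype=np.float64)
    rng = np.random.default_rng(0)
    gp, hp, sp = gen.init_params(rng), disc.init_params(rng), seg.init_params(rng)
    batch = draw_batches(d_tr, d_val, cfg, AugmentConfig.disabled(),
                         np.random.default_rng(3))
    return dict(cfg=cfg, gen=gen, arch=arch, disc=disc, seg=seg,
                gp=gp, hp=hp, sp=sp, batch=batch, d_tr=d_tr, d_val=d_val)
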