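"""The trilevel solver: one-step update closed forms, hypergradient against
finite differences, zero-rate degeneracies, and training-loop contracts."""

import numpy as np
import pytest

from genseg import autodiff as ad
from genseg.augmentation import AugmentConfig
from genseg.autodiff import Tensor, grad
from genseg.fixtures import ShapeDatasetConfig, generate_shape_dataset
from genseg.genmodel import discretize_architecture, generate_image
from genseg.mlo import (MLOConfig, ModelConfig, TrainState,
                        architecture_gradient, build_models, draw_batches,
                        mlo_iteration, synthesize_training_set, train_genseg,
                        train_separate, train_vanilla,
                        unrolled_validation_loss, virtual_gan_step,
                        virtual_seg_step)

from conftest import small_model_cfg


class _LogitSeg:
    """Stub segmenter: class-1 score = w everywhere, class-0 score = 0.

    With an all-ones target mask the pixel loss is softplus(-w), so the
    one-step update has the closed form w' = w + η·σ(-w).
    """

    def forward(self, images, params):
        n, _, h, w_ = images.shape
        z = ad.mul(params["w"], Tensor(np.ones((n, 1, h, w_))))
        return ad.concat([Tensor(np.zeros((n, 1, h, w_))), z], axis=1)


class TestVirtualSegStep:
    def _data(self, n=2, size=4):
        imgs = Tensor(np.zeros((n, 1, size, size)))
        masks = np.ones((n, size, size), dtype=np.int64)
        return imgs, masks

    def test_scalar_closed_form(self):
        w0, eta = 0.3, 0.25
        s = {"w": Tensor(np.array(w0), requires_grad=True)}
        s1, _ = virtual_seg_step(_LogitSeg(), s, self._data(), self._data(),
                                 gamma=0.0, eta_s=eta)
        expected = w0 + eta / (1.0 + np.exp(w0))   # w + η·σ(-w)
        assert s1["w"].item() == pytest.approx(expected, rel=1e-12)

    def test_zero_rate_is_identity(self):
        s = {"w": Tensor(np.array(0.7), requires_grad=True)}
        s1, _ = virtual_seg_step(_LogitSeg(), s, self._data(), self._data(),
                                 gamma=1.0, eta_s=0.0)
        assert s1["w"].item() == 0.7

    def test_gamma_zero_ignores_real_data(self):
        s = {"w": Tensor(np.array(0.1), requires_grad=True)}
        d_hat = self._data()
        other = (Tensor(np.full((2, 1, 4, 4), 9.0)),
                 np.zeros((2, 4, 4), dtype=np.int64))
        a, _ = virtual_seg_step(_LogitSeg(), s, d_hat, self._data(), 0.0, 0.2)
        b, _ = virtual_seg_step(_LogitSeg(), s, d_hat, other, 0.0, 0.2)
        assert a["w"].item() == b["w"].item()

    def test_gamma_weights_real_term_per_objective(self):
        # with both terms identical, gradient scales by (1 + γ)
        s0 = {"w": Tensor(np.array(0.0), requires_grad=True)}
        a, _ = virtual_seg_step(_LogitSeg(), s0, self._data(), self._data(), 0.0, 0.1)
        s0 = {"w": Tensor(np.array(0.0), requires_grad=True)}
        b, _ = virtual_seg_step(_LogitSeg(), s0, self._data(), self._data(), 1.0, 0.1)
        assert (b["w"].item()) == pytest.approx(2 * a["w"].item(), rel=1e-12)


class TestVirtualGanStep:
    def test_zero_rates_are_identity(self, tiny_setup):
        t = tiny_setup
        g1, h1, _ = virtual_gan_step(t["gen"], t["disc"], t["gp"], t["hp"],
                                     t["arch"], t["batch"], 0.0, 0.0)
        for k in t["gp"]:
            np.testing.assert_array_equal(g1[k].data, t["gp"][k].data)
        for k in t["hp"]:
            np.testing.assert_array_equal(h1[k].data, t["hp"][k].data)

    def test_update_matches_finite_difference_gradient(self, tiny_setup):
        """G' == G − η·(central-difference gradient) to high precision."""
        from genseg.genmodel import minimax_gan_objective
        t = tiny_setup
        eta = 0.1
        g1, _, _ = virtual_gan_step(t["gen"], t["disc"], t["gp"], t["hp"],
                                    t["arch"], t["batch"], eta, 0.0)

        def l_gan():
            fake = generate_image(t["gen"], t["arch"], t["batch"].gan_masks, t["gp"])
            return minimax_gan_objective(
                t["disc"], t["hp"],
                (t["batch"].gan_images, t["batch"].gan_masks),
                (fake, t["batch"].gan_masks)).item()

        name = "enc0.op0.w"
        h = 1e-6
        rng = np.random.default_rng(0)
        flat_ids = rng.choice(t["gp"][name].size, size=5, replace=False)
        for i in flat_ids:
            orig = t["gp"][name].data.flat[i]
            t["gp"][name].data.flat[i] = orig + h
            lp = l_gan()
            t["gp"][name].data.flat[i] = orig - h
            lm = l_gan()
            t["gp"][name].data.flat[i] = orig
            fd = (lp - lm) / (2 * h)
            expected = orig - eta * fd
            assert g1[name].data.flat[i] == pytest.approx(expected, rel=1e-6, abs=1e-10)


class TestSynthesize:
    def test_counts_and_mask_passthrough(self, tiny_setup):
        t = tiny_setup
        masks = np.stack([p.mask for p in t["d_tr"]])
        imgs, out_masks = synthesize_training_set(t["gen"], t["arch"], t["gp"], masks)
        assert imgs.shape[0] == len(t["d_tr"])
        np.testing.assert_array_equal(out_masks, masks)  # identity augmentation

    def test_reproducible_with_fixed_rng(self, tiny_setup):
        t = tiny_setup
        masks = np.stack([p.mask for p in t["d_tr"]])
        cfg = AugmentConfig()
        a = synthesize_training_set(t["gen"], t["arch"], t["gp"], masks, cfg,
                                    np.random.default_rng(3))
        b = synthesize_training_set(t["gen"], t["arch"], t["gp"], masks, cfg,
                                    np.random.default_rng(3))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1], b[1])

    def test_requires_rng_when_augmenting(self, tiny_setup):
        t = tiny_setup
        with pytest.raises(ValueError):
            synthesize_training_set(t["gen"], t["arch"], t["gp"],
                                    t["d_tr"][0].mask, AugmentConfig())


class TestArchitectureGradient:
    def test_matches_finite_differences(self, tiny_setup):
        t = tiny_setup
        cfg = t["cfg"]
        cfg.eta_g = cfg.eta_s = 0.5   # amplify the second-order signal
        g_ad = architecture_gradient(t["gen"], t["disc"], t["seg"], t["gp"],
                                     t["hp"], t["sp"], t["arch"], t["batch"], cfg)
        synth_alphas = Tensor(t["arch"].alphas_data())
        base = t["arch"].logits.data.copy()

        def lval(logits):
            a = type(t["arch"])(Tensor(logits))
            return unrolled_validation_loss(
                t["gen"], t["disc"], t["seg"], t["gp"], t["hp"], t["sp"],
                a, t["batch"], cfg, synth_alphas=synth_alphas).item()

        h = 1e-4
        fd = np.zeros_like(base)
        for i in range(base.shape[0]):
            for k in range(base.shape[1]):
                up, dn = base.copy(), base.copy()
                up[i, k] += h
                dn[i, k] -= h
                fd[i, k] = (lval(up) - lval(dn)) / (2 * h)
        rel = np.abs(g_ad.data - fd).max() / max(np.abs(fd).max(), 1e-300)
        assert rel < 1e-4

    @pytest.mark.parametrize("which", ["eta_g", "eta_s"])
    def test_zero_rate_kills_gradient_exactly(self, tiny_setup, which):
        t = tiny_setup
        cfg = t["cfg"]
        setattr(cfg, which, 0.0)
        g = architecture_gradient(t["gen"], t["disc"], t["seg"], t["gp"],
                                  t["hp"], t["sp"], t["arch"], t["batch"], cfg)
        assert np.abs(g.data).max() == 0.0

    def test_discretized_architecture_rejected(self, tiny_setup):
        t = tiny_setup
        hard = discretize_architecture(t["arch"])
        with pytest.raises(ValueError):
            architecture_gradient(t["gen"], t["disc"], t["seg"], t["gp"],
                                  t["hp"], t["sp"], hard, t["batch"], t["cfg"])

    def test_first_order_mode_gives_finite_nonzero_gradient(self, tiny_setup):
        t = tiny_setup
        cfg = t["cfg"]
        cfg.hypergradient_mode = "first-order"
        g = architecture_gradient(t["gen"], t["disc"], t["seg"], t["gp"],
                                  t["hp"], t["sp"], t["arch"], t["batch"], cfg)
        assert np.all(np.isfinite(g.data))
        assert np.abs(g.data).max() > 0


def _short_cfg(iterations, seed=0, **kw):
    cfg = MLOConfig.toy(iterations=iterations, seed=seed)
    cfg.batch_size = 2
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestTrainingLoops:
    def test_frozen_arch_rate_keeps_logits_fixed(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        cfg = _short_cfg(50, eta_a=0.0)
        state = train_genseg(d_tr, d_val, cfg, small_model_cfg(act="lrelu"))
        np.testing.assert_array_equal(state.arch.logits.data,
                                      np.zeros_like(state.arch.logits.data))

    def test_single_iteration_records_once_and_checkpoints(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        state = train_genseg(d_tr, d_val, _short_cfg(1), small_model_cfg(act="lrelu"))
        assert len(state.history) == 1
        assert state.best_checkpoint is not None
        assert state.best_metric == state.val_history[-1]["val_metric"]

    def test_identical_seeds_give_identical_checkpoints(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        a = train_genseg(d_tr, d_val, _short_cfg(5, seed=3), small_model_cfg(act="lrelu"))
        b = train_genseg(d_tr, d_val, _short_cfg(5, seed=3), small_model_cfg(act="lrelu"))
        assert a.history == b.history
        np.testing.assert_array_equal(a.arch.logits.data, b.arch.logits.data)
        for k in a.best_checkpoint["s"]:
            np.testing.assert_array_equal(a.best_checkpoint["s"][k],
                                          b.best_checkpoint["s"][k])

    def test_checkpoint_metric_is_running_maximum(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        for trainer in (train_genseg, train_separate):
            state = trainer(d_tr, d_val, _short_cfg(12, seed=1),
                            small_model_cfg(act="lrelu"))
            best = max(r["val_metric"] for r in state.val_history)
            assert state.best_metric == best
            assert state.best_checkpoint["val_metric"] == best

    def test_separate_never_updates_architecture(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        state = train_separate(d_tr, d_val, _short_cfg(10), small_model_cfg(act="lrelu"))
        np.testing.assert_array_equal(state.arch.logits.data,
                                      np.zeros_like(state.arch.logits.data))

    def test_trainers_share_checkpoint_interface(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        states = [trainer(d_tr, d_val, _short_cfg(4), small_model_cfg(act="lrelu"))
                  for trainer in (train_genseg, train_separate)]
        states.append(train_vanilla(d_tr, d_val, _short_cfg(4),
                                    small_model_cfg(act="lrelu")))
        for st in states:
            assert isinstance(st, TrainState)
            assert st.best_checkpoint is not None
            assert set(st.best_checkpoint) >= {"s", "logits", "val_metric"}

    def test_empty_split_rejected(self, tiny_datasets):
        from genseg.fixtures import SegDataset
        d_tr, d_val = tiny_datasets
        with pytest.raises(ValueError):
            train_genseg(SegDataset([]), d_val, _short_cfg(1))

    def test_checkpoint_file_roundtrip(self, tiny_datasets, tmp_path):
        from genseg.mlo import load_checkpoint
        d_tr, d_val = tiny_datasets
        state = train_genseg(d_tr, d_val, _short_cfg(3), small_model_cfg(act="lrelu"))
        state.save_checkpoint(tmp_path / "best.npz")
        back = load_checkpoint(tmp_path / "best.npz")
        assert back["val_metric"] == state.best_checkpoint["val_metric"]
        assert back["iteration"] == state.best_checkpoint["iteration"]
        for k, v in state.best_checkpoint["s"].items():
            np.testing.assert_array_equal(back["s"][k], v)
        np.testing.assert_array_equal(back["logits"], state.best_checkpoint["logits"])

    def test_losses_stay_finite_through_training(self, tiny_datasets):
        d_tr, d_val = tiny_datasets
        state = train_genseg(d_tr, d_val, _short_cfg(10), small_model_cfg(act="lrelu"))
        for row in state.history:
            for key in ("loss_d", "loss_g", "loss_seg", "loss_val"):
                assert np.isfinite(row[key])
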