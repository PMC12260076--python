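"""Cell algebra, architecture-weight normalization, generator contracts,
discriminator scores, and adversarial-loss closed forms."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from genseg import autodiff as ad
from genseg.autodiff import Tensor, grad
from genseg.genmodel import (DEFAULT_POOL, ArchWeights, CandidateOp, CellSpec,
                             adversarial_losses_from_scores,
                             build_discriminator, build_searchable_generator,
                             cell_forward, discretize_architecture,
                             discriminator_scores, gan_losses, generate_image,
                             init_cell_params, normalize_alphas, one_hot_masks)


class TestNormalizeAlphas:
    def test_equal_logits_give_uniform(self):
        a = normalize_alphas(Tensor(np.zeros((2, 3))))
        np.testing.assert_allclose(a.data, 1 / 3)

    def test_dominant_logit_saturates(self):
        a = normalize_alphas(Tensor(np.array([[10.0, 0.0, 0.0]])))
        assert a.data[0, 0] > 0.999

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        a = normalize_alphas(Tensor(rng.standard_normal((5, 3)) * 10))
        np.testing.assert_allclose(a.data.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(a.data > 0) and np.all(a.data < 1)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError):
            normalize_alphas(Tensor(np.array([[np.nan, 0.0, 0.0]])))


class TestDiscretize:
    def test_argmax_retained(self):
        arch = ArchWeights(Tensor(np.log(np.array([[0.7, 0.2, 0.1]]))))
        out = discretize_architecture(arch)
        np.testing.assert_array_equal(out._onehot, [[1.0, 0.0, 0.0]])

    def test_ties_break_to_lowest_index(self):
        arch = ArchWeights(Tensor(np.array([[1.0, 1.0, -30.0], [0.0, 0.0, 0.0]])))
        out = discretize_architecture(arch)
        np.testing.assert_array_equal(out._onehot, [[1, 0, 0], [1, 0, 0]])


class TestCellAlgebra:
    def _bare_cell(self, kind="conv", in_ch=1, out_ch=1):
        ops = tuple(CandidateOp(kind, k, s, p) for k, s, p in DEFAULT_POOL)
        return CellSpec(ops, in_ch, out_ch, norm="none", act="identity")

    def test_all_candidates_share_output_shape(self):
        rng = np.random.default_rng(1)
        for kind, hw_out in [("conv", 4), ("upconv", 16)]:
            spec = self._bare_cell(kind, 2, 3)
            params = init_cell_params(rng, spec, "c")
            x = Tensor(rng.standard_normal((1, 2, 8, 8)))
            shapes = set()
            for k in range(spec.K):
                onehot = np.zeros((1, 3))
                onehot[0, k] = 1.0
                y = cell_forward(x, spec, Tensor(onehot[0]), params, "c")
                shapes.add(y.shape)
            assert shapes == {(1, 3, hw_out, hw_out)}

    def test_one_hot_alpha_collapses_exactly(self):
        rng = np.random.default_rng(2)
        spec = self._bare_cell("conv", 2, 2)
        params = init_cell_params(rng, spec, "c")
        x = Tensor(rng.standard_normal((1, 2, 8, 8)))
        for k, op in enumerate(spec.candidates):
            onehot = np.eye(3)[k]
            y = cell_forward(x, spec, Tensor(onehot), params, "c")
            from genseg import nn
            direct = nn.conv2d(x, params[f"c.op{k}.w"], params[f"c.op{k}.b"],
                               op.stride, op.padding)
            np.testing.assert_array_equal(y.data, direct.data)

    def test_zero_weights_give_zero_output(self):
        spec = self._bare_cell("conv", 1, 1)
        params = {f"c.op{k}.w": Tensor(np.zeros((1, 1, kk, kk)))
                  for k, kk in enumerate((4, 6, 8))}
        params.update({f"c.op{k}.b": Tensor(np.zeros(1)) for k in range(3)})
        y = cell_forward(Tensor(np.ones((1, 1, 8, 8))), spec,
                         Tensor(np.array([0.2, 0.5, 0.3])), params, "c")
        np.testing.assert_array_equal(y.data, 0.0)

    def test_linear_in_alpha(self):
        rng = np.random.default_rng(3)
        spec = self._bare_cell("conv", 1, 2)
        params = init_cell_params(rng, spec, "c")
        x = Tensor(rng.standard_normal((1, 1, 8, 8)))
        a1 = np.array([0.5, 0.3, 0.2])
        a2 = np.array([0.1, 0.1, 0.8])
        y1 = cell_forward(x, spec, Tensor(a1), params, "c").data
        y2 = cell_forward(x, spec, Tensor(a2), params, "c").data
        ymix = cell_forward(x, spec, Tensor(0.25 * a1 + 0.75 * a2), params, "c").data
        np.testing.assert_allclose(ymix, 0.25 * y1 + 0.75 * y2, rtol=1e-10, atol=1e-12)

    def test_mixture_matches_direct_convolution_oracle_on_4x4(self):
        """Hand-set kernels on a 4×4 input against scipy cross-correlation."""
        rng = np.random.default_rng(4)
        spec = self._bare_cell("conv", 1, 1)
        params = init_cell_params(rng, spec, "c")
        x0 = rng.standard_normal((1, 1, 4, 4))
        alphas = np.array([0.5, 0.3, 0.2])
        y = cell_forward(Tensor(x0), spec, Tensor(alphas), params, "c")
        expected = np.zeros((1, 1, 2, 2))
        for k, (kk, s, p) in enumerate(DEFAULT_POOL):
            w = params[f"c.op{k}.w"].data[0, 0]
            xp = np.pad(x0[0, 0], p)
            full = correlate2d(xp, w, mode="valid")[::s, ::s]
            expected[0, 0] += alphas[k] * (full + params[f"c.op{k}.b"].data[0])
        np.testing.assert_allclose(y.data, expected, rtol=1e-9, atol=1e-6)

    def test_incompatible_candidates_rejected(self):
        with pytest.raises(ValueError):
            CellSpec((CandidateOp("conv", 4, 2, 1), CandidateOp("conv", 3, 1, 1)), 1, 1)
        with pytest.raises(ValueError):
            CellSpec((CandidateOp("conv", 5, 2, 1),), 1, 1)  # k - 2p != s


class TestGenerator:
    def test_bottleneck_size_from_stride_arithmetic(self):
        gen, arch = build_searchable_generator(64, depth=4, base_width=2)
        # 64 -> 32 -> 16 -> 8 -> 4 through four halving cells
        rng = np.random.default_rng(0)
        params = gen.init_params(rng)
        x = one_hot_masks(np.zeros((1, 64, 64), dtype=np.int64), 2)
        h = x
        for i, spec in enumerate(gen.encoder_cells):
            h = cell_forward(h, spec, arch.alphas()[i], params, f"enc{i}")
        assert h.shape[2:] == (4, 4)

    def test_forward_contract_shape_and_range(self):
        gen, arch = build_searchable_generator(16, depth=2, base_width=2)
        params = gen.init_params(np.random.default_rng(0))
        mask = generate_masks(16)
        img = generate_image(gen, arch, mask, params)
        assert img.shape == (1, 1, 16, 16)
        assert img.data.min() >= -1.0 and img.data.max() <= 1.0

    def test_depth_zero_and_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            build_searchable_generator(16, depth=0)
        with pytest.raises(ValueError):
            build_searchable_generator(48, depth=5)

    def test_generation_is_deterministic(self):
        gen, arch = build_searchable_generator(16, depth=2, base_width=2)
        params = gen.init_params(np.random.default_rng(0))
        mask = generate_masks(16)
        a = generate_image(gen, arch, mask, params)
        b = generate_image(gen, arch, mask, params)
        np.testing.assert_array_equal(a.data, b.data)

    def test_all_background_mask_accepted(self):
        gen, arch = build_searchable_generator(16, depth=2, base_width=2)
        params = gen.init_params(np.random.default_rng(0))
        img = generate_image(gen, arch, np.zeros((16, 16), dtype=np.int64), params)
        assert np.all(np.isfinite(img.data))

    def test_unknown_label_rejected(self):
        gen, arch = build_searchable_generator(16, depth=2, base_width=2)
        params = gen.init_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_image(gen, arch, np.full((16, 16), 7, dtype=np.int64), params)

    def test_discretized_forward_equals_single_branch_network(self):
        """One-hot α everywhere collapses the mixture to a plain network
        built from only the retained kernels."""
        gen, arch = build_searchable_generator(16, depth=2, base_width=2)
        params = gen.init_params(np.random.default_rng(1))
        rng = np.random.default_rng(2)
        arch.logits.data[:] = rng.standard_normal(arch.logits.shape) * 3
        hard = discretize_architecture(arch)
        mask = generate_masks(16)
        mixture = generate_image(gen, hard, mask, params)

        # independent single-branch forward using only the argmax branches
        from genseg import nn
        keep = np.argmax(hard._onehot, axis=1)
        x = one_hot_masks(mask, 2)
        feats, h = [], x
        for i, spec in enumerate(gen.encoder_cells):
            k = keep[i]
            op = spec.candidates[k]
            h = nn.conv2d(h, params[f"enc{i}.op{k}.w"], params[f"enc{i}.op{k}.b"],
                          op.stride, op.padding)
            h = nn.activation(nn.instance_norm(h), spec.act)
            feats.append(h)
        n_enc = len(gen.encoder_cells)
        for i, spec in enumerate(gen.decoder_cells):
            if gen.skip and i > 0:
                h = ad.concat([h, feats[n_enc - 1 - i]], axis=1)
            k = keep[n_enc + i]
            op = spec.candidates[k]
            h = nn.conv_transpose2d(h, params[f"dec{i}.op{k}.w"],
                                    params[f"dec{i}.op{k}.b"], op.stride, op.padding)
            if spec.norm == "instance":
                h = nn.instance_norm(h)
            h = nn.activation(h, spec.act)
        single = ad.tanh(h)
        np.testing.assert_array_equal(mixture.data, single.data)


def generate_masks(size):
    m = np.zeros((size, size), dtype=np.int64)
    m[size // 4: size // 2, size // 4: size // 2] = 1
    return m


class TestAdversarialLosses:
    def test_half_scores_give_log_two(self):
        p = Tensor(np.full((2, 1, 2, 2), 0.5))
        l_d, l_g = adversarial_losses_from_scores(p, p)
        assert l_d.item() == pytest.approx(np.log(2), rel=1e-9)
        assert l_g.item() == pytest.approx(np.log(2), rel=1e-9)

    def test_perfect_discrimination_drives_l_d_to_zero(self):
        p_real = Tensor(np.full((2, 1, 1, 1), 1.0 - 1e-9))
        p_fake = Tensor(np.full((2, 1, 1, 1), 1e-9))
        l_d, _ = adversarial_losses_from_scores(p_real, p_fake)
        assert l_d.item() < 1e-6

    def test_hand_set_scores_match_scalar_oracle(self):
        # L_d = -(ln 0.8 + ln 0.7) / 2 for real score 0.8, fake score 0.3
        l_d, l_g = adversarial_losses_from_scores(Tensor(np.array([0.8])),
                                                  Tensor(np.array([0.3])))
        assert l_d.item() == pytest.approx(-(np.log(0.8) + np.log(0.7)) / 2, rel=1e-9)
        assert l_g.item() == pytest.approx(-np.log(0.3), rel=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_losses_from_scores(Tensor(np.zeros((0,))), Tensor(np.zeros((0,))))

    def test_gan_losses_through_discriminator_are_finite_and_backpropable(self):
        disc = build_discriminator(16, base_width=2, n_layers=1)
        h = disc.init_params(np.random.default_rng(0))
        rng = np.random.default_rng(1)
        imgs = Tensor(rng.standard_normal((2, 1, 16, 16)))
        masks = np.zeros((2, 16, 16), dtype=np.int64)
        l_d, l_g = gan_losses(disc, h, (imgs, masks), (imgs, masks))
        assert np.isfinite(l_d.item()) and np.isfinite(l_g.item())
        gs = grad(l_d, list(h.values()))
        assert all(np.all(np.isfinite(g.data)) for g in gs)

    def test_scores_lie_in_unit_interval(self):
        disc = build_discriminator(16, base_width=2, n_layers=1)
        h = disc.init_params(np.random.default_rng(0))
        imgs = Tensor(np.random.default_rng(2).standard_normal((3, 1, 16, 16)) * 10)
        p = discriminator_scores(disc, h, imgs, np.zeros((3, 16, 16), dtype=np.int64))
        assert np.all(p.data > 0) and np.all(p.data < 1)
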