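"""Architecture contracts: attention, modality fusion, ablations, shapes."""

import numpy as np
import pytest

from mcldti.network import (
    ConfigError,
    ConvBackbone,
    FeatureMap,
    MCLDTINet,
    ModelConfig,
    combine_modalities,
    resample_matrix,
)
from mcldti.nn.autograd import Tensor
from mcldti.nn.layers import MultiHeadAttention, seed_dropout


def naive_multihead(attn: MultiHeadAttention, q_in, kv_in, key_pad_mask=None):
    """Per-head cross/self-attention oracle: explicit loops, then concat."""
    def lin(layer, x):
        return x @ layer.weight.data + layer.bias.data

    B, Lq, d = q_in.shape
    H = attn.n_heads
    dh = d // H
    q_all, k_all, v_all = (lin(attn.wq, q_in), lin(attn.wk, kv_in),
                           lin(attn.wv, kv_in))
    outs = np.zeros((B, Lq, d))
    for b in range(B):
        per_head = []
        for h in range(H):
            sl = slice(h * dh, (h + 1) * dh)
            q, k, v = q_all[b, :, sl], k_all[b, :, sl], v_all[b, :, sl]
            logits = q @ k.T / np.sqrt(dh)
            if key_pad_mask is not None:
                logits[:, key_pad_mask[b]] = -np.inf
            w = np.exp(logits - logits.max(axis=-1, keepdims=True))
            w /= w.sum(axis=-1, keepdims=True)
            per_head.append(w @ v)
        outs[b] = np.concatenate(per_head, axis=-1)
    return lin(attn.wo, outs)


class TestMultiHeadAttention:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.attn = MultiHeadAttention(16, 4, 0.0, self.rng).eval()

    def test_rows_sum_to_one_over_unmasked_keys(self):
        q = Tensor(self.rng.normal(size=(3, 5, 16)))
        kv = Tensor(self.rng.normal(size=(3, 7, 16)))
        mask = np.zeros((3, 7), bool)
        mask[0, 4:] = True
        self.attn(q, kv, key_pad_mask=mask)
        rows = self.attn.last_attn.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_masked_keys_get_negligible_weight(self):
        q = Tensor(self.rng.normal(size=(2, 4, 16)))
        kv = Tensor(self.rng.normal(size=(2, 6, 16)))
        mask = np.zeros((2, 6), bool)
        mask[:, 3:] = True
        self.attn(q, kv, key_pad_mask=mask)
        assert self.attn.last_attn[:, :, :, 3:].max() < 1e-8

    def test_single_key_receives_full_weight(self):
        q = Tensor(self.rng.normal(size=(1, 5, 16)))
        kv = Tensor(self.rng.normal(size=(1, 1, 16)))
        self.attn(q, kv)
        np.testing.assert_array_equal(self.attn.last_attn, 1.0)

    def test_single_token_self_attention_weight_is_one(self):
        x = Tensor(self.rng.normal(size=(2, 1, 16)))
        self.attn(x, x)
        np.testing.assert_array_equal(self.attn.last_attn, 1.0)

    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_naive_per_head_oracle(self, masked):
        q_in = self.rng.normal(size=(2, 5, 16))
        kv_in = self.rng.normal(size=(2, 6, 16))
        mask = None
        if masked:
            mask = np.zeros((2, 6), bool)
            mask[1, 4:] = True
        got = self.attn(Tensor(q_in), Tensor(kv_in), key_pad_mask=mask).data
        expected = naive_multihead(self.attn, q_in, kv_in, key_pad_mask=mask)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_width_head_mismatch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(10, 4, 0.0, self.rng)


class TestConvBackbone:
    @pytest.mark.parametrize("h,n_tokens", [(224, 196), (64, 16), (48, 9)])
    def test_token_count_is_h_over_16_squared(self, h, n_tokens):
        cfg = ModelConfig(h=h, d_model=16, n_heads=2,
                          conv_channels=(4, 4, 8, 8))
        bb = ConvBackbone(cfg, np.random.default_rng(0)).eval()
        out = bb(Tensor(np.random.default_rng(1).random((1, 3, h, h))))
        assert out.tokens.shape == (1, n_tokens, 16)

    def test_spatially_constant_image_gives_identical_tokens(self):
        cfg = ModelConfig(h=48, d_model=16, n_heads=2,
                          conv_channels=(4, 4, 8, 8))
        bb = ConvBackbone(cfg, np.random.default_rng(0)).eval()
        out = bb(Tensor(np.full((1, 3, 48, 48), 0.25))).tokens.data[0]
        np.testing.assert_allclose(out, np.broadcast_to(out[0], out.shape),
                                   atol=1e-6)

    def test_h_not_divisible_by_16_rejected(self):
        with pytest.raises(ConfigError, match="divisible"):
            ModelConfig(h=50)


class TestCombineModalities:
    def _maps(self, rng, L_img=4, L_txt=6, d=8):
        img = FeatureMap(tokens=Tensor(rng.normal(size=(2, L_img, d))),
                         pad_mask=np.zeros(L_img, bool))
        txt = FeatureMap(tokens=Tensor(rng.normal(size=(2, L_txt, d))),
                         pad_mask=np.zeros(L_txt, bool))
        return img, txt

    def test_lambda_one_zero_reproduces_image_exactly(self):
        rng = np.random.default_rng(0)
        img, txt = self._maps(rng, L_img=6, L_txt=6)
        out = combine_modalities(img, txt, 1.0, 0.0)
        np.testing.assert_array_equal(out.tokens.data, img.tokens.data)

    def test_equal_unit_weights_double_identical_streams(self):
        rng = np.random.default_rng(1)
        img, _ = self._maps(rng, L_img=6, L_txt=6)
        same = FeatureMap(tokens=Tensor(img.tokens.data.copy()),
                          pad_mask=img.pad_mask)
        out = combine_modalities(img, same, 1.0, 1.0)
        np.testing.assert_allclose(out.tokens.data, 2 * img.tokens.data,
                                   rtol=1e-6)

    def test_arbitrary_weights_recompute_entrywise(self):
        rng = np.random.default_rng(2)
        img, txt = self._maps(rng)
        out = combine_modalities(img, txt, 0.3, 0.7)
        resampled = resample_matrix(4, 6) @ img.tokens.data
        np.testing.assert_allclose(out.tokens.data,
                                   0.3 * resampled + 0.7 * txt.tokens.data,
                                   rtol=1e-5, atol=1e-6)

    def test_single_modality_passes_through(self):
        rng = np.random.default_rng(3)
        img, txt = self._maps(rng)
        assert combine_modalities(img, None, 1.0, 1.0) is img
        assert combine_modalities(None, txt, 1.0, 1.0) is txt

    def test_resample_matrix_rows_average_to_one(self):
        for n_in, n_out in [(4, 6), (9, 48), (48, 9), (5, 5)]:
            m = resample_matrix(n_in, n_out)
            np.testing.assert_allclose(m.sum(axis=1), 1.0)


def _batch(cfg, rng, n=2):
    batch = {"labels": rng.integers(0, 2, n).astype(float)}
    if "image" in cfg.modalities:
        batch["drug_images"] = rng.random((n, cfg.channels, cfg.h, cfg.h))
    if "text" in cfg.modalities:
        batch["drug_tokens"] = rng.integers(2, 20, (n, cfg.L_drug))
        batch["drug_mask"] = np.zeros((n, cfg.L_drug), bool)
    batch["tgt_tokens"] = rng.integers(2, 20, (n, cfg.L_tgt))
    batch["tgt_mask"] = np.zeros((n, cfg.L_tgt), bool)
    return batch


class TestMCLDTINet:
    def _net(self, cfg, seed=0):
        return MCLDTINet(cfg, vocab_drug_size=30, vocab_tgt_size=30, seed=seed)

    def test_forward_probability_in_open_unit_interval(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        p = net(_batch(tiny_model_config, np.random.default_rng(0))).data
        assert np.all((p > 0) & (p < 1))

    def test_inference_is_deterministic(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        batch = _batch(tiny_model_config, np.random.default_rng(1))
        np.testing.assert_array_equal(net(batch).data, net(batch).data)

    def test_forward_finite_across_many_random_inputs(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        for seed in range(100):
            p = net(_batch(tiny_model_config, np.random.default_rng(seed),
                           n=1)).data
            assert np.all(np.isfinite(p))

    def test_swapping_fusion_inputs_changes_output(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        rng = np.random.default_rng(2)
        L, d = 6, tiny_model_config.d_model
        a = FeatureMap(tokens=Tensor(rng.normal(size=(1, L, d))))
        b = FeatureMap(tokens=Tensor(rng.normal(size=(1, L, d))))
        assert net.fuse_predict(a, b).data != net.fuse_predict(b, a).data

    def test_without_mca_drug_path_ignores_target(self, tiny_model_config):
        from dataclasses import replace

        cfg = replace(tiny_model_config, use_mca=False)
        net = self._net(cfg).eval()
        rng = np.random.default_rng(3)
        d = cfg.d_model
        x_drug = FeatureMap(tokens=Tensor(rng.normal(size=(1, 5, d))))
        t1 = FeatureMap(tokens=Tensor(rng.normal(size=(1, 7, d))))
        t2 = FeatureMap(tokens=Tensor(rng.normal(size=(1, 7, d))))
        z1, _ = net.decode_pair(x_drug, t1)
        z2, _ = net.decode_pair(x_drug, t2)
        np.testing.assert_array_equal(z1.tokens.data, z2.tokens.data)

    def test_with_mca_drug_path_depends_on_target(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        rng = np.random.default_rng(4)
        d = tiny_model_config.d_model
        x_drug = FeatureMap(tokens=Tensor(rng.normal(size=(1, 5, d))))
        t1 = FeatureMap(tokens=Tensor(rng.normal(size=(1, 7, d))))
        t2 = FeatureMap(tokens=Tensor(rng.normal(size=(1, 7, d))))
        z1, _ = net.decode_pair(x_drug, t1)
        z2, _ = net.decode_pair(x_drug, t2)
        assert np.abs(z1.tokens.data - z2.tokens.data).max() > 1e-6

    def test_decode_pair_output_shapes(self, tiny_model_config):
        net = self._net(tiny_model_config).eval()
        rng = np.random.default_rng(5)
        d = tiny_model_config.d_model
        x_drug = FeatureMap(tokens=Tensor(rng.normal(size=(2, 5, d))))
        x_tgt = FeatureMap(tokens=Tensor(rng.normal(size=(2, 7, d))))
        z_dt, z_td = net.decode_pair(x_drug, x_tgt)
        assert z_dt.tokens.shape == (2, 5, d)
        assert z_td.tokens.shape == (2, 7, d)

    def test_removing_mca_removes_exactly_its_parameters(self, tiny_model_config):
        from dataclasses import replace

        full = self._net(tiny_model_config)
        nomca = self._net(replace(tiny_model_config, use_mca=False))
        mca_params = sum(p.data.size for name, p in full.named_parameters()
                         if "_mca" in name)
        assert mca_params > 0
        assert full.n_parameters() - nomca.n_parameters() == mca_params

    def test_single_modality_removes_other_branch(self, tiny_model_config):
        from dataclasses import replace

        text_only = self._net(replace(tiny_model_config, modalities=("text",)))
        image_only = self._net(replace(tiny_model_config, modalities=("image",)))
        assert not any("backbone" in n or "img" in n
                       for n, _ in text_only.named_parameters())
        assert not any("txt_enc" in n for n, _ in image_only.named_parameters())

    def test_learnable_lambdas_receive_gradient(self, tiny_model_config):
        net = self._net(tiny_model_config)
        net.train()
        seed_dropout(net, np.random.default_rng(0))
        batch = _batch(tiny_model_config, np.random.default_rng(6), n=4)
        p = net(batch)
        loss = (p * p).sum()
        loss.backward()
        assert net.lam1.grad is not None and abs(net.lam1.grad) > 0
        assert net.lam2.grad is not None and abs(net.lam2.grad) > 0

    def test_fixed_lambda_mode_has_no_lambda_parameters(self, tiny_model_config):
        from dataclasses import replace

        cfg = replace(tiny_model_config, lambda_mode="fixed", lambda1=1.0,
                      lambda2=0.0)
        net = self._net(cfg)
        assert not any(name.startswith("lam")
                       for name, _ in net.named_parameters())

    def test_ddi_partner_shares_drug_encoder(self, tiny_model_config):
        from dataclasses import replace

        dti = self._net(tiny_model_config)
        ddi = self._net(replace(tiny_model_config, task="ddi"))
        assert not any("tgt_enc" in n for n, _ in ddi.named_parameters())
        assert ddi.n_parameters() < dti.n_parameters()

    def test_config_serialization_round_trip(self, tiny_model_config):
        restored = ModelConfig.from_dict(tiny_model_config.to_dict())
        assert restored == tiny_model_config


class TestModelConfigValidation:
    def test_rejects_empty_modalities(self):
        with pytest.raises(ConfigError):
            ModelConfig(modalities=())

    def test_rejects_unknown_lambda_mode(self):
        with pytest.raises(ConfigError):
            ModelConfig(lambda_mode="frozen")

    def test_rejects_indivisible_heads(self):
        with pytest.raises(ConfigError):
            ModelConfig(d_model=30, n_heads=4)
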