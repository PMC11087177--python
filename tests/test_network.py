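"""Architecture audits: path independence, shape schedule, probability
contract, channel attention."""

from __future__ import annotations

import numpy as np
import pytest

from rgmcmp.network import (
    AlignedInputs,
    ConfigurationError,
    ModelConfig,
    build_model,
    channel_attention,
    plan_encoder_shapes,
)


def small_cfg(variant, **kw):
    ch = 1 if variant in ("scsp", "unet3d") else 3
    return ModelConfig(variant=variant, in_channels=ch, base_filters=4, n_levels=3, **kw)


class TestModelConfig:
    def test_variant_channel_consistency_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="scsp", in_channels=3)
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="mcmp", in_channels=1)

    def test_unet3d_is_plain_isotropic(self):
        cfg = ModelConfig(variant="unet3d", in_channels=1)
        assert cfg.axial_preserving_steps == ()
        assert not cfg.use_channel_attention
        assert cfg.deep_supervision_heads == 0


class TestShapeSchedule:
    def test_clinical_grid_axial_schedule(self):
        # 4 downsamplings; the first and last leave the axial dimension
        # unchanged: axial 48,48,24,12,12; lateral halves at every step
        cfg = ModelConfig(variant="mcmp", in_channels=3, n_levels=5, base_filters=16)
        shapes = plan_encoder_shapes(cfg, (192, 160, 48))
        assert [s[2] for s in shapes] == [48, 48, 24, 12, 12]
        assert [s[0] for s in shapes] == [192, 96, 48, 24, 12]
        assert [s[1] for s in shapes] == [160, 80, 40, 20, 10]

    def test_forward_shapes_match_plan(self):
        cfg = small_cfg("mcmp")
        net = build_model(cfg, seed=0)
        x = np.random.default_rng(0).random((3, 24, 24, 16), dtype=np.float32)
        net.forward(x)
        assert net.last_encoder_shapes == plan_encoder_shapes(cfg, (24, 24, 16))


class TestPathIndependence:
    def test_mcmp_encoder_parameters_triple_scsp(self):
        mcmp = build_model(small_cfg("mcmp"), seed=0)
        scsp = build_model(small_cfg("scsp"), seed=0)
        assert mcmp.encoder_parameter_count() == 3 * scsp.encoder_parameter_count()

    def test_no_cross_path_mixing_before_decoder(self):
        # perturbing one input channel must leave the other paths' encoder
        # features untouched
        net = build_model(small_cfg("mcmp"), seed=1)
        rng = np.random.default_rng(1)
        x = rng.random((3, 16, 16, 8), dtype=np.float32)
        net.forward(x)
        # capture per-path bottleneck features
        feats = {}
        for p_idx, levels in enumerate(net.paths):
            from rgmcmp.nn.autodiff import Tensor

            h = Tensor(x[p_idx : p_idx + 1])
            for blocks in levels:
                for blk in blocks:
                    h = blk(h)
            feats[p_idx] = h.data.copy()
        x2 = x.copy()
        x2[0] += 1.0  # perturb channel 0 only
        for p_idx, levels in enumerate(net.paths):
            from rgmcmp.nn.autodiff import Tensor

            h = Tensor(x2[p_idx : p_idx + 1])
            for blocks in levels:
                for blk in blocks:
                    h = blk(h)
            if p_idx == 0:
                assert not np.allclose(h.data, feats[0])
            else:
                assert np.array_equal(h.data, feats[p_idx])

    def test_guidance_channel_is_live(self):
        # zeroing the propagated-contour channel changes the output of a
        # briefly trained model
        from rgmcmp.objective import total_loss
        from rgmcmp.training import Adam

        net = build_model(small_cfg("mcmp"), seed=2)
        rng = np.random.default_rng(2)
        x = rng.random((3, 16, 16, 8), dtype=np.float32)
        y = (rng.random((16, 16, 8)) > 0.7).astype(np.uint8)
        opt = Adam(net.params, 1e-3)
        for _ in range(3):
            net.zero_grad()
            loss = total_loss(net.forward(x), y)
            loss.backward()
            opt.step()
        p_full = net.forward(x).data
        x0 = x.copy()
        x0[1] = 0.0
        p_zeroed = net.forward(x0).data
        assert not np.allclose(p_full, p_zeroed)


class TestForward:
    @pytest.mark.parametrize("variant", ["unet3d", "scsp", "mcsp", "mcmp"])
    def test_output_is_valid_probability_map(self, variant):
        cfg = small_cfg(variant)
        net = build_model(cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((cfg.in_channels, 16, 16, 8), dtype=np.float32)
        p = net.forward(x)
        assert p.data.shape == (2, 16, 16, 8)
        assert np.all(p.data >= 0) and np.all(p.data <= 1)
        assert np.allclose(p.data.sum(axis=0), 1.0, atol=1e-5)

    def test_forward_deterministic(self):
        net = build_model(small_cfg("mcmp"), seed=0)
        x = np.random.default_rng(1).random((3, 16, 16, 8), dtype=np.float32)
        assert np.array_equal(net.forward(x).data, net.forward(x).data)

    def test_same_config_seed_same_init(self):
        a = build_model(small_cfg("mcmp"), seed=9)
        b = build_model(small_cfg("mcmp"), seed=9)
        assert all(np.array_equal(p.data, q.data) for p, q in zip(a.params, b.params))
        c = build_model(small_cfg("mcmp"), seed=10)
        assert any(not np.array_equal(p.data, q.data) for p, q in zip(a.params, c.params))

    def test_wrong_channel_count_rejected(self):
        net = build_model(small_cfg("mcmp"), seed=0)
        with pytest.raises(ValueError, match="channel"):
            net.forward(np.zeros((2, 16, 16, 8), np.float32))

    def test_aligned_inputs_container(self):
        net = build_model(small_cfg("mcmp"), seed=0)
        rng = np.random.default_rng(3)
        ai = AlignedInputs(
            act1=rng.random((16, 16, 8)),
            actv1=(rng.random((16, 16, 8)) > 0.8).astype(np.uint8),
            ct2=rng.random((16, 16, 8)),
        )
        p = net.forward(ai)
        assert p.data.shape == (2, 16, 16, 8)


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_config(self, tmp_path):
        from rgmcmp.network import describe, load_checkpoint, save_checkpoint

        net = build_model(small_cfg("mcmp"), seed=4)
        x = np.random.default_rng(0).random((3, 16, 16, 8), dtype=np.float32)
        before = net.forward(x).data
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path)
        assert back.cfg.to_dict() == net.cfg.to_dict()
        assert np.array_equal(back.forward(x).data, before)
        audit = describe(back)
        assert "encoder paths      : 3" in audit


class TestChannelAttention:
    def test_gates_depend_only_on_channel_means(self):
        # the squeeze step is a global average pool, so spatially permuting
        # the feature map leaves every gate unchanged
        rng = np.random.default_rng(0)
        f = rng.random((8, 6, 6, 6)).astype(np.float32)
        perm = rng.permutation(216)
        f_perm = f.reshape(8, -1)[:, perm].reshape(8, 6, 6, 6)
        g1 = channel_attention(f, reduction=4, seed=0) / np.maximum(f, 1e-12)
        g2 = channel_attention(f_perm, reduction=4, seed=0) / np.maximum(f_perm, 1e-12)
        assert np.allclose(g1.mean(axis=(1, 2, 3)), g2.mean(axis=(1, 2, 3)), atol=1e-5)

    def test_channelwise_scaling_contract(self):
        rng = np.random.default_rng(1)
        f = rng.random((8, 5, 5, 5)).astype(np.float32) + 0.1
        out = channel_attention(f, reduction=4, seed=1)
        ratios = out / f
        for c in range(8):
            assert np.allclose(ratios[c], ratios[c].flat[0], atol=1e-5)
            assert 0.0 < ratios[c].flat[0] < 1.0  # sigmoid gate

    def test_zero_input_zero_output(self):
        out = channel_attention(np.zeros((8, 4, 4, 4)), reduction=4, seed=0)
        assert np.all(out == 0)

    def test_excessive_reduction_rejected(self):
        with pytest.raises(ConfigurationError):
            channel_attention(np.ones((4, 2, 2, 2)), reduction=8, seed=0)
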