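"""Network blocks vs loop oracles, residual identities, and bookkeeping."""

import numpy as np
import pytest

from grrdb import nn
from grrdb.gnet import (
    DAB,
    ChannelAttention,
    ConfigError,
    DenseBlock,
    GhostConv,
    GhostLKABlock,
    LKABlock,
    ModelConfig,
    RRDB,
    SpatialAttention,
    build_grrdb,
    desk_config,
    load_checkpoint,
    save_checkpoint,
    variant_config,
)
from grrdb.nn import functional as F

from conftest import zero_all
from oracles import (
    naive_channel_pool,
    naive_conv2d,
    naive_dab_combine,
    naive_depthwise,
    naive_spatial_pool,
)


def _f64(module):
    """Promote a module's parameters to float64 for tight oracle comparison."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    return module


def _rand_x(rng, c=4, h=8, w=8, n=1):
    return rng.standard_normal((n, c, h, w))


class TestLKA:
    def test_matches_composition_oracle(self, rng, tiny_cfg):
        blk = _f64(LKABlock(tiny_cfg, rng))
        x = _rand_x(rng)
        y1 = naive_depthwise(x, blk.dw.weight.data, blk.dw.bias.data)
        y2 = naive_depthwise(y1, blk.dwd.weight.data, blk.dwd.bias.data, dilation=3)
        attn = naive_conv2d(y2, blk.pw.weight.data, blk.pw.bias.data)
        expected = attn * x
        got = blk(nn.Tensor(x)).data
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_identity_when_attention_is_one(self, rng, tiny_cfg):
        blk = zero_all(LKABlock(tiny_cfg, rng))
        blk.pw.bias.data = np.ones_like(blk.pw.bias.data)  # A == 1 everywhere
        x = _rand_x(rng)
        np.testing.assert_allclose(blk(nn.Tensor(x)).data, x, atol=1e-6)

    def test_zero_weights_give_zero_output(self, rng, tiny_cfg):
        blk = zero_all(LKABlock(tiny_cfg, rng))
        x = _rand_x(rng)
        assert np.all(blk(nn.Tensor(x)).data == 0)


class TestGhostConv:
    def test_parameter_count_savings(self, rng):
        ghost = GhostConv(64, 64, rng, ratio=2, kernel=3, bias=False)
        n_ghost = ghost.n_parameters()
        assert n_ghost == 64 * 32 * 9 + 32 * 1 * 9 == 18_720
        n_plain = 64 * 64 * 9
        assert n_plain == 36_864
        assert 1 - n_ghost / n_plain >= 0.49

    @pytest.mark.parametrize("ratio", [2, 4, 8])
    def test_strictly_fewer_params_than_plain(self, rng, ratio):
        ghost = GhostConv(32, 32, rng, ratio=ratio, kernel=3, bias=False)
        assert ghost.n_parameters() < 32 * 32 * 9

    @pytest.mark.parametrize("out_ch,ratio", [(8, 2), (12, 3), (8, 1)])
    def test_output_channels(self, rng, out_ch, ratio):
        ghost = GhostConv(4, out_ch, rng, ratio=ratio)
        y = ghost(nn.Tensor(_rand_x(rng)))
        assert y.shape == (1, out_ch, 8, 8)

    def test_ratio_one_is_plain_conv(self, rng):
        ghost = _f64(GhostConv(4, 4, rng, ratio=1, kernel=3))
        x = _rand_x(rng)
        expected = naive_conv2d(x, ghost.primary.weight.data, ghost.primary.bias.data)
        np.testing.assert_allclose(ghost(nn.Tensor(x)).data, expected, atol=1e-10)

    def test_concat_is_primary_then_cheap(self, rng):
        ghost = _f64(GhostConv(4, 8, rng, ratio=2))
        x = _rand_x(rng)
        p = naive_conv2d(x, ghost.primary.weight.data, ghost.primary.bias.data)
        q = naive_depthwise(p, ghost.cheap.weight.data, ghost.cheap.bias.data)
        np.testing.assert_allclose(ghost(nn.Tensor(x)).data,
                                   np.concatenate([p, q], axis=1), atol=1e-5)

    def test_indivisible_raises(self, rng):
        with pytest.raises(ConfigError, match="divisible"):
            GhostConv(4, 6, rng, ratio=4)


class TestGhostLKA:
    def test_zero_weights_identity(self, rng, tiny_cfg):
        blk = zero_all(GhostLKABlock(tiny_cfg, rng))
        x = _rand_x(rng)
        np.testing.assert_array_equal(blk(nn.Tensor(x)).data, x)

    def test_residual_decomposition(self, rng, tiny_cfg):
        """Removing the residual sum changes the output by exactly x."""
        blk = _f64(GhostLKABlock(tiny_cfg, rng))
        x = _rand_x(rng)
        full = blk(nn.Tensor(x)).data
        z = blk.ghost(blk.lka(nn.Tensor(x))).data
        np.testing.assert_allclose(full - z, x, atol=1e-10)

    def test_shape_preserved(self, rng, tiny_cfg):
        blk = GhostLKABlock(tiny_cfg, rng)
        for h, w in [(8, 8), (11, 9), (16, 32)]:
            y = blk(nn.Tensor(_rand_x(rng, h=h, w=w).astype(np.float32)))
            assert y.shape == (1, 4, h, w)


class TestDenseBlock:
    def test_zero_weights_identity(self, rng, tiny_cfg):
        blk = zero_all(DenseBlock(tiny_cfg, rng))
        x = _rand_x(rng)
        np.testing.assert_array_equal(blk(nn.Tensor(x)).data, x)

    def test_concatenation_widths(self, rng):
        cfg = ModelConfig(base_channels=8, n_conv_per_dense=5, ca_reduction=2)
        blk = DenseBlock(cfg, rng)
        # conv k consumes C + (k-1)*growth channels, growth = C/2 = 4
        widths = [conv.in_ch for conv in blk.convs]
        assert widths == [8 + k * 4 for k in range(5)]
        assert [conv.out_ch for conv in blk.convs] == [4, 4, 4, 4, 8]

    def test_matches_loop_oracle(self, rng, tiny_cfg):
        blk = _f64(DenseBlock(tiny_cfg, rng))
        x = _rand_x(rng)
        feats = [x]
        for k, conv in enumerate(blk.convs):
            inp = np.concatenate(feats, axis=1)
            y = naive_conv2d(inp, conv.weight.data, conv.bias.data)
            if k < len(blk.convs) - 1:
                y = np.where(y > 0, y, 0.2 * y)
                feats.append(y)
        expected = x + tiny_cfg.res_scale * y
        np.testing.assert_allclose(blk(nn.Tensor(x)).data, expected, atol=1e-5)

    def test_res_scale_zero_is_identity(self, rng):
        cfg = ModelConfig(base_channels=4, ca_reduction=2, res_scale=1e-300)
        blk = DenseBlock(cfg, rng)
        blk.res_scale = 0.0
        x = _rand_x(rng).astype(np.float32)
        np.testing.assert_array_equal(blk(nn.Tensor(x)).data, x)


class TestRRDB:
    def test_zero_weights_identity(self, rng, tiny_cfg):
        blk = zero_all(RRDB(tiny_cfg, rng))
        x = _rand_x(rng)
        np.testing.assert_array_equal(blk(nn.Tensor(x)).data, x)

    def test_outer_residual_formula(self, rng, tiny_cfg):
        blk = _f64(RRDB(tiny_cfg, rng))
        x = _rand_x(rng)
        d = nn.Tensor(x)
        for sub in blk.blocks:
            d = sub(d)
        expected = x + tiny_cfg.res_scale * (d.data - x)
        np.testing.assert_allclose(blk(nn.Tensor(x)).data, expected, atol=1e-10)

    def test_literal_variant_scales_chain(self, rng):
        cfg = ModelConfig(base_channels=4, ca_reduction=2, rrdb_literal_residual=True,
                          n_dense_per_rrdb=1, n_conv_per_dense=2)
        blk = zero_all(RRDB(cfg, rng))
        x = _rand_x(rng)
        # zero weights: chain(x) = x, so the literal form returns 1.2 * x
        np.testing.assert_allclose(blk(nn.Tensor(x)).data, 1.2 * x, atol=1e-12)


class TestAttention:
    def test_spatial_pools_match_loop_oracle(self, rng):
        x = _rand_x(rng)
        mean, mx = naive_spatial_pool(x)
        np.testing.assert_allclose(F.channel_mean(nn.Tensor(x)).data, mean, atol=1e-12)
        np.testing.assert_allclose(F.channel_max(nn.Tensor(x)).data, mx, atol=1e-12)

    def test_channel_pools_match_loop_oracle(self, rng):
        x = _rand_x(rng)
        avg, mx = naive_channel_pool(x)
        np.testing.assert_allclose(F.global_avg_pool(nn.Tensor(x)).data[..., 0, 0], avg, atol=1e-12)
        np.testing.assert_allclose(F.global_max_pool(nn.Tensor(x)).data[..., 0, 0], mx, atol=1e-12)

    def test_spatial_attention_zero_conv_halves_input(self, rng):
        sa = zero_all(SpatialAttention(rng))
        x = np.full((1, 4, 8, 8), 3.0)
        np.testing.assert_allclose(sa(nn.Tensor(x)).data, 0.5 * x, atol=1e-12)

    def test_spatial_attention_full_oracle(self, rng):
        sa = _f64(SpatialAttention(rng))
        x = _rand_x(rng)
        mean, mx = naive_spatial_pool(x)
        pooled = np.concatenate([mean, mx], axis=1)
        wmap = 1 / (1 + np.exp(-naive_conv2d(pooled, sa.conv.weight.data, sa.conv.bias.data)))
        np.testing.assert_allclose(sa(nn.Tensor(x)).data, x * wmap, atol=1e-5)

    def test_channel_attention_zero_weights_halves_input(self, rng):
        ca = zero_all(ChannelAttention(4, 2, rng))
        x = _rand_x(rng)
        np.testing.assert_allclose(ca(nn.Tensor(x)).data, 0.5 * x, atol=1e-12)

    def test_channel_attention_spatial_permutation_invariant(self, rng):
        ca = ChannelAttention(4, 2, rng)
        x = _rand_x(rng).astype(np.float32)
        perm = rng.permutation(64)
        xp = x.reshape(1, 4, 64)[:, :, perm].reshape(1, 4, 8, 8).copy()
        w_ref = ca(nn.Tensor(x)).data / x
        w_perm = ca(nn.Tensor(xp)).data / xp
        np.testing.assert_allclose(w_ref[..., 0, 0], w_perm[..., 0, 0], rtol=1e-5)

    def test_channel_attention_indivisible_raises(self, rng):
        with pytest.raises(ConfigError, match="divisible"):
            ChannelAttention(4, 3, rng)

    def test_attention_weights_strictly_inside_unit_interval(self, rng, tiny_cfg):
        dab = DAB(tiny_cfg, rng)
        x = _rand_x(rng, n=2).astype(np.float32)
        xa = F.add(dab.sa(nn.Tensor(x)), dab.ca(nn.Tensor(x)))
        w = dab.gate(xa).data
        assert np.all(w > 0) and np.all(w < 1)


class TestDAB:
    def test_combine_matches_loop_oracle(self, rng):
        shape = (1, 3, 5, 5)
        w = rng.uniform(0.01, 0.99, shape)
        s1, s2, xout = (rng.standard_normal(shape) for _ in range(3))
        got = DAB.combine(nn.Tensor(w), nn.Tensor(s1), nn.Tensor(s2), nn.Tensor(xout)).data
        np.testing.assert_allclose(got, naive_dab_combine(w, s1, s2, xout), atol=1e-6)

    def test_limits_of_gate(self, rng):
        shape = (1, 2, 4, 4)
        s1, s2, xout = (rng.standard_normal(shape) for _ in range(3))
        ones, zeros = np.ones(shape), np.zeros(shape)
        hi = DAB.combine(nn.Tensor(ones), nn.Tensor(s1), nn.Tensor(s2), nn.Tensor(xout)).data
        np.testing.assert_allclose(hi, s1 + s2, atol=1e-12)  # W==1 -> Xa
        lo = DAB.combine(nn.Tensor(zeros), nn.Tensor(s1), nn.Tensor(s2), nn.Tensor(xout)).data
        np.testing.assert_allclose(lo, 2 * xout, atol=1e-12)  # W==0 -> 2*Xout

    def test_literal_reading_differs(self, rng):
        shape = (1, 2, 4, 4)
        w = rng.uniform(0.2, 0.8, shape)
        s1, s2, xout = (rng.standard_normal(shape) for _ in range(3))
        lit = DAB.combine(nn.Tensor(w), nn.Tensor(s1), nn.Tensor(s2), nn.Tensor(xout), literal=True).data
        np.testing.assert_allclose(lit, naive_dab_combine(w, s1, s2, xout, literal=True), atol=1e-6)

    def test_forward_shape(self, rng, tiny_cfg):
        dab = DAB(tiny_cfg, rng)
        x = _rand_x(rng, n=2).astype(np.float32)
        assert dab(nn.Tensor(x)).shape == x.shape


class TestAssembledNetwork:
    def test_default_architecture_counts(self):
        model = build_grrdb(ModelConfig(), seed=0)
        assert len(model.ghost_lka) == 3
        assert len(model.rrdbs) == 5
        assert len(model.dabs) == 2
        assert all(b.res_scale == 0.2 for b in model.rrdbs)

    def test_identity_at_initialization(self, rng):
        """Zero-initialized tail + global skip: the fresh network is the
        identity on images (up to float32 casting of the input)."""
        model = build_grrdb(desk_config(), seed=1)
        x = rng.random((2, 32, 32)).astype(np.float32)
        y = model.denoise(x.astype(np.float64), clip=False)
        np.testing.assert_array_equal(y.astype(np.float32), x)

    def test_shape_preserved_various_sizes(self, rng):
        model = build_grrdb(desk_config(), seed=0)
        for h, w in [(16, 16), (17, 23), (32, 48)]:
            out = model.denoise(rng.random((h, w)))
            assert out.shape == (h, w)

    def test_parameter_count_matches_arithmetic_oracle(self):
        """Layer-by-layer parameter arithmetic for the tiny config."""
        cfg = ModelConfig(base_channels=8, n_ghost_lka=1, n_rrdb=1,
                          n_dense_per_rrdb=1, n_conv_per_dense=2,
                          ca_reduction=2, n_dab=1)
        model = build_grrdb(cfg, seed=0)
        C, g, red = 8, 4, 2
        head = (1 * 9 + 1) * C
        lka = (C * 25 + C) + (C * 49 + C) + (C * C + C)          # dw5, dwd7, pw
        ghost = (C * (C // 2) * 9 + C // 2) + ((C // 2) * 9 + C // 2)
        dense = (C * g * 9 + g) + ((C + g) * C * 9 + C)          # 2 convs
        sa = (2 * 49 + 1)
        ca = (C * C // red + C // red) + ((C // red) * C + C)
        dab = (C * C * 9 + C) + sa + ca + (C * C * 9 + C) + ca   # feat, sa, ca, local, glob
        tail = 2 * (C * C * 9 + C) + (C * 1 + 1)
        assert model.n_parameters() == head + lka + ghost + dense + dab + tail

    def test_every_parameter_receives_gradient(self, rng):
        """MSE on a random batch: all parameter gradients finite, not all zero."""
        cfg = ModelConfig(base_channels=8, n_ghost_lka=1, n_rrdb=1,
                          n_dense_per_rrdb=1, n_conv_per_dense=2,
                          ca_reduction=2, n_dab=1, global_skip=True)
        model = build_grrdb(cfg, seed=3)
        # leave the identity start: a zeroed output conv blocks upstream
        # gradients by construction, so emulate a mid-training state
        model.out_conv.weight.data = (
            0.1 * np.random.default_rng(9).standard_normal(model.out_conv.weight.shape)
        ).astype(np.float32)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        tgt = rng.random((2, 1, 16, 16)).astype(np.float32)
        loss = F.mse_loss(model(nn.Tensor(x)), nn.Tensor(tgt))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
            assert np.any(p.grad != 0), name

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="ghost_ratio"):
            ModelConfig(base_channels=30, ghost_ratio=4, ca_reduction=5)

    def test_variant_configs(self):
        base = variant_config("baseline")
        assert base.n_ghost_lka == 0 and base.n_dab == 0
        bdab = variant_config("baseline_dab")
        assert bdab.n_ghost_lka == 0 and bdab.n_dab == 2
        full = variant_config("grrdb")
        assert full.n_ghost_lka == 3 and full.n_dab == 2
        with pytest.raises(ConfigError):
            variant_config("nonsense")


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, rng, tmp_path):
        model = build_grrdb(desk_config(n_rrdb=1, n_ghost_lka=1, n_dab=1), seed=4)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        x = rng.random((1, 24, 24))
        np.testing.assert_array_equal(model.denoise(x), clone.denoise(x))

    def test_config_mismatch_rejected(self, tmp_path):
        model = build_grrdb(desk_config(n_rrdb=1, n_ghost_lka=0, n_dab=0), seed=0)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        with pytest.raises(ConfigError, match="match"):
            load_checkpoint(path, cfg=desk_config(n_rrdb=2, n_ghost_lka=0, n_dab=0))
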