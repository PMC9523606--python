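"""Shape contracts, fusion bookkeeping, channel-attention oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafshot as ls
from leafshot import autodiff as ad
from leafshot.autodiff import Tensor
from leafshot.encoder import cascade_fuse, parallel_fuse


def ceil_half(x):
    return -(-x // 2)


class TestMultiscaleTaps:
    @pytest.mark.parametrize(
        "size,expected_spatial",
        [(32, [16, 8, 4, 2]), (84, [42, 21, 11, 6])],
    )
    def test_tap_shapes_follow_halve_double_rule(self, size, expected_spatial):
        enc = ls.Encoder(ls.EncoderConfig(base_width=4), seed=0)
        with ad.no_grad():
            maps = enc.extract_multiscale(
                Tensor(np.zeros((1, 3, size, size), np.float32))
            )
        for i, (m, s) in enumerate(zip(maps, expected_spatial)):
            assert m.shape == (1, 4 * 2 ** i, s, s)

    def test_resnet12_same_contract(self):
        enc = ls.Encoder(
            ls.EncoderConfig(backbone="resnet12", base_width=4), seed=0
        )
        with ad.no_grad():
            maps = enc.extract_multiscale(
                Tensor(np.zeros((1, 3, 20, 20), np.float32))
            )
        sizes = [20, 10, 5, 3]
        for i, m in enumerate(maps):
            assert m.shape == (1, 4 * 2 ** i, ceil_half(sizes[i]), ceil_half(sizes[i]))

    def test_too_small_input_rejected(self):
        enc = ls.Encoder(ls.EncoderConfig(base_width=4), seed=0)
        with pytest.raises(ValueError, match="spatial"):
            enc.extract_multiscale(Tensor(np.zeros((1, 3, 8, 8), np.float32)))

    def test_zero_image_gives_finite_activations(self, small_encoder):
        with ad.no_grad():
            out = small_encoder(Tensor(np.zeros((2, 3, 32, 32), np.float32)))
        assert np.isfinite(out.data).all()

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(h=st.integers(16, 40), w=st.integers(16, 40))
    def test_shape_contract_any_input_size(self, h, w):
        enc = ls.Encoder(ls.EncoderConfig(base_width=2, attention="none"), seed=0)
        with ad.no_grad():
            maps = enc.extract_multiscale(
                Tensor(np.zeros((1, 3, h, w), np.float32))
            )
            fused = enc.fuse(maps)
        hh, ww = h, w
        for i, m in enumerate(maps):
            hh, ww = ceil_half(hh), ceil_half(ww)
            assert m.shape == (1, 2 * 2 ** i, hh, ww)
        assert fused.shape == (1, 15 * 2, maps[0].shape[2], maps[0].shape[3])


def _fake_maps(rng, c=4, h=8, w=8, constant=None):
    maps = []
    for i in range(4):
        shape = (2, c * 2 ** i, ceil_half(h) if i else h, ceil_half(w) if i else w)
        h, w = shape[2], shape[3]
        if constant is None:
            data = rng.normal(size=shape).astype(np.float32)
        else:
            data = np.full(shape, constant, np.float32)
        maps.append(Tensor(data))
    from leafshot.encoder import FeatureMapSet
    return FeatureMapSet(maps)


class TestFusion:
    def test_cascaded_channel_bookkeeping(self):
        maps = _fake_maps(np.random.default_rng(0), c=64, h=16, w=16)
        f = cascade_fuse(maps)
        assert f.shape == (2, 15 * 64, 16, 16)

    def test_parallel_matches_cascaded_shape_and_channel_set(self):
        maps = _fake_maps(np.random.default_rng(1), c=4, h=16, w=16)
        fc = cascade_fuse(maps).data
        fp = parallel_fuse(maps).data
        assert fc.shape == fp.shape == (2, 60, 16, 16)
        # with exact power-of-two sizes the channel contents coincide
        assert np.allclose(np.sort(fc, axis=1), np.sort(fp, axis=1))

    def test_constant_maps_propagate_unchanged(self):
        maps = _fake_maps(np.random.default_rng(2), c=3, h=8, w=8, constant=0.7)
        for fuse in (cascade_fuse, parallel_fuse):
            f = fuse(maps)
            assert np.allclose(f.data, 0.7)

    def test_fusion_none_is_deepest_map(self):
        enc = ls.Encoder(
            ls.EncoderConfig(base_width=4, fusion="none", attention="none"),
            seed=0,
        )
        x = Tensor(np.random.default_rng(3).normal(size=(1, 3, 32, 32)).astype(np.float32))
        with ad.no_grad():
            maps = enc.extract_multiscale(x)
            f = enc.fuse(maps)
        assert np.array_equal(f.data, maps[3].data)


class TestChannelAttention:
    def test_zero_mlp_gives_half_gate(self):
        ca = ls.ChannelAttention(8, 2, np.random.default_rng(0))
        ca.fc1.weight.data[...] = 0.0
        ca.fc2.weight.data[...] = 0.0
        f = Tensor(np.random.default_rng(1).normal(size=(3, 8, 4, 4)).astype(np.float32))
        m, out = ca(f)
        assert np.allclose(m.data, 0.5)
        assert np.allclose(out.data, f.data / 2, atol=1e-6)

    def test_spatially_constant_input_doubles_mlp(self):
        ca = ls.ChannelAttention(4, 2, np.random.default_rng(2))
        v = np.random.default_rng(3).normal(size=(1, 4)).astype(np.float32)
        f = Tensor(np.broadcast_to(v[:, :, None, None], (1, 4, 5, 5)).copy())
        m, _ = ca(f)
        w1, w2 = ca.fc1.weight.data, ca.fc2.weight.data
        mlp = np.maximum(v @ w1, 0) @ w2
        assert np.allclose(m.data, 1 / (1 + np.exp(-2 * mlp)), atol=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        ca = ls.ChannelAttention(4, 2, np.random.default_rng(5))
        f = rng.normal(size=(2, 4, 2, 2)).astype(np.float32)
        m, out = ca(Tensor(f))
        # independent pool -> shared MLP -> sum -> sigmoid recomputation
        w1, w2 = ca.fc1.weight.data, ca.fc2.weight.data
        avg = f.mean(axis=(2, 3))
        mx = f.max(axis=(2, 3))
        mlp = lambda v: np.maximum(v @ w1, 0) @ w2
        expect = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        assert np.abs(m.data - expect).max() < 1e-6
        assert np.abs(out.data - f * expect[:, :, None, None]).max() < 1e-6

    def test_gate_strictly_inside_unit_interval(self, small_encoder):
        rng = np.random.default_rng(6)
        x = Tensor(rng.uniform(size=(2, 3, 32, 32)).astype(np.float32))
        with ad.no_grad():
            f = small_encoder.fuse(small_encoder.extract_multiscale(x))
            m, _ = small_encoder.attend(f)
        assert (m.data > 0).all() and (m.data < 1).all()


class TestEmbedding:
    def test_embedding_lengths_by_config(self):
        x = np.zeros((1, 3, 32, 32), np.float32)
        full = ls.Encoder(ls.EncoderConfig(base_width=4), seed=0)
        plain = ls.Encoder(
            ls.EncoderConfig(base_width=4, fusion="none", attention="none"), seed=0
        )
        assert full.embed(x).shape == (1, 15 * 4)
        assert plain.embed(x).shape == (1, 8 * 4)

    def test_identical_images_identical_embeddings(self, small_encoder, tiny_bank):
        x = tiny_bank.images[:3]
        a = small_encoder.embed(x)
        b = small_encoder.embed(x.copy())
        assert np.array_equal(a, b)

    def test_attention_none_is_identity_on_fused(self):
        enc = ls.Encoder(ls.EncoderConfig(base_width=4, attention="none"), seed=0)
        x = Tensor(np.random.default_rng(7).normal(size=(1, 3, 32, 32)).astype(np.float32))
        with ad.no_grad():
            f = enc.fuse(enc.extract_multiscale(x))
            m, out = enc.attend(f)
        assert m is None and out is f

    def test_ablation_arms_differ_only_in_flags(self):
        """MB / MB+CMSFF / MB+CMSFF+CA share the backbone code path."""
        cfgs = [
            ls.EncoderConfig(base_width=4, fusion="none", attention="none"),
            ls.EncoderConfig(base_width=4, fusion="cascaded", attention="none"),
            ls.EncoderConfig(base_width=4, fusion="cascaded", attention="channel"),
        ]
        encs = [ls.Encoder(c, seed=0) for c in cfgs]
        # identical seeds -> identical backbone weights across arms
        w0 = [e.block1.conv.weight.data for e in encs]
        assert np.array_equal(w0[0], w0[1]) and np.array_equal(w0[1], w0[2])
        x = np.random.default_rng(8).uniform(size=(2, 3, 32, 32)).astype(np.float32)
        taps = []
        for e in encs:
            with ad.no_grad():
                taps.append(e.extract_multiscale(Tensor(x))[3].data)
        assert np.array_equal(taps[0], taps[1]) and np.array_equal(taps[1], taps[2])


def test_checkpoint_roundtrip(tmp_path, small_encoder, tiny_bank):
    x = tiny_bank.images[:2]
    before = small_encoder.embed(x)
    path = str(tmp_path / "enc.npz")
    ls.save_checkpoint(path, small_encoder, {"note": "test"})
    enc2, extra = ls.load_checkpoint(path)
    assert extra == {"note": "test"}
    assert enc2.config == small_encoder.config
    assert np.allclose(enc2.embed(x), before, atol=1e-6)
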