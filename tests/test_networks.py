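"""Network architecture contracts: attention identities, parameter counts,
shape preservation, feature projection."""

import numpy as np
import pytest

from t2adc.networks import (
    CBAM, AttentionConfig, ChannelAttention, GeneratorConfig, SpatialAttention,
    build_discriminator, build_generator, build_projection_head,
    encode_patch_features,
)
from t2adc.nn import Tensor


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        ca = ChannelAttention(8, reduction_ratio=4, rng=rng)
        zero_params(ca)
        out = ca(Tensor(rng.normal(size=(2, 8, 5, 5)))).numpy()
        assert np.allclose(out, 0.5, atol=1e-12)

    def test_spatially_constant_input_oracle(self, rng):
        # constant maps: AvgPool == MaxPool, so M_C = sigmoid(2*MLP(pooled))
        ca = ChannelAttention(8, reduction_ratio=4, rng=rng)
        const = rng.normal(size=(1, 8, 1, 1)) * np.ones((1, 8, 6, 6))
        out = ca(Tensor(const)).numpy()
        pooled = const[:, :, 0, 0]
        h = np.maximum(pooled @ ca.fc1.weight.data, 0.0) @ ca.fc2.weight.data
        expected = 1.0 / (1.0 + np.exp(-2.0 * h))
        assert np.allclose(out, expected, atol=1e-10)

    @pytest.mark.parametrize("channels", [8, 16, 64])
    def test_output_length(self, rng, channels):
        ca = ChannelAttention(channels, reduction_ratio=8, rng=rng)
        out = ca(Tensor(rng.normal(size=(3, channels, 4, 4))))
        assert out.shape == (3, channels)

    def test_channel_mismatch_errors(self, rng):
        ca = ChannelAttention(8, reduction_ratio=4, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            ca(Tensor(rng.normal(size=(1, 16, 4, 4))))

    def test_range_open_unit_interval(self, rng):
        ca = ChannelAttention(16, reduction_ratio=8, rng=rng)
        out = ca(Tensor(rng.normal(size=(2, 16, 5, 5)))).numpy()
        assert np.all(out > 0) and np.all(out < 1)


class TestSpatialAttention:
    def test_zero_weights_give_half(self, rng):
        sa = SpatialAttention(5, rng=rng)
        zero_params(sa)
        out = sa(Tensor(rng.normal(size=(1, 4, 7, 9)))).numpy()
        assert out.shape == (1, 1, 7, 9)
        assert np.allclose(out, 0.5, atol=1e-12)

    def test_single_channel_pools_are_input(self, rng):
        x = rng.normal(size=(1, 1, 5, 5))
        avg = x.mean(axis=1)
        mx = x.max(axis=1)
        assert np.allclose(avg, x[:, 0]) and np.allclose(mx, x[:, 0])

    def test_matches_brute_force_convolution(self, rng):
        # oracle: direct 5x5 convolution of the stacked avg/max maps
        sa = SpatialAttention(5, rng=rng)
        x = rng.normal(size=(1, 3, 6, 6))
        out = sa(Tensor(x)).numpy()[0, 0]
        stacked = np.stack([x.mean(axis=1)[0], x.max(axis=1)[0]])
        padded = np.pad(stacked, ((0, 0), (2, 2), (2, 2)))
        w = sa.conv.weight.data[0]
        b = sa.conv.bias.data[0]
        ref = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                ref[i, j] = np.sum(padded[:, i:i + 5, j:j + 5] * w) + b
        ref = 1.0 / (1.0 + np.exp(-ref))
        assert np.allclose(out, ref, atol=1e-10)


class TestCBAM:
    def test_zeroed_params_quarter_identity(self, rng):
        cbam = CBAM(8, reduction_ratio=4, rng=rng)
        zero_params(cbam)
        x = rng.normal(size=(2, 8, 6, 6))
        out = cbam(Tensor(x)).numpy()
        assert np.allclose(out, 0.25 * x, atol=1e-9)

    def test_zero_input_zero_output(self, rng):
        cbam = CBAM(8, reduction_ratio=4, rng=rng)
        out = cbam(Tensor(np.zeros((1, 8, 4, 4)))).numpy()
        assert np.allclose(out, 0.0)

    def test_composition_oracle(self, rng):
        cbam = CBAM(8, reduction_ratio=4, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 5, 5)))
        out = cbam(x).numpy()
        mc = cbam.channel(x).numpy().reshape(1, 8, 1, 1)
        xp = mc * x.numpy()
        ms = cbam.spatial(Tensor(xp)).numpy()
        assert np.allclose(out, ms * xp, atol=1e-12)


class TestGenerator:
    def test_default_parameter_count(self):
        _, n = build_generator()
        assert round(n / 1e6, 3) == 11.379

    def test_plain_parameter_count(self):
        _, n = build_generator(GeneratorConfig(cbam=None))
        assert round(n / 1e6, 3) == 11.378

    @pytest.mark.parametrize("size", [24, 32])
    def test_shape_preservation(self, rng, size):
        gen, _ = build_generator(GeneratorConfig(base_width=8), seed=1)
        y = gen(Tensor(rng.normal(size=(1, 3, size, size))))
        assert y.shape == (1, 3, size, size)

    def test_output_in_tanh_range(self, rng):
        gen, _ = build_generator(GeneratorConfig(base_width=8), seed=1)
        y = gen(Tensor(rng.normal(size=(1, 3, 24, 24)))).numpy()
        assert np.all(y > -1.0) and np.all(y < 1.0)

    def test_invalid_config_errors(self):
        with pytest.raises(ValueError, match="n_resblocks"):
            build_generator(GeneratorConfig(n_resblocks=0))
        with pytest.raises(ValueError, match="reduction_ratio"):
            build_generator(GeneratorConfig(
                base_width=12, cbam=AttentionConfig(reduction_ratio=8)))

    def test_forward_with_taps_matches_encode(self, rng):
        gen, _ = build_generator(GeneratorConfig(base_width=8), seed=2)
        x = Tensor(rng.normal(size=(1, 3, 24, 24)))
        out, taps = gen.forward_with_taps(x, (0, 1, 2, 3, 4))
        enc = gen.encode(x, (0, 1, 2, 3, 4))
        for l in (0, 1, 2, 3, 4):
            assert np.allclose(taps[l].numpy(), enc[l].numpy(), atol=1e-12)
        assert np.allclose(out.numpy(), gen(x).numpy(), atol=1e-12)


class TestDiscriminator:
    def test_score_map_shape_from_stride_schedule(self, rng):
        # closed form: three stride-2 stages then two stride-1 4x4 convs
        d = build_discriminator(base_width=8, seed=0)
        size = 152
        s = size
        for _ in range(3):
            s = (s + 2 * 1 - 4) // 2 + 1
        for _ in range(2):
            s = s + 2 * 1 - 4 + 1
        out = d(Tensor(rng.normal(size=(1, 3, size, size))))
        assert out.shape == (1, 1, s, s)
        assert s < size

    def test_zero_weights_constant_map(self, rng):
        d = build_discriminator(base_width=8, seed=0)
        zero_params(d)
        out = d(Tensor(rng.normal(size=(1, 3, 32, 32)))).numpy()
        assert np.allclose(out, out.flat[0])

    def test_unbounded_scores(self, rng):
        # least-squares head: no sigmoid, scores may leave (0, 1)
        d = build_discriminator(base_width=8, seed=0)
        out = d(Tensor(10.0 * rng.normal(size=(1, 3, 32, 32)))).numpy()
        assert out.min() < 0 or out.max() > 1


class TestProjection:
    def test_output_dims(self, rng):
        heads = build_projection_head([3, 8, 16], out_dim=32, seed=0)
        for i, d in enumerate((3, 8, 16)):
            assert heads(i, Tensor(rng.normal(size=(4, d)))).shape == (4, 32)

    def test_heads_have_independent_parameters(self, rng):
        heads = build_projection_head([8, 8], out_dim=16, seed=0)
        x = Tensor(rng.normal(size=(4, 8)))
        before = heads(1, x).numpy().copy()
        for p in heads.heads[0].parameters():
            p.data += 1.0
        after = heads(1, x).numpy()
        assert np.array_equal(before, after)

    def test_zero_weights_zero_embeddings(self, rng):
        heads = build_projection_head([8], out_dim=16, seed=0)
        zero_params(heads)
        out = heads(0, Tensor(rng.normal(size=(3, 8)))).numpy()
        assert np.allclose(out, 0.0)


class TestEncodePatchFeatures:
    @pytest.fixture
    def setup(self, rng):
        gen, _ = build_generator(GeneratorConfig(base_width=8), seed=3)
        heads = build_projection_head(gen.nce_feature_dims((0, 1, 2)),
                                      out_dim=16, seed=4)
        img = Tensor(rng.normal(size=(2, 3, 16, 16)))
        return gen, heads, img

    def test_unit_norm(self, setup):
        gen, heads, img = setup
        fs = encode_patch_features(gen, img, (0, 1, 2), 8, heads,
                                   rng=np.random.default_rng(5))
        for l in fs.layers:
            norms = np.linalg.norm(fs.embeddings[l].numpy(), axis=-1)
            assert np.allclose(norms, 1.0, atol=1e-5)

    def test_same_seed_same_locations(self, setup):
        gen, heads, img = setup
        a = encode_patch_features(gen, img, (0, 1, 2), 8, heads,
                                  rng=np.random.default_rng(6))
        b = encode_patch_features(gen, img, (0, 1, 2), 8, heads,
                                  rng=np.random.default_rng(6))
        for l in a.layers:
            assert np.array_equal(a.locations[l], b.locations[l])

    def test_shared_locations_correspondence(self, setup, rng):
        gen, heads, img = setup
        other = Tensor(rng.normal(size=(2, 3, 16, 16)))
        a = encode_patch_features(gen, img, (0, 1, 2), 8, heads,
                                  rng=np.random.default_rng(7))
        b = encode_patch_features(gen, other, (0, 1, 2), 8, heads,
                                  shared_locations=a.locations)
        for l in a.layers:
            assert np.array_equal(a.locations[l], b.locations[l])

    def test_too_many_locations_errors(self, setup):
        gen, heads, img = setup
        with pytest.raises(ValueError, match="n_locations"):
            encode_patch_features(gen, img, (2,), 10_000, heads,
                                  rng=np.random.default_rng(8))

    def test_locations_unique_within_layer(self, setup):
        gen, heads, img = setup
        fs = encode_patch_features(gen, img, (0, 1, 2), 16, heads,
                                   rng=np.random.default_rng(9))
        for l in fs.layers:
            assert len(np.unique(fs.locations[l])) == len(fs.locations[l])
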