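"""Architecture contracts: shapes, attention arithmetic, oracles, ablations."""

import numpy as np
import pytest

from ductstone import autodiff as ad
from ductstone.autodiff import Tensor
from ductstone.errors import ConfigError, ValidationError
from ductstone.network import ModelConfig, StoneDetector, count_parameters

from test_autodiff import brute_force_conv


def sigmoid(x):
    return 1 / (1 + np.exp(-np.asarray(x, dtype=float)))


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ModelConfig(
        image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
        dropout=0.0, c_d=4, decoder_channels=(8, 8, 8), classifier_hidden=16,
        seed=3,
    )
    model = StoneDetector(cfg)
    model.eval()
    return model


@pytest.mark.parametrize("size", [64, 96, 128])
def test_shape_contracts_default_config(size):
    """Full-width model: f_b at 1/4 res with 256 channels, blocks at 64/128,
    f_E = 4*C_d + C_b channels, f_U full-res 64ch, m_c 1x64, maps in (0,1)."""
    cfg = ModelConfig(image_size=size, seed=0)
    model = StoneDetector(cfg)
    model.eval()
    out = model.forward(np.random.default_rng(size).random((size, size)))
    q = size // 4
    assert out.f_b.shape == (1, 256, q, q)
    assert out.block1.shape == (1, 64, size, size)
    assert out.block2.shape == (1, 128, size // 2, size // 2)
    assert out.f_E.shape == (1, 4 * 64 + 256, q, q)
    assert all(f.shape == (1, 64, q, q) for f in out.f_d)
    assert out.f_p.shape == (1, 256, q, q)
    assert out.f_U.shape == (1, 64, size, size)
    assert out.m_c.shape == (1, 64)
    assert out.m_s.shape == (1, 1, size, size)
    assert out.m_p.shape == (1, 1, size, size)
    for m in (out.m_s, out.m_p):
        assert m.data.min() > 0 and m.data.max() < 1
    assert np.all(np.isfinite(out.m_c.data))
    assert 0 < out.y_hat.data[0] < 1


def test_indivisible_size_rejected(tiny_model):
    with pytest.raises(ValidationError):
        tiny_model.backbone_forward(np.zeros((30, 30)))


def test_eval_mode_deterministic(tiny_model, rng):
    x = rng.random((32, 32))
    a = tiny_model.forward(x)
    b = tiny_model.forward(x)
    assert np.array_equal(a.y_hat.data, b.y_hat.data)
    assert np.array_equal(a.m_p.data, b.m_p.data)


def test_train_mode_dropout_reproducible_under_seed():
    cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                      dropout=0.3, c_d=4, decoder_channels=(8, 8, 8),
                      classifier_hidden=16, seed=3)
    x = np.random.default_rng(0).random((32, 32))
    model = StoneDetector(cfg)
    model.train()
    model.reseed_dropout(9)
    a = model.forward(x).y_hat.data.copy()
    model.reseed_dropout(9)
    b = model.forward(x).y_hat.data.copy()
    model.reseed_dropout(10)
    c = model.forward(x).y_hat.data.copy()
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


class TestMFOV:
    def test_channel_arithmetic(self, tiny_model):
        f_b = Tensor(np.random.default_rng(1).random((1, 8, 8, 8)))
        f_d, f_p, f_E = tiny_model.mfov_forward(f_b)
        assert f_E.shape == (1, 4 * 4 + 8, 8, 8)
        assert f_p.shape == (1, 8, 8, 8)
        assert all(f.shape == (1, 4, 8, 8) for f in f_d)

    def test_zero_weights_zero_dilated_features(self):
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=3)
        model = StoneDetector(cfg)
        for conv in model.mfov_convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        f_b = Tensor(np.random.default_rng(2).random((1, 8, 8, 8)))
        f_d, f_p, f_E = model.mfov_forward(f_b)
        for f in f_d:
            assert np.all(f.data == 0)
        np.testing.assert_array_equal(f_E.data[:, 16:], f_p.data)

    def test_cascade_matches_dilated_conv_oracle(self, rng):
        """8x8 single-channel toy: every stage equals a brute-force dilated
        convolution of (f_b ++ previous) with the layer's kernel."""
        cfg = ModelConfig(image_size=32, backbone_channels=(2, 2, 1), convs_per_block=1,
                          dropout=0.0, c_d=1, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=5, dtype="float64")
        model = StoneDetector(cfg)
        f_b = rng.normal(size=(1, 1, 8, 8))
        f_d, _, _ = model.mfov_forward(Tensor(f_b))
        prev = None
        for conv, rate, f in zip(model.mfov_convs, cfg.dilation_rates, f_d):
            inp = f_b if prev is None else np.concatenate([f_b, prev], axis=1)
            expected = np.maximum(
                brute_force_conv(inp, conv.weight.data, conv.bias.data, rate), 0
            )
            np.testing.assert_allclose(f.data, expected, atol=1e-6)
            prev = f.data

    def test_constant_input_gives_constant_interior(self):
        cfg = ModelConfig(image_size=32, backbone_channels=(2, 2, 1), convs_per_block=1,
                          dropout=0.0, c_d=1, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=5, dtype="float64")
        model = StoneDetector(cfg)
        f_d, _, _ = model.mfov_forward(Tensor(np.full((1, 1, 16, 16), 0.7)))
        # rate-1 stage: interior excludes the 1px same-padding frame
        interior = f_d[0].data[0, 0, 1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0])

    def test_bypass_flag(self):
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=3, use_mfov=False)
        model = StoneDetector(cfg)
        f_b = Tensor(np.random.default_rng(3).random((1, 8, 8, 8)))
        f_d, f_p, f_E = model.mfov_forward(f_b)
        assert f_d is None and f_p is None and f_E is f_b


class TestDecoder:
    def test_output_shape_and_upsampling(self, tiny_model, rng):
        f_E = Tensor(rng.random((1, 24, 8, 8)))
        block1 = Tensor(rng.random((1, 4, 32, 32)))
        block2 = Tensor(rng.random((1, 6, 16, 16)))
        f_U = tiny_model.decoder_forward(f_E, block1, block2)
        assert f_U.shape == (1, 64, 32, 32)

    def test_mismatched_resolution_rejected(self, tiny_model, rng):
        with pytest.raises(ValidationError):
            tiny_model.decoder_forward(
                Tensor(rng.random((1, 24, 8, 8))),
                Tensor(rng.random((1, 4, 32, 32))),
                Tensor(rng.random((1, 6, 8, 8))),
            )

    def test_gap_of_constant_block_is_that_constant(self, rng):
        """The forward-connection weight vector from a constant block equals
        the constant per channel (arithmetic-mean oracle)."""
        from ductstone.network import _gap

        consts = rng.uniform(0.1, 2.0, size=4)
        block = np.broadcast_to(consts[None, :, None, None], (1, 4, 6, 6)).copy()
        np.testing.assert_allclose(_gap(Tensor(block)).data.ravel(), consts, atol=1e-12)

    def test_unit_connection_weights_are_identity(self, rng):
        """With the block2 1x1 conv at its zero-weight/unit-bias init and a
        block1 whose GAP is exactly one, connections change nothing."""
        cfg = ModelConfig(image_size=32, backbone_channels=(8, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=3, dtype="float64")
        model = StoneDetector(cfg)
        assert model.conn1 is None  # block1 channels == stage-2 channels
        f_E = Tensor(rng.random((1, 24, 8, 8)))
        block1 = Tensor(np.ones((1, 8, 32, 32)))
        block2 = Tensor(rng.random((1, 6, 16, 16)))
        with_conn = model.decoder_forward(f_E, block1, block2, connections=True)
        without = model.decoder_forward(f_E, block1, block2, connections=False)
        np.testing.assert_allclose(with_conn.data, without.data, atol=1e-12)


class TestAttention:
    def test_channel_attention_worked_examples(self, tiny_model):
        f_U = Tensor(np.array([[0.0, 1.0], [2.0, 3.0]]).reshape(1, 1, 2, 2))
        m_c = tiny_model.channel_attention(f_U)
        assert m_c.data[0, 0] == pytest.approx(sigmoid(4.5), abs=1e-5)  # max 3 + mean 1.5
        m_c2 = tiny_model.channel_attention(Tensor(np.full((1, 1, 2, 2), -1.0)))
        assert m_c2.data[0, 0] == pytest.approx(sigmoid(-2.0), abs=1e-5)

    def test_channel_attention_ablation_identity(self):
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=3, use_channel_attention=False)
        model = StoneDetector(cfg)
        f_U = Tensor(np.random.default_rng(0).random((1, 64, 4, 4)))
        m_c = model.channel_attention(f_U)
        np.testing.assert_array_equal(m_c.data, np.ones((1, 64)))
        attended = model.attended_feature(f_U, m_c, Tensor(np.ones((1, 1, 4, 4))))
        np.testing.assert_allclose(attended.data, f_U.data, atol=1e-12)

    def test_spatial_attention_zero_conv_gives_uniform_half(self, tiny_model, rng):
        tiny2 = StoneDetector(tiny_model.config)
        tiny2.spatial_conv.weight.data[:] = 0
        tiny2.spatial_conv.bias.data[:] = 0
        m_s = tiny2.spatial_attention(Tensor(rng.random((1, 64, 8, 8))))
        np.testing.assert_allclose(m_s.data, 0.5, atol=1e-7)

    def test_spatial_attention_matches_sliding_window_oracle(self, rng):
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=4, dtype="float64")
        model = StoneDetector(cfg)
        f_U = rng.normal(size=(1, 5, 8, 8))
        m_s = model.spatial_attention(Tensor(f_U)).data
        stacked = np.stack([f_U.max(axis=1), f_U.mean(axis=1)], axis=1)
        pre = brute_force_conv(stacked, model.spatial_conv.weight.data,
                               model.spatial_conv.bias.data)
        np.testing.assert_allclose(m_s, sigmoid(pre), atol=1e-6)

    def test_probability_map_zero_conv_and_annihilation(self, tiny_model, rng):
        model = StoneDetector(tiny_model.config)
        f_U = Tensor(rng.random((1, 64, 4, 4)))
        m_c = model.channel_attention(f_U)
        model.prob_conv.weight.data[:] = 0
        model.prob_conv.bias.data[:] = 0
        m_p = model.probability_map(f_U, m_c, model.spatial_attention(f_U))
        np.testing.assert_allclose(m_p.data, 0.5, atol=1e-7)
        # m_s == 0 with bias b -> uniform sigmoid(b)
        model.prob_conv.bias.data[:] = 0.7
        m_p = model.probability_map(f_U, m_c, Tensor(np.zeros((1, 1, 4, 4))))
        np.testing.assert_allclose(m_p.data, sigmoid(0.7), atol=1e-6)

    def test_probability_map_matches_arithmetic_oracle(self):
        """2x2x2 toy evaluated against a literal per-pixel computation."""
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=4, dtype="float64", f_u_channels=2)
        model = StoneDetector(cfg)
        f_U = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.5, -1.0], [2.0, 0.0]]])[None]
        m_c = np.array([[0.3, 0.8]])
        m_s = np.array([[[0.9, 0.1], [0.5, 0.7]]])[None]
        w = model.prob_conv.weight.data.reshape(2)
        b = float(model.prob_conv.bias.data[0])
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                acc = b
                for c in range(2):
                    acc += w[c] * (m_s[0, 0, i, j] * m_c[0, c] * f_U[0, c, i, j])
                expected[i, j] = 1 / (1 + np.exp(-acc))
        m_p = model.probability_map(Tensor(f_U), Tensor(m_c), Tensor(m_s))
        np.testing.assert_allclose(m_p.data[0, 0], expected, atol=1e-6)

    def test_spatial_ablation_gives_ones(self):
        cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                          dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                          classifier_hidden=16, seed=3, use_spatial_attention=False)
        model = StoneDetector(cfg)
        m_s = model.spatial_attention(Tensor(np.random.default_rng(0).random((1, 64, 4, 4))))
        np.testing.assert_array_equal(m_s.data, np.ones((1, 1, 4, 4)))


class TestClassifier:
    def test_zero_weights_give_half(self, tiny_model, rng):
        model = StoneDetector(tiny_model.config)
        for fc in (model.fc1, model.fc2, model.fc3):
            fc.weight.data[:] = 0
            fc.bias.data[:] = 0
        _, y_hat = model.classify(Tensor(rng.random((2, 1, 32, 32))))
        np.testing.assert_allclose(y_hat.data, 0.5, atol=1e-9)

    def test_softmax_closed_form(self, tiny_model):
        model = StoneDetector(tiny_model.config)
        model.fc3.weight.data[:] = 0
        a, delta = 0.4, 1.3
        model.fc3.bias.data[:] = [a, a + delta]
        _, y_hat = model.classify(Tensor(np.zeros((1, 1, 32, 32))))
        assert y_hat.data[0] == pytest.approx(sigmoid(delta), abs=1e-6)

    def test_wrong_input_size_rejected(self, tiny_model):
        with pytest.raises(ValidationError):
            tiny_model.classify(Tensor(np.zeros((1, 1, 16, 16))))


class TestParameterCount:
    def test_classifier_head_closed_form(self):
        cfg = ModelConfig(image_size=64, seed=0)
        model = StoneDetector(cfg)
        head = sum(p.size for name, p in model.named_parameters() if name.startswith("cls."))
        wh = 64 * 64
        assert head == wh * 256 + 256 + 256 * 256 + 256 + 256 * 2 + 2  # 1,114,882

    def test_widening_cd_changes_only_mfov_and_first_decoder_conv(self):
        base = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                           dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                           classifier_hidden=16, seed=3)
        wide = ModelConfig(**{**base.to_dict(), "c_d": 8})
        m0 = dict(StoneDetector(base).named_parameters())
        m1 = dict(StoneDetector(wide).named_parameters())
        for name in m0:
            same = m0[name].size == m1[name].size
            touched = name.startswith("mfov.") or name.startswith("decoder.conv1")
            assert same != touched, name

    def test_deterministic(self, tiny_model):
        assert count_parameters(tiny_model.config) == count_parameters(tiny_model.config)


class TestAblationIsolation:
    def test_flags_change_only_their_component(self, rng):
        base = dict(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                    dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                    classifier_hidden=16, seed=3)
        x = rng.random((32, 32))
        full = StoneDetector(ModelConfig(**base))
        full.eval()
        ref = full.forward(x)

        no_mc = StoneDetector(ModelConfig(**base, use_channel_attention=False))
        no_mc.eval()
        out = no_mc.forward(x)
        np.testing.assert_array_equal(out.f_U.data, ref.f_U.data)
        np.testing.assert_array_equal(out.m_s.data, ref.m_s.data)
        assert not np.array_equal(out.m_c.data, ref.m_c.data)

        no_ms = StoneDetector(ModelConfig(**base, use_spatial_attention=False))
        no_ms.eval()
        out = no_ms.forward(x)
        np.testing.assert_array_equal(out.f_U.data, ref.f_U.data)
        np.testing.assert_array_equal(out.m_c.data, ref.m_c.data)
        assert not np.array_equal(out.m_s.data, ref.m_s.data)

        no_mfov = StoneDetector(ModelConfig(**base, use_mfov=False))
        no_mfov.eval()
        out = no_mfov.forward(x)
        np.testing.assert_array_equal(out.f_b.data, ref.f_b.data)
        assert out.f_E.shape[1] == 8 and ref.f_E.shape[1] == 24


def test_gradient_reaches_every_parameter(rng):
    """Mixed batch (one stone, one normal): every trainable parameter gets a
    nonzero gradient from the total loss."""
    from ductstone import losses as L

    cfg = ModelConfig(image_size=32, backbone_channels=(4, 6, 8), convs_per_block=1,
                      dropout=0.0, c_d=4, decoder_channels=(8, 8, 8),
                      classifier_hidden=16, seed=3, dtype="float64")
    model = StoneDetector(cfg)
    model.train()
    x = rng.random((2, 32, 32))
    out = model.forward(x)
    total, _ = L.compute_losses(out, np.array([1.0, 0.0]))
    model.zero_grad()
    total.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"{name} got no gradient"
        assert np.any(p.grad != 0), f"{name} gradient identically zero"


def test_checkpoint_roundtrip(tmp_path, tiny_model, rng):
    x = rng.random((32, 32))
    ref = tiny_model.forward(x).y_hat.data.copy()
    p = tmp_path / "ckpt.npz"
    tiny_model.save(p)
    loaded = StoneDetector.load(p)
    loaded.eval()
    np.testing.assert_array_equal(loaded.forward(x).y_hat.data, ref)
    assert loaded.config == tiny_model.config


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        ModelConfig(image_size=30)
    with pytest.raises(ConfigError):
        ModelConfig(dilation_rates=(1, 2, 2, 4))
    with pytest.raises(ConfigError):
        ModelConfig(pool_mode="nearest")
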