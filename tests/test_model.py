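"""Architecture laws: shape arithmetic, attention against a brute-force
oracle, residual identities, softmax normalization, variant wiring and
gradient correctness."""

import numpy as np
import pytest

from beatformer import ModelConfig, VARIANT_NAMES, VariantFlags, build_variant
from beatformer import nn
from beatformer.model import ConvBlock, EcvtNet, PatchEmbed, TransformerBlock
from beatformer.training import softmax_cross_entropy_grad


def brute_force_attention(Q, K, V, d, scale="sqrt"):
    """Straight double-loop transcription of scaled dot-product attention."""
    nq, nk = Q.shape[0], K.shape[0]
    denom = np.sqrt(d) if scale == "sqrt" else d
    out = np.zeros((nq, V.shape[1]))
    for i in range(nq):
        scores = np.array([np.dot(Q[i], K[j]) / denom for j in range(nk)])
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        for j in range(nk):
            out[i] += w[j] * V[j]
    return out


SMALL_CFG = ModelConfig(input_len=250, n_kernels=4, kernel_size=7, pool_size=2,
                        patch_len=25, depth=2, n_heads=2, mlp_dim=16,
                        embed_dim=16)


class TestConvBlock:
    def test_default_feature_map_shape(self, rng):
        cfg = ModelConfig()
        block = ConvBlock(cfg, VariantFlags(), np.random.default_rng(0))
        out = block.forward(rng.random((3, 1, 250)), training=True)
        assert out.shape == (3, 32, 125)

    def test_relu_output_nonnegative(self, rng):
        block = ConvBlock(ModelConfig(), VariantFlags(use_pool=False),
                          np.random.default_rng(0))
        out = block.forward(rng.standard_normal((2, 1, 250)), training=True)
        assert (out >= 0).all()

    def test_pool_disabled_keeps_length(self, rng):
        block = ConvBlock(ModelConfig(), VariantFlags(use_pool=False),
                          np.random.default_rng(0))
        out = block.forward(rng.random((2, 1, 250)), training=True)
        assert out.shape[-1] == 250


class TestPatchEmbed:
    def test_five_patches_six_tokens(self):
        """The 32x125 default feature map splits into 5 patches; with the
        class token the sequence is 6 tokens long."""
        cfg = ModelConfig()
        pe = PatchEmbed(cfg.n_kernels, 125, cfg, np.random.default_rng(0))
        assert pe.n_patches == 5
        z = pe.forward(np.random.default_rng(1).random((2, 32, 125)))
        assert z.shape == (2, 6, cfg.embed_dim)

    def test_zero_input_gives_bias_plus_position(self):
        cfg = SMALL_CFG
        pe = PatchEmbed(cfg.n_kernels, 50, cfg, np.random.default_rng(0))
        z = pe.forward(np.zeros((1, cfg.n_kernels, 50)))
        expected = pe.proj.b.value + pe.pos_embed.value[1:]
        np.testing.assert_allclose(z[0, 1:], expected, atol=1e-12)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            PatchEmbed(4, 123, ModelConfig(), np.random.default_rng(0))

    def test_single_patch_boundary(self):
        cfg = ModelConfig(input_len=250, n_kernels=4, kernel_size=7,
                          pool_size=2, patch_len=125, depth=1, n_heads=2,
                          mlp_dim=8, embed_dim=8)
        pe = PatchEmbed(4, 125, cfg, np.random.default_rng(0))
        assert pe.n_patches == 1


class TestScaledAttention:
    def test_single_token_returns_value(self, rng):
        Q = rng.random((1, 4))
        K = rng.random((1, 4))
        V = rng.random((1, 3))
        np.testing.assert_allclose(nn.scaled_attention(Q, K, V), V, atol=1e-12)

    def test_identical_keys_give_column_mean(self, rng):
        K = np.tile(rng.random(4), (5, 1))
        V = rng.random((5, 3))
        Q = rng.random((2, 4))
        out = nn.scaled_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)),
                                   atol=1e-12)

    @pytest.mark.parametrize("scale", ["sqrt", "linear"])
    def test_matches_brute_force_oracle(self, rng, scale):
        Q, K, V = rng.standard_normal((3, 3, 4))
        out = nn.scaled_attention(Q, K, V, scale_mode=scale)
        ref = brute_force_attention(Q, K, V, 4, scale)
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="width"):
            nn.scaled_attention(rng.random((2, 4)), rng.random((2, 5)),
                                rng.random((2, 5)))


class TestMultiHeadAttention:
    def test_attention_rows_sum_to_one(self, rng):
        mha = nn.MultiHeadAttention(128, 8, np.random.default_rng(0))
        mha.forward(rng.standard_normal((2, 6, 128)))
        rows = mha.last_attention.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_single_head_reduces_to_scaled_attention(self, rng):
        """With one head, MHA equals plain attention on the projected
        Q/K/V followed by the output projection."""
        dim = 8
        mha = nn.MultiHeadAttention(dim, 1, np.random.default_rng(3))
        x = rng.standard_normal((1, 5, dim))
        out = mha.forward(x)
        q = x @ mha.wq.W.value + mha.wq.b.value
        k = x @ mha.wk.W.value + mha.wk.b.value
        v = x @ mha.wv.W.value + mha.wv.b.value
        ref = nn.scaled_attention(q[0], k[0], v[0], d=dim) \
            @ mha.wo.W.value + mha.wo.b.value
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_shape_preserved(self, rng):
        mha = nn.MultiHeadAttention(16, 4, np.random.default_rng(0))
        x = rng.standard_normal((3, 6, 16))
        assert mha.forward(x).shape == x.shape

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            nn.MultiHeadAttention(10, 4, np.random.default_rng(0))


class TestTransformerBlock:
    def test_residual_identity_with_zeroed_branches(self, rng):
        """Zeroing the attention and MLP branch weights reduces the block
        to the identity map."""
        blk = TransformerBlock(SMALL_CFG, np.random.default_rng(0))
        for p in blk.mha.parameters():
            p.value[...] = 0.0
        for p in blk.mlp.parameters():
            p.value[...] = 0.0
        z = rng.standard_normal((2, 6, SMALL_CFG.embed_dim))
        np.testing.assert_allclose(blk.forward(z), z, atol=1e-12)

    def test_matches_straight_line_transcription(self, rng):
        """One block equals an independent step-by-step evaluation of the
        pre-norm residual equations with the same weights."""
        blk = TransformerBlock(SMALL_CFG, np.random.default_rng(5))
        z = rng.standard_normal((1, 4, SMALL_CFG.embed_dim))
        out = blk.forward(z)

        def layer_norm(x, gamma, beta, eps=1e-5):
            mu = x.mean(-1, keepdims=True)
            var = x.var(-1, keepdims=True)
            return gamma * (x - mu) / np.sqrt(var + eps) + beta

        h = blk.mha.forward(layer_norm(z, blk.ln1.gamma.value,
                                       blk.ln1.beta.value)) + z
        m = layer_norm(h, blk.ln2.gamma.value, blk.ln2.beta.value)
        for layer in blk.mlp.layers:
            m = layer.forward(m)
        np.testing.assert_allclose(out, m + h, atol=1e-10)

    def test_shape_preserved_through_depth(self, rng):
        model = EcvtNet(SMALL_CFG, np.random.default_rng(0))
        z = model.patch_embed.forward(
            model.conv_block.forward(rng.random((2, 1, 250)), training=True))
        for blk in model.blocks:
            z = blk.forward(z)
            assert z.shape == (2, model.n_tokens, SMALL_CFG.embed_dim)


class TestClassifierHead:
    def test_softmax_laws(self, rng):
        model = EcvtNet(SMALL_CFG, np.random.default_rng(0))
        probs = model.predict_proba(rng.random((5, 250)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert ((probs > 0) & (probs < 1)).all()

    def test_logit_shift_invariance(self):
        p1 = nn.softmax(np.array([[1.0, 3.0]]))
        p2 = nn.softmax(np.array([[11.0, 13.0]]))
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_zero_weights_give_uniform(self, rng):
        model = EcvtNet(SMALL_CFG, np.random.default_rng(0))
        for p in model.head.fc.parameters():
            p.value[...] = 0.0
        probs = model.predict_proba(rng.random((3, 250)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)


class TestVariants:
    def test_vit_only_token_count(self):
        """Patching the raw 250-sample beat at length 25 gives 10 patches,
        11 tokens with the class token."""
        model = build_variant("vit_only", ModelConfig.fixture(), seed=0)
        assert model.patch_embed.n_patches == 10
        assert model.n_tokens == 11

    def test_conv_vit_has_no_bn_relu_pool(self):
        model = build_variant("conv_vit", ModelConfig.fixture(), seed=0)
        assert model.conv_block.bn is None
        assert model.conv_block.relu is None
        assert model.conv_block.pool is None

    @pytest.mark.parametrize("name", VARIANT_NAMES)
    def test_all_variants_run_forward(self, name, rng):
        model = build_variant(name, ModelConfig.fixture(), seed=0)
        probs = model.predict_proba(rng.random((2, 250)))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_variant_lists_names(self):
        with pytest.raises(ValueError, match="ecvt_net"):
            build_variant("mystery", ModelConfig.fixture())

    def test_parameter_count_is_config_function(self):
        a = build_variant("ecvt_net", ModelConfig.fixture(), seed=0)
        b = build_variant("ecvt_net", ModelConfig.fixture(), seed=99)
        assert a.n_parameters() == b.n_parameters()


class TestGradients:
    def test_full_model_gradients_match_finite_differences(self, rng):
        """Backprop through conv, patching, attention and the head agrees
        with central finite differences on sampled coordinates."""
        cfg = ModelConfig(input_len=50, n_kernels=3, kernel_size=5,
                          pool_size=2, patch_len=5, depth=1, n_heads=2,
                          mlp_dim=8, embed_dim=8)
        model = EcvtNet(cfg, np.random.default_rng(1))
        X = rng.random((4, 50))
        y = np.array([0, 1, 0, 1])

        def loss():
            logits = model.forward(X, training=True)
            return softmax_cross_entropy_grad(logits, y)[0]

        logits = model.forward(X, training=True)
        _, g = softmax_cross_entropy_grad(logits, y)
        model.zero_grad()
        model.backward(g)
        check_rng = np.random.default_rng(2)
        params = model.parameters()
        for pi in check_rng.choice(len(params), size=10, replace=False):
            P = params[pi]
            flat = P.value.ravel()
            i = int(check_rng.integers(flat.size))
            eps, orig = 1e-6, flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = P.grad.ravel()[i]
            assert abs(numeric - analytic) <= 1e-4 * max(
                1.0, abs(numeric) + abs(analytic)), P.name

    def test_one_step_touches_every_stage(self, rng):
        """After a single SGD step every named stage has at least one
        changed parameter (gradient flow end to end)."""
        from beatformer.training import SGD

        model = EcvtNet(SMALL_CFG, np.random.default_rng(0))
        before = {p.name: p.value.copy() for p in model.parameters()}
        X = rng.random((8, 250))
        y = np.array([0, 1] * 4)
        logits = model.forward(X, training=True)
        _, g = softmax_cross_entropy_grad(logits, y)
        model.zero_grad()
        model.backward(g)
        SGD(model.parameters(), lr=0.1).step()
        changed_stages = {p.name.split(".")[0] for p in model.parameters()
                          if not np.array_equal(before[p.name], p.value)}
        expected = {"conv", "patch_proj", "cls_token", "pos_embed",
                    "head"} | {f"blk{i}" for i in range(SMALL_CFG.depth)}
        assert expected <= changed_stages
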