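"""SE / CBAM / P-CSEM forward math, parameter accounting, and gradients.

Hand-computed scalar oracles run in float64 (the blocks preserve a float64
input dtype), so agreement is checked essentially to machine precision.
"""

import numpy as np
import pytest

from pcsem.attention import (AttentionConfig, CBAMBlock, PCSEMBlock, SEBlock,
                             block_param_count, make_block)

KINDS = ["se", "cbam", "pcsem"]


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def conv2d_same_oracle(x, w, b):
    """Direct-sum 2-D convolution with zero 'same' padding, (Cout,Cin,k,k)."""
    cout, cin, k, _ = w.shape
    h, ww = x.shape[1], x.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    out = np.zeros((cout, h, ww))
    for f in range(cout):
        for c in range(cin):
            for i in range(h):
                for j in range(ww):
                    out[f, i, j] += (xp[c, i:i + k, j:j + k] * w[f, c]).sum()
        out[f] += b[f]
    return out


@pytest.mark.parametrize("kind", KINDS)
def test_zero_input_is_annihilated(kind):
    block = make_block(AttentionConfig(kind, 8, 4), np.random.default_rng(0))
    x = np.zeros((2, 8, 5, 5), dtype=np.float32)
    assert np.all(block.forward(x) == 0.0)


def test_se_gate_strictly_attenuates_nonzero_entries():
    block = SEBlock(6, 2, rng=np.random.default_rng(1))
    x = np.random.default_rng(2).normal(size=(3, 6, 4, 4)).astype(np.float32)
    y = block.forward(x)
    nz = x != 0
    assert np.all(np.abs(y[nz]) < np.abs(x[nz]))


@pytest.mark.parametrize("kind", KINDS)
@pytest.mark.parametrize("channels", [256, 512, 1024, 2048])
@pytest.mark.parametrize("hw", [7, 14, 28, 56])
def test_shape_preservation(kind, channels, hw):
    block = make_block(AttentionConfig(kind, channels, 16), np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, channels, hw, hw)).astype(np.float32)
    assert block.forward(x).shape == x.shape


@pytest.mark.parametrize("kind", KINDS)
def test_batched_and_unbatched_agree(kind):
    block = make_block(AttentionConfig(kind, 8, 4), np.random.default_rng(3))
    x = np.random.default_rng(4).normal(size=(3, 8, 5, 5)).astype(np.float32)
    batched = block.forward(x)
    singles = np.stack([block.forward(x[i]) for i in range(3)])
    assert np.allclose(batched, singles, atol=1e-6)


def test_cbam_constant_map_pools_identically():
    """A spatially constant input makes SAP and SMP coincide."""
    block = CBAMBlock(5, 1, rng=np.random.default_rng(5))
    x = np.ones((1, 5, 4, 4)) * np.arange(1, 6)[None, :, None, None]
    x = x.astype(np.float32)
    sa = x.mean(axis=(2, 3))
    sm = x.max(axis=(2, 3))
    assert np.array_equal(sa, sm)
    y = block.forward(x)
    assert y.shape == x.shape


class TestScalarOracles:
    def test_se_two_channel_single_pixel(self):
        """GAP -> FC -> ReLU -> FC -> sigmoid -> multiply, by hand."""
        block = SEBlock(2, 2, rng=np.random.default_rng(0))
        block.fc1.weight.value[...] = np.array([[0.5, -0.25]], dtype=np.float32)
        block.fc1.bias.value[...] = np.array([0.125], dtype=np.float32)
        block.fc2.weight.value[...] = np.array([[1.0], [-0.5]], dtype=np.float32)
        block.fc2.bias.value[...] = np.array([0.25, -0.75], dtype=np.float32)
        x = np.array([[[1.5]], [[-2.0]]], dtype=np.float64)
        s = np.array([1.5, -2.0])
        h = max(0.5 * 1.5 + (-0.25) * (-2.0) + 0.125, 0.0)
        g = sigmoid(np.array([1.0 * h + 0.25, -0.5 * h - 0.75]))
        expected = (s * g)[:, None, None]
        assert np.allclose(block.forward(x), expected, atol=1e-12)

    def test_cbam_2x2x2_full_pipeline(self):
        block = CBAMBlock(2, 1, spatial_kernel=3, rng=np.random.default_rng(0))
        rng = np.random.default_rng(8)
        for p in block.parameters():
            p.value[...] = np.round(rng.uniform(-0.5, 0.5, p.value.shape) * 8) / 8
        x = np.round(rng.uniform(-1, 1, (2, 2, 2)) * 4) / 4
        x = x.astype(np.float64)

        w1, b1 = block.w1.value.astype(float), block.b1.value.astype(float)
        w2, b2 = block.w2.value.astype(float), block.b2.value.astype(float)
        sa, sm = x.mean(axis=(1, 2)), x.max(axis=(1, 2))
        mlp = lambda s: w2 @ np.maximum(w1 @ s + b1, 0) + b2
        g = sigmoid(mlp(sa) + mlp(sm))
        x1 = x * g[:, None, None]
        cat = np.stack([x1.mean(axis=0), x1.max(axis=0)])
        conv = conv2d_same_oracle(cat, block.conv.weight.value.astype(float),
                                  block.conv.bias.value.astype(float))
        expected = x1 * sigmoid(conv[0])
        assert np.allclose(block.forward(x), expected, atol=1e-9)

    def test_pcsem_2x3x3_both_branches(self):
        block = PCSEMBlock(2, 1, mid_channels=8, rng=np.random.default_rng(0))
        rng = np.random.default_rng(9)
        for p in block.parameters():
            p.value[...] = np.round(rng.uniform(-0.5, 0.5, p.value.shape) * 8) / 8
        x = np.round(rng.uniform(-1, 1, (2, 3, 3)) * 4) / 4
        x = x.astype(np.float64)

        w1, b1 = block.fc1.weight.value.astype(float), block.fc1.bias.value.astype(float)
        w2, b2 = block.fc2.weight.value.astype(float), block.fc2.bias.value.astype(float)
        g = sigmoid(w2 @ np.maximum(w1 @ x.mean(axis=(1, 2)) + b1, 0) + b2)
        m = x.mean(axis=0, keepdims=True)
        u = np.maximum(conv2d_same_oracle(m, block.conv1.weight.value.astype(float),
                                          block.conv1.bias.value.astype(float)), 0)
        v = conv2d_same_oracle(u, block.conv2.weight.value.astype(float),
                               block.conv2.bias.value.astype(float))
        expected = x * (g[:, None, None] * sigmoid(v[0]))
        assert np.allclose(block.forward(x), expected, atol=1e-9)


class TestParameterCounts:
    @pytest.mark.parametrize("kind", KINDS)
    @pytest.mark.parametrize("channels,reduction",
                             [(8, 4), (64, 8), (256, 16), (100, 16), (512, 4)])
    def test_closed_form_matches_instantiated_block(self, kind, channels, reduction):
        cfg = AttentionConfig(kind, channels, reduction)
        assert block_param_count(cfg) == make_block(cfg).num_parameters()

    def test_pcsem_reference_values(self):
        assert block_param_count(AttentionConfig("pcsem", 256, 16)) == 8464 + 153
        assert block_param_count(AttentionConfig("se", 256, 16)) == 8464
        assert block_param_count(AttentionConfig("cbam", 256, 16)) == 8464 + 99

    def test_channel_branch_scales_inversely_with_reduction(self):
        r4 = block_param_count(AttentionConfig("pcsem", 256, 4)) - 153
        r16 = block_param_count(AttentionConfig("pcsem", 256, 16)) - 153
        assert r4 / r16 == pytest.approx(4.0, rel=0.05)


def test_se_channel_gate_is_permutation_equivariant():
    rng = np.random.default_rng(6)
    block = SEBlock(5, 1, rng=rng)
    x = rng.normal(size=(1, 5, 3, 3)).astype(np.float64)
    g = block.channel_gate(x)
    perm = np.array([3, 0, 4, 1, 2])
    permuted = SEBlock(5, 1, rng=np.random.default_rng(0))
    permuted.fc1.weight.value[...] = block.fc1.weight.value[:, perm]
    permuted.fc1.bias.value[...] = block.fc1.bias.value
    permuted.fc2.weight.value[...] = block.fc2.weight.value[perm]
    permuted.fc2.bias.value[...] = block.fc2.bias.value[perm]
    g_perm = permuted.channel_gate(x[:, perm])
    assert np.allclose(g_perm, g[:, perm], atol=1e-6)


class TestValidation:
    def test_channel_mismatch_is_a_configuration_error(self):
        block = SEBlock(4, 2)
        with pytest.raises(ValueError, match="channels"):
            block.forward(np.zeros((1, 3, 2, 2), dtype=np.float32))

    def test_non_finite_input_rejected(self):
        block = PCSEMBlock(2, 1)
        x = np.full((1, 2, 2, 2), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="finite"):
            block.forward(x)

    def test_unknown_kind_and_bad_reduction(self):
        with pytest.raises(ValueError):
            AttentionConfig("transformer", 8)
        with pytest.raises(ValueError):
            AttentionConfig("se", 8, reduction=0)
        with pytest.raises(ValueError):
            AttentionConfig("cbam", 8, spatial_kernel=4)


@pytest.mark.parametrize("kind", KINDS)
def test_backward_matches_finite_differences(kind):
    rng = np.random.default_rng(12)
    block = make_block(AttentionConfig(kind, 4, 2), rng)
    x = rng.normal(size=(2, 4, 3, 3)).astype(np.float64)
    t = rng.normal(size=x.shape)
    block.zero_grad()
    block.forward(x.copy())
    dx = block.backward(t)

    eps = 1e-6
    num = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num[idx] = ((block.forward(xp) * t).sum() - (block.forward(xm) * t).sum()) / (2 * eps)
    assert np.allclose(dx, num, atol=1e-5)
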