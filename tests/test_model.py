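"""Attention blocks, backbone, fusion, and full-network forward behaviour."""

import numpy as np
import pytest

import bfpcnet as b
import bfpcnet.engine as engine
from bfpcnet import nn
from bfpcnet.model import (ChannelAttentionGate, RAMBlock, SpatialAttention,
                           sigmoid, softmax)


def _zero_gate(gate):
    for layer in (gate.fc1a, gate.fc1b, gate.fc2a, gate.fc2b):
        layer.weight.data[...] = 0.0
        layer.bias.data[...] = 0.0


def _zero_attention(block):
    _zero_gate(block.channel_gate)
    block.spatial.conv.weight.data[...] = 0.0
    block.spatial.conv.bias.data[...] = 0.0


# ---------------------------------------------------------------------------
# channel attention


def test_zeroed_dense_maps_give_zero_channel_attention():
    rng = np.random.default_rng(0)
    gate = ChannelAttentionGate(8, reduction=4, rng=rng)
    _zero_gate(gate)
    f_prime = rng.random((2, 8, 5, 5))
    assert np.array_equal(gate.forward(f_prime), np.zeros_like(f_prime))


def test_channel_attention_matches_hand_computation():
    # identity dense maps: s = ReLU(z + z) = 2 * GAP(F'), U = F' * s
    gate = ChannelAttentionGate(2, reduction=1, rng=np.random.default_rng(0))
    for layer in (gate.fc1a, gate.fc1b, gate.fc2a, gate.fc2b):
        layer.weight.data[...] = np.eye(2)
        layer.bias.data[...] = 0.0
    f_prime = np.array([[[[1.0, 2.0], [3.0, 4.0]],
                         [[0.0, 1.0], [0.0, 1.0]]]])
    u = gate.forward(f_prime)
    expected = f_prime * np.array([2 * 2.5, 2 * 0.5])[None, :, None, None]
    assert np.allclose(u, expected)


def test_channel_attention_preserves_shape():
    out = b.channel_attention(np.random.default_rng(1).random((4, 6, 6)),
                              b.AttentionParams(channel_reduction=2,
                                                n_pre_convs=1))
    assert out.shape == (4, 6, 6)
    assert out.role == "U"


def test_channel_attention_rejects_indivisible_reduction():
    with pytest.raises(ValueError):
        b.channel_attention(np.zeros((6, 4, 4)),
                            b.AttentionParams(channel_reduction=4))


# ---------------------------------------------------------------------------
# spatial attention


def test_spatial_attention_matches_hand_computation():
    sa = SpatialAttention(kernel=3, rng=np.random.default_rng(0))
    w = np.arange(9, dtype=float).reshape(1, 1, 3, 3) / 10.0
    sa.conv.weight.data[...] = w
    sa.conv.bias.data[...] = 0.5
    u = np.arange(9, dtype=float).reshape(1, 1, 3, 3)
    out = sa.forward(u)
    # manual arithmetic on the 9 numbers
    p0 = u[0, 0]                                     # channel mean of 1 channel
    p = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            p[i, j] = p0[max(0, i - 1):i + 2, max(0, j - 1):j + 2].max()
    pad = np.pad(p, 1)
    a = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            a[i, j] = (pad[i:i + 3, j:j + 3] * w[0, 0]).sum() + 0.5
    assert np.allclose(out[0, 0], a * p, atol=1e-5)


def test_constant_input_gives_constant_spatial_map():
    sa = SpatialAttention(kernel=3, rng=np.random.default_rng(0))
    u = np.full((1, 4, 8, 8), 3.0)
    out = sa.forward(u)
    interior = out[0, :, 2:-2, 2:-2]
    assert np.allclose(interior, interior.reshape(4, -1)[:, :1][:, None])


def test_spatial_attention_preserves_shape_and_rejects_even_kernel():
    out = b.spatial_attention(np.random.default_rng(0).random((3, 5, 7)))
    assert out.shape == (3, 5, 7) and out.role == "U'"
    with pytest.raises(ValueError):
        SpatialAttention(kernel=4)


# ---------------------------------------------------------------------------
# residual attention block


def test_zero_attention_reduces_block_to_relu_passthrough():
    rng = np.random.default_rng(2)
    block = RAMBlock(8, b.AttentionParams(channel_reduction=1, n_pre_convs=2),
                     rng)
    _zero_attention(block)
    f = rng.standard_normal((2, 8, 6, 6))
    assert np.allclose(block.forward(f), np.maximum(f, 0.0))


def test_block_equals_staged_composition_oracle():
    rng = np.random.default_rng(3)
    params = b.AttentionParams(channel_reduction=2, spatial_kernel=3, n_pre_convs=1)
    block = RAMBlock(4, params, np.random.default_rng(7))
    f = rng.random((1, 4, 5, 5))
    m = block.forward(f)
    f_prime = block.pre.forward(f)
    u = block.channel_gate.forward(f_prime)
    u_prime = block.spatial.forward(u)
    assert np.allclose(m, np.maximum(u_prime + f, 0.0))


@pytest.mark.parametrize("shape", [(2, 4, 4), (4, 7, 5), (8, 3, 9)])
def test_all_attention_ops_preserve_shape(shape):
    params = b.AttentionParams(channel_reduction=2, spatial_kernel=3, n_pre_convs=1)
    f = np.random.default_rng(0).random(shape)
    assert b.residual_attention_block(f, params).shape == shape
    assert b.spatial_attention(f, params).shape == shape


# ---------------------------------------------------------------------------
# backbone


def test_tiny_backbone_shape_contract():
    net = b.build_backbone(b.BackboneConfig(variant="tiny"), seed=0)
    x = np.random.default_rng(0).random((2, 3, 64, 64), dtype=np.float32)
    e = net.forward(x)
    assert e.shape == (2, net.embedding_dim)
    assert np.isfinite(e).all()


def test_resnet50_backbone_runs_at_full_image_size():
    net = b.build_backbone(b.BackboneConfig(variant="resnet50"), seed=0)
    x = np.random.default_rng(0).random((1, 3, 256, 256), dtype=np.float32)
    e = net.forward(x)
    assert e.shape == (1, 2048)
    assert np.isfinite(e).all()


def test_seeded_builds_are_identical():
    c = b.BackboneConfig(variant="tiny")
    n1 = b.build_backbone(c, seed=5)
    n2 = b.build_backbone(c, seed=5)
    s1, s2 = n1.state_dict(), n2.state_dict()
    assert s1.keys() == s2.keys()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_invalid_insertion_points_and_pretrained_rejected():
    with pytest.raises(ValueError):
        b.build_backbone(b.BackboneConfig(variant="tiny", insertion_points=[9]))
    with pytest.raises(ValueError):
        b.build_backbone(b.BackboneConfig(variant="resnet50", pretrained=True))


def test_zeroed_attention_network_equals_attention_free_backbone():
    cfg = b.BackboneConfig(variant="tiny")
    with_ram = b.build_backbone(cfg, seed=4)
    without = b.build_backbone(
        b.BackboneConfig(variant="tiny", insertion_points=[]), seed=4)
    for block in with_ram.body.layers:
        if isinstance(block, RAMBlock):
            _zero_attention(block)
    # share the residual-stage weights between the two networks
    src = [l for l in with_ram.body.layers if not isinstance(l, RAMBlock)]
    dst = without.body.layers
    assert len(src) == len(dst)
    for s, d in zip(src, dst):
        d.load_state_dict(s.state_dict())
    if with_ram.proj is not None:
        without.proj.load_state_dict(with_ram.proj.state_dict())
    x = np.random.default_rng(0).random((2, 3, 64, 64), dtype=np.float32)
    assert np.allclose(with_ram.forward(x), without.forward(x), atol=1e-5)


def test_gradient_reaches_every_parameter():
    net = b.BFPCNet(b.BackboneConfig(variant="tiny", dropout_rate=0.0), seed=0)
    rng = np.random.default_rng(0)
    x = rng.random((4, 3, 64, 64), dtype=np.float32)
    y = rng.integers(0, 2, (4, 8)).astype(float)
    engine._loss_and_grad(net, x, x, b.smooth_labels(y), "smoothed_binary")
    dead = [n for n, p in net.named_parameters() if np.abs(p.grad).sum() == 0]
    assert dead == []


# ---------------------------------------------------------------------------
# fusion and full forward


def test_fuse_literal_formula_examples():
    y = np.array([0.2, 0.4, 0.8])
    assert np.allclose(b.fuse(y, y, b.FusionConfig()), 0.5 * y)
    assert np.allclose(b.fuse(y, np.zeros(3), b.FusionConfig(weights=(2.0, 0.0))), y)


def test_fuse_matches_elementwise_loop_oracle():
    rng = np.random.default_rng(0)
    yl, yr = rng.random(8), rng.random(8)
    w = (0.3, 1.1)
    got = b.fuse(yl, yr, b.FusionConfig(weights=w))
    expected = np.array([(w[0] * yl[k] + w[1] * yr[k]) / 2 for k in range(8)])
    assert np.allclose(got, expected)


def test_fuse_rejects_length_mismatch():
    with pytest.raises(ValueError):
        b.fuse(np.zeros(8), np.zeros(7))


def test_sigmoid_head_outputs_probabilities():
    net = b.BFPCNet(b.BackboneConfig(variant="tiny"), seed=1)
    rng = np.random.default_rng(1)
    p = net.forward_pair(rng.random((3, 3, 64, 64), dtype=np.float32),
                         rng.random((3, 3, 64, 64), dtype=np.float32))
    assert p.shape == (3, 8)
    assert ((p >= 0) & (p <= 1)).all()


def test_softmax_head_sums_to_one():
    net = b.BFPCNet(b.BackboneConfig(variant="tiny", head_activation="softmax"),
                    seed=1)
    rng = np.random.default_rng(2)
    p = net.forward_pair(rng.random((2, 3, 64, 64), dtype=np.float32),
                         rng.random((2, 3, 64, 64), dtype=np.float32))
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("mode", ["feature_average", "prediction_average"])
def test_eye_swap_symmetry_with_shared_weights(mode):
    net = b.BFPCNet(b.BackboneConfig(variant="tiny"),
                    b.FusionConfig(mode=mode), seed=3)
    rng = np.random.default_rng(3)
    left = rng.random((2, 3, 64, 64), dtype=np.float32)
    right = rng.random((2, 3, 64, 64), dtype=np.float32)
    assert np.allclose(net.forward_pair(left, right),
                       net.forward_pair(right, left), atol=1e-6)


def test_predict_labels_thresholding():
    probs = np.array([[0.9, 0.5, 0.1, 0.0, 1.0, 0.49, 0.51, 0.3]])
    assert b.predict_labels(probs).tolist() == [[1, 1, 0, 0, 1, 0, 1, 0]]
    with pytest.raises(ValueError):
        b.predict_labels(probs, threshold=0.0)


def test_activation_helpers():
    z = np.array([[-3.0, 0.0, 4.0]])
    assert np.allclose(sigmoid(z), 1 / (1 + np.exp(-z)))
    assert np.allclose(softmax(z).sum(), 1.0)
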