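"""Residual attention network with binocular feature fusion.

The classifier runs one convolutional branch per eye (weights shared by
default), inserts a residual attention block (RAM) after each residual
stage, fuses the two branch outputs, and maps the fused feature through
ReLU -> dropout -> dense -> sigmoid/softmax to 8 per-class scores in the
fixed label order N, D, G, C, A, H, M, O.

One RAM block computes, for block input ``F`` of shape C x H x W:

* ``F' = preconvs(F)`` — ``n_pre_convs`` channel-preserving 3x3
  conv + batchnorm + ReLU layers capturing cross-channel structure;
* channel attention: the globally average-pooled C-vector of ``F'`` is
  passed through two independently parameterized bottleneck dense maps
  (C -> C/r -> C), their sum is rectified (ReLU, not sigmoid), and the
  resulting vector rescales ``F'`` channel-wise, giving ``U``;
* spatial attention: ``U`` is collapsed to one channel by a mean over C,
  sharpened by a stride-1 3x3 spatial max pool, ``P``; a single 1->1
  channel conv produces an attention map which multiplies ``P``; the
  product is broadcast back over the C channels, giving ``U'``;
* residual merge: ``M = ReLU(U' + F)``.

All attention maps preserve the C x H x W shape, which the residual
merge requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn

N_CLASSES = 8

FEATURE_ROLES = ("F", "F'", "U", "U'", "M")


@dataclass
class FeatureMap:
    """A C x H x W activation tensor tagged with its role in the RAM block."""

    values: np.ndarray
    role: str = "F"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap values must be C x H x W")
        if self.role not in FEATURE_ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class AttentionParams:
    channel_reduction: int = 16
    spatial_kernel: int = 7
    n_pre_convs: int = 3

    def validate(self):
        if self.channel_reduction < 1:
            raise ValueError("channel_reduction must be >= 1")
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel < 1:
            raise ValueError("spatial_kernel must be odd and positive")
        if self.n_pre_convs < 0:
            raise ValueError("n_pre_convs must be >= 0")


@dataclass
class FusionConfig:
    """Two-branch fusion p = (1/T) * sum_i w_i y_i (taken literally)."""

    T: int = 2
    weights: tuple = (0.5, 0.5)
    mode: str = "feature_average"

    def validate(self):
        if self.T != 2:
            raise ValueError("fusion is defined for exactly two branches")
        if len(self.weights) != self.T:
            raise ValueError("need one weight per branch")
        if any(w < 0 for w in self.weights):
            raise ValueError("fusion weights must be nonnegative")
        if self.mode not in ("prediction_average", "feature_average", "feature_concat"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")


@dataclass
class BackboneConfig:
    variant: str = "tiny"
    insertion_points: Sequence[int] | None = None
    pretrained: bool = False
    embedding_dim: int | None = None
    dropout_rate: float = 0.5
    head_activation: str = "sigmoid"
    attention: AttentionParams = field(default_factory=AttentionParams)
    share_branches: bool = True

    def validate(self):
        if self.variant not in ("tiny", "resnet50"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.head_activation not in ("sigmoid", "softmax"):
            raise ValueError("head_activation must be sigmoid or softmax")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        self.attention.validate()


# ---------------------------------------------------------------------------
# attention modules


class ChannelAttentionGate(nn.Module):
    """Channel gate applied to F': U = ReLU(mlp1(z) + mlp2(z)) (.) F',
    with z the global average pool of F'."""

    def __init__(self, channels, reduction=16, rng=None):
        if channels % reduction != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        if rng is None:
            rng = np.random.default_rng(0)
        mid = channels // reduction
        self.fc1a = nn.Dense(channels, mid, rng)
        self.fc1b = nn.Dense(mid, channels, rng)
        self.fc2a = nn.Dense(channels, mid, rng)
        self.fc2b = nn.Dense(mid, channels, rng)
        # small positive bias keeps the narrow ReLU bottlenecks alive at init
        self.fc1a.bias.data[...] = 0.1
        self.fc2a.bias.data[...] = 0.1
        self.relu_a = nn.ReLU()
        self.relu_b = nn.ReLU()
        self.relu_gate = nn.ReLU()
        self._cache = None

    def forward(self, f_prime, train=False):
        n, c, h, w = f_prime.shape
        z = f_prime.mean(axis=(2, 3))                      # global average pool
        h1 = self.fc1b.forward(self.relu_a.forward(self.fc1a.forward(z)))
        h2 = self.fc2b.forward(self.relu_b.forward(self.fc2a.forward(z)))
        s = self.relu_gate.forward(h1 + h2)                # sigma is ReLU here
        out = f_prime * s[:, :, None, None]
        self._cache = (f_prime, s)
        return out

    def backward(self, dout):
        f_prime, s = self._cache
        n, c, h, w = f_prime.shape
        df = dout * s[:, :, None, None]
        ds = (dout * f_prime).sum(axis=(2, 3))
        dh = self.relu_gate.backward(ds)
        dz = self.fc1a.backward(self.relu_a.backward(self.fc1b.backward(dh)))
        dz += self.fc2a.backward(self.relu_b.backward(self.fc2b.backward(dh)))
        df += np.broadcast_to(dz[:, :, None, None] / (h * w), f_prime.shape)
        return df


class SpatialAttention(nn.Module):
    """U' = conv(P) (.) P broadcast over channels, P = MaxPool(AvgPool(U)).

    AvgPool collapses channels (C x H x W -> 1 x H x W); MaxPool is a
    stride-1 3x3 spatial max keeping H x W; conv is a single odd-kernel
    1 -> 1 channel convolution with same padding.
    """

    def __init__(self, kernel=7, rng=None):
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        if rng is None:
            rng = np.random.default_rng(0)
        self.pool = nn.MaxPool2d(kernel=3, stride=1)
        self.conv = nn.Conv2d(1, 1, kernel, rng=rng)
        self._cache = None

    def forward(self, u, train=False):
        n, c, h, w = u.shape
        p0 = u.mean(axis=1, keepdims=True)                 # channel collapse
        p = self.pool.forward(p0)
        a = self.conv.forward(p, train=train)
        up = a * p                                         # 1 x H x W map
        self._cache = (p, a, c)
        return np.broadcast_to(up, u.shape).copy()

    def backward(self, dout):
        p, a, c = self._cache
        dup = dout.sum(axis=1, keepdims=True)
        da = dup * p
        dp = dup * a + self.conv.backward(da)
        dp0 = self.pool.backward(dp)
        return np.broadcast_to(dp0 / c, dout.shape).copy()


class ConvBNReLU(nn.Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride=stride, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)
        self.relu = nn.ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train))

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


def _effective_reduction(channels: int, reduction: int, min_mid: int = 8) -> int:
    """Largest divisor of ``channels`` not above ``reduction`` whose
    bottleneck width is at least ``min_mid`` (narrow gates die at init)."""
    r = min(reduction, max(1, channels // min_mid))
    while r > 1 and channels % r:
        r -= 1
    return max(r, 1)


class RAMBlock(nn.Module):
    """Residual attention block: M = ReLU(spatial(channel(preconvs(F))) + F)."""

    def __init__(self, channels, params: AttentionParams, rng=None):
        params.validate()
        if rng is None:
            rng = np.random.default_rng(0)
        self.pre = nn.Sequential(*[
            ConvBNReLU(channels, channels, 3, rng=rng) for _ in range(params.n_pre_convs)])
        self.channel_gate = ChannelAttentionGate(
            channels, _effective_reduction(channels, params.channel_reduction), rng)
        self.spatial = SpatialAttention(params.spatial_kernel, rng)
        self._mask = None

    def forward(self, f, train=False):
        f_prime = self.pre.forward(f, train=train)
        u = self.channel_gate.forward(f_prime, train=train)
        u_prime = self.spatial.forward(u, train=train)
        m = u_prime + f
        self._mask = m > 0
        return m * self._mask

    def backward(self, dout):
        dm = dout * self._mask
        du = self.spatial.backward(dm)
        df_prime = self.channel_gate.backward(du)
        return self.pre.backward(df_prime) + dm


# ---------------------------------------------------------------------------
# functional forms of the three attention operations


def _as_batch(x):
    arr = x.values if isinstance(x, FeatureMap) else np.asarray(x)
    if arr.ndim == 3:
        return arr[None].astype(np.float64), True
    return arr, False


def channel_attention(f, params: AttentionParams | None = None, *,
                      block: RAMBlock | None = None, seed: int = 0):
    """Apply preconvs + channel gate to F, returning U (same shape as F)."""
    params = params or AttentionParams()
    arr, squeeze = _as_batch(f)
    if block is None:
        if arr.shape[1] % params.channel_reduction:
            raise ValueError(
                f"channels ({arr.shape[1]}) must be divisible by "
                f"channel_reduction ({params.channel_reduction})")
        block = RAMBlock(arr.shape[1], params, np.random.default_rng(seed))
    f_prime = block.pre.forward(arr)
    u = block.channel_gate.forward(f_prime)
    out = u[0] if squeeze else u
    return FeatureMap(out, "U") if squeeze else out


def spatial_attention(u, params: AttentionParams | None = None, *,
                      block: RAMBlock | None = None, seed: int = 0):
    """Apply the spatial gate to U, returning U' (same shape as U)."""
    params = params or AttentionParams()
    arr, squeeze = _as_batch(u)
    if block is None:
        block = RAMBlock(arr.shape[1], params, np.random.default_rng(seed))
    up = block.spatial.forward(arr)
    return FeatureMap(up[0], "U'") if squeeze else up


def residual_attention_block(f, params: AttentionParams | None = None, *,
                             block: RAMBlock | None = None, seed: int = 0):
    """Full RAM block M = ReLU(U' + F)."""
    params = params or AttentionParams()
    arr, squeeze = _as_batch(f)
    if block is None:
        block = RAMBlock(arr.shape[1], params, np.random.default_rng(seed))
    m = block.forward(arr)
    return FeatureMap(m[0], "M") if squeeze else m


# ---------------------------------------------------------------------------
# residual backbone


class BasicResBlock(nn.Module):
    """Two 3x3 conv+BN with identity (or 1x1 projection) skip, final ReLU."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.project = in_ch != out_ch or stride != 1
        if self.project:
            self.conv_s = nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng)
            self.bn_s = nn.BatchNorm2d(out_ch)
        self._mask = None

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        skip = self.bn_s.forward(self.conv_s.forward(x, train), train) if self.project else x
        out = h + skip
        self._mask = out > 0
        return out * self._mask

    def backward(self, dout):
        d = dout * self._mask
        dh = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        dskip = self.conv_s.backward(self.bn_s.backward(d)) if self.project else d
        return dh + dskip


class Bottleneck(nn.Module):
    """1x1 reduce, 3x3, 1x1 expand bottleneck with projection skip."""

    def __init__(self, in_ch, mid_ch, stride=1, rng=None):
        out_ch = mid_ch * 4
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, pad=0, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, pad=0, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.project = in_ch != out_ch or stride != 1
        if self.project:
            self.conv_s = nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng)
            self.bn_s = nn.BatchNorm2d(out_ch)
        self._mask = None

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train))
        h = self.bn3.forward(self.conv3.forward(h, train), train)
        skip = self.bn_s.forward(self.conv_s.forward(x, train), train) if self.project else x
        out = h + skip
        self._mask = out > 0
        return out * self._mask

    def backward(self, dout):
        d = dout * self._mask
        dh = self.bn3.backward(d)
        dh = self.relu2.backward(self.conv3.backward(dh))
        dh = self.relu1.backward(self.conv2.backward(self.bn2.backward(dh)))
        dh = self.conv1.backward(self.bn1.backward(dh))
        dskip = self.conv_s.backward(self.bn_s.backward(d)) if self.project else d
        return dh + dskip


_VARIANTS = {
    # stem channels, per-stage (block type, n blocks, channel arg, stride), embedding
    "tiny": dict(stem=16, stages=[("basic", 1, 32, 2), ("basic", 1, 64, 2),
                                  ("basic", 1, 128, 2)],
                 embedding=64),
    "resnet50": dict(stem=64, stages=[("bottleneck", 3, 64, 1), ("bottleneck", 4, 128, 2),
                                      ("bottleneck", 6, 256, 2), ("bottleneck", 3, 512, 2)],
                     embedding=2048),
}


class Branch(nn.Module):
    """Single-eye feature extractor: stem, residual stages with RAM blocks
    at the configured insertion points, global average pooling, optional
    linear projection to ``embedding_dim``."""

    def __init__(self, config: BackboneConfig, rng=None):
        config.validate()
        if config.pretrained:
            raise ValueError("pretrained weights are not bundled; use pretrained=False")
        if rng is None:
            rng = np.random.default_rng(0)
        spec = _VARIANTS[config.variant]
        n_stages = len(spec["stages"])
        points = (tuple(range(n_stages)) if config.insertion_points is None
                  else tuple(config.insertion_points))
        for p in points:
            if not (0 <= p < n_stages):
                raise ValueError(f"insertion point {p} outside stages 0..{n_stages - 1}")
        layers = [ConvBNReLU(3, spec["stem"], 3, stride=2, rng=rng)]
        if config.variant == "resnet50":
            layers.append(nn.MaxPool2d(kernel=3, stride=2, pad=1))
        ch = spec["stem"]
        for i, (kind, n_blocks, ch_arg, stride) in enumerate(spec["stages"]):
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                if kind == "basic":
                    layers.append(BasicResBlock(ch, ch_arg, s, rng))
                    ch = ch_arg
                else:
                    layers.append(Bottleneck(ch, ch_arg, s, rng))
                    ch = ch_arg * 4
            if i in points:
                layers.append(RAMBlock(ch, config.attention, rng))
        self.body = nn.Sequential(*layers)
        self.gap = nn.GlobalAvgPool2d()
        self.embedding_dim = config.embedding_dim or spec["embedding"]
        self.proj = (nn.Dense(ch, self.embedding_dim, rng)
                     if self.embedding_dim != ch else None)
        self.config = config

    def forward(self, x, train=False):
        e = self.gap.forward(self.body.forward(x, train=train))
        if self.proj is not None:
            e = self.proj.forward(e)
        return e

    def backward(self, dout):
        if self.proj is not None:
            dout = self.proj.backward(dout)
        return self.body.backward(self.gap.backward(dout))


def build_backbone(config: BackboneConfig, seed: int = 0) -> Branch:
    """Build one deterministic branch network from a config and seed."""
    return Branch(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# fusion


def fuse(y_left, y_right, config: FusionConfig | None = None):
    """Combine two branch outputs: p = (1/T) * (w1*y_left + w2*y_right).

    ``feature_concat`` concatenates instead of averaging (the dense head
    then reduces); both averaging modes share the literal formula.
    """
    config = config or FusionConfig()
    config.validate()
    yl = np.asarray(y_left, dtype=float)
    yr = np.asarray(y_right, dtype=float)
    if yl.shape != yr.shape:
        raise ValueError(f"branch outputs differ in shape: {yl.shape} vs {yr.shape}")
    if config.mode == "feature_concat":
        return np.concatenate([yl, yr], axis=-1)
    w1, w2 = config.weights
    return (w1 * yl + w2 * yr) / config.T


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class BFPCNet(nn.Module):
    """Full binocular classifier.

    Left and right images pass through the branch network (shared weights
    by default; when shared, the pair is stacked into one batch so a
    single forward serves both eyes). Branch outputs are fused, rectified,
    dropped out, and mapped by a dense layer to 8 class scores.
    """

    def __init__(self, backbone: BackboneConfig | None = None,
                 fusion: FusionConfig | None = None, seed: int = 0):
        self.backbone_config = backbone or BackboneConfig()
        self.fusion_config = fusion or FusionConfig()
        self.backbone_config.validate()
        self.fusion_config.validate()
        rng = np.random.default_rng(seed)
        self.branch = Branch(self.backbone_config, rng)
        if not self.backbone_config.share_branches:
            self.branch_right = Branch(self.backbone_config, rng)
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(self.backbone_config.dropout_rate,
                                  np.random.default_rng(rng.integers(2 ** 31)))
        e = self.branch.embedding_dim
        head_in = 2 * e if self.fusion_config.mode == "feature_concat" else e
        self.head = nn.Dense(head_in, N_CLASSES, rng)
        self._cache = None

    # -- forward -----------------------------------------------------------

    def _branch_forward(self, left, right, train):
        if self.backbone_config.share_branches:
            e = self.branch.forward(np.concatenate([left, right], axis=0), train=train)
            n = left.shape[0]
            return e[:n], e[n:]
        return (self.branch.forward(left, train=train),
                self.branch_right.forward(right, train=train))

    def _activate(self, z):
        if self.backbone_config.head_activation == "sigmoid":
            return sigmoid(z)
        return softmax(z)

    def forward_pair(self, left, right, train=False):
        """Return per-class probabilities of shape (N, 8)."""
        left = np.ascontiguousarray(left, dtype=nn.DTYPE)
        right = np.ascontiguousarray(right, dtype=nn.DTYPE)
        if left.shape != right.shape:
            raise ValueError("left/right batches must share shape")
        el, er = self._branch_forward(left, right, train)
        mode = self.fusion_config.mode
        if mode == "prediction_average":
            zl = self.head.forward(self.dropout.forward(
                self.relu.forward(el), train=train))
            # the shared-head second call would clobber caches; run the
            # right eye through functionally identical math
            hr = np.maximum(er, 0.0)
            if self.dropout._mask is not None:
                hr = hr * self.dropout._mask
            zr = hr @ self.head.weight.data + self.head.bias.data
            pl, pr = self._activate(zl), self._activate(zr)
            w1, w2 = self.fusion_config.weights
            probs = (w1 * pl + w2 * pr) / self.fusion_config.T
            self._cache = ("pred", el, er, zl, zr, pl, pr)
            return probs
        fused = fuse(el, er, self.fusion_config).astype(nn.DTYPE)
        z = self.head.forward(self.dropout.forward(self.relu.forward(fused), train=train))
        self._cache = ("feat", left.shape[0])
        return self._activate(z)

    def forward_logits(self, left, right, train=False):
        """Logits for the single-head fusion modes (training fast path)."""
        if self.fusion_config.mode == "prediction_average":
            raise ValueError("prediction_average has two heads; use forward_pair")
        left = np.ascontiguousarray(left, dtype=nn.DTYPE)
        right = np.ascontiguousarray(right, dtype=nn.DTYPE)
        el, er = self._branch_forward(left, right, train)
        fused = fuse(el, er, self.fusion_config).astype(nn.DTYPE)
        z = self.head.forward(self.dropout.forward(self.relu.forward(fused), train=train))
        self._cache = ("feat", left.shape[0])
        return z

    def forward(self, x, train=False):  # Module interface; x = (left, right)
        return self.forward_pair(x[0], x[1], train=train)

    # -- backward ----------------------------------------------------------

    def _branch_backward(self, del_, der):
        if self.backbone_config.share_branches:
            self.branch.backward(np.concatenate([del_, der], axis=0))
        else:
            self.branch.backward(del_)
            self.branch_right.backward(der)

    def backward_logits(self, dz):
        """Backprop from dL/dlogits for the single-head fusion modes."""
        kind = self._cache[0]
        if kind != "feat":
            raise RuntimeError("backward_logits requires a feature-fusion forward")
        dfused = self.relu.backward(self.dropout.backward(
            self.head.backward(dz.astype(nn.DTYPE))))
        w1, w2 = self.fusion_config.weights
        if self.fusion_config.mode == "feature_concat":
            e = self.branch.embedding_dim
            del_, der = dfused[:, :e], dfused[:, e:]
        else:
            t = self.fusion_config.T
            del_, der = dfused * (w1 / t), dfused * (w2 / t)
        self._branch_backward(del_, der)

    def backward_pred(self, dzl, dzr):
        """Backprop from per-branch dL/dlogits in prediction_average mode."""
        kind, el, er, zl, zr, pl, pr = self._cache
        if kind != "pred":
            raise RuntimeError("backward_pred requires a prediction-fusion forward")
        dzl = dzl.astype(nn.DTYPE)
        dzr = dzr.astype(nn.DTYPE)
        dhl = dzl @ self.head.weight.data.T
        dhr = dzr @ self.head.weight.data.T
        hl = np.maximum(el, 0.0)
        hr = np.maximum(er, 0.0)
        mask = self.dropout._mask
        if mask is not None:
            self.head.weight.grad += (hl * mask).T @ dzl + (hr * mask).T @ dzr
            dhl, dhr = dhl * mask, dhr * mask
        else:
            self.head.weight.grad += hl.T @ dzl + hr.T @ dzr
        self.head.bias.grad += dzl.sum(axis=0) + dzr.sum(axis=0)
        self._branch_backward(dhl * (el > 0), dhr * (er > 0))


def predict_labels(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Multi-hot decisions from per-class probabilities."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    return (np.asarray(probs) >= threshold).astype(int)
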