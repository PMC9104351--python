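"""Convolution + Vision-Transformer heartbeat classifier and its ablation variants.

The full model runs a single 1D convolution stage (conv -> batch norm -> ReLU
-> max pool) over a 250-sample normalized heartbeat, splits the resulting
feature map along time into fixed-length patches, projects each patch into a
token, prepends a learned class token, adds learned position embeddings, and
passes the token sequence through a stack of pre-norm Transformer blocks.
The final class-token state feeds a layer-norm + linear + softmax head that
scores the beat as normal sinus rhythm or congestive heart failure (CHF).

With the default configuration (32 kernels, pool 2, patch length 25) a
250-sample beat yields a 32x125 feature map, five patch tokens and six
tokens total including the class token.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

VARIANT_NAMES = (
    "cnn_alexnet1d",
    "vit_only",
    "conv_vit",
    "conv_bn_vit",
    "conv_bn_relu_vit",
    "ecvt_net",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 32 convolution kernels,
    patch length 25, 6 Transformer blocks, 8 attention heads, MLP hidden
    width 2048.  ``embed_dim`` (token width) and ``kernel_size`` are open
    choices, defaulting to 128 and 7.  ``attention_scale`` selects the
    score normalization: ``'sqrt'`` divides by sqrt(d) (standard),
    ``'linear'`` divides by d itself.
    """

    input_len: int = 250
    n_kernels: int = 32
    kernel_size: int = 7
    pool_size: int = 2
    patch_len: int = 25
    depth: int = 6
    n_heads: int = 8
    mlp_dim: int = 2048
    embed_dim: int = 128
    n_classes: int = 2
    dropout: float = 0.0
    attention_scale: str = "sqrt"

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by "
                f"n_heads {self.n_heads}")
        if self.attention_scale not in ("sqrt", "linear"):
            raise ValueError("attention_scale must be 'sqrt' or 'linear'")

    @staticmethod
    def fixture() -> "ModelConfig":
        """Reduced configuration for fast CPU experiments on synthetic
        cohorts: same topology, scaled-down widths, mild dropout."""
        return ModelConfig(n_kernels=8, kernel_size=7, pool_size=2,
                           patch_len=25, depth=2, n_heads=4, mlp_dim=64,
                           embed_dim=32, dropout=0.1)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "ModelConfig":
        return ModelConfig(**json.loads(text))


@dataclass(frozen=True)
class VariantFlags:
    """Toggles for the convolutional-stage ablations."""

    use_conv: bool = True
    use_bn: bool = True
    use_relu: bool = True
    use_pool: bool = True


class ConvBlock(nn.Module):
    """1D conv -> (batch norm) -> (ReLU) -> (max pool), each stage optional."""

    def __init__(self, cfg: ModelConfig, flags: VariantFlags,
                 rng: np.random.Generator):
        self.flags = flags
        self.conv = nn.Conv1d(1, cfg.n_kernels, cfg.kernel_size, rng)
        self.bn = nn.BatchNorm1d(cfg.n_kernels) if flags.use_bn else None
        self.relu = nn.ReLU() if flags.use_relu else None
        self.pool = nn.MaxPool1d(cfg.pool_size) if flags.use_pool else None

    def forward(self, x, training=False):
        x = self.conv(x, training)
        if self.bn is not None:
            x = self.bn(x, training)
        if self.relu is not None:
            x = self.relu(x, training)
        if self.pool is not None:
            x = self.pool(x, training)
        return x

    def backward(self, grad_out):
        if self.pool is not None:
            grad_out = self.pool.backward(grad_out)
        if self.relu is not None:
            grad_out = self.relu.backward(grad_out)
        if self.bn is not None:
            grad_out = self.bn.backward(grad_out)
        return self.conv.backward(grad_out)


class PatchEmbed(nn.Module):
    """Split a (batch, channels, time) feature map into contiguous time
    patches, linearly project each to the token width, prepend a learned
    class token and add learned position embeddings."""

    def __init__(self, n_channels: int, feature_len: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        if feature_len % cfg.patch_len != 0:
            raise ValueError(
                f"feature length {feature_len} not divisible by "
                f"patch length {cfg.patch_len}")
        self.n_patches = feature_len // cfg.patch_len
        self.patch_len = cfg.patch_len
        self.proj = nn.Linear(n_channels * cfg.patch_len, cfg.embed_dim, rng,
                              name="patch_proj")
        self.cls_token = nn.Parameter(
            nn.truncated_normal(rng, (cfg.embed_dim,), 0.02), "cls_token")
        self.pos_embed = nn.Parameter(
            nn.truncated_normal(rng, (self.n_patches + 1, cfg.embed_dim), 0.02),
            "pos_embed")
        self.drop = nn.Dropout(cfg.dropout, rng)

    def forward(self, x, training=False):
        B, C, L = x.shape
        n, p = self.n_patches, self.patch_len
        # (B, C, n, p) -> (B, n, C*p): each patch keeps all channels
        patches = x.reshape(B, C, n, p).transpose(0, 2, 1, 3).reshape(B, n, C * p)
        tokens = self.proj(patches, training)            # (B, n, D)
        cls = np.broadcast_to(self.cls_token.value, (B, 1, tokens.shape[-1]))
        z = np.concatenate([cls, tokens], axis=1) + self.pos_embed.value
        self._in_shape = (B, C, L)
        return self.drop(z, training)

    def backward(self, grad_out):
        B, C, L = self._in_shape
        n, p = self.n_patches, self.patch_len
        grad_out = self.drop.backward(grad_out)
        self.pos_embed.grad += grad_out.sum(axis=0)
        self.cls_token.grad += grad_out[:, 0, :].sum(axis=0)
        gpatches = self.proj.backward(grad_out[:, 1:, :])
        return gpatches.reshape(B, n, C, p).transpose(0, 2, 1, 3).reshape(B, C, L)


class TransformerBlock(nn.Module):
    """Pre-norm residual block: z' = MHA(LN(z)) + z ; z'' = MLP(LN(z')) + z'.

    The MLP has two hidden layers of width ``mlp_dim`` with GELU activations.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, idx: int = 0):
        D = cfg.embed_dim
        self.ln1 = nn.LayerNorm(D, name=f"blk{idx}.ln1")
        self.mha = nn.MultiHeadAttention(D, cfg.n_heads, rng,
                                         scale_mode=cfg.attention_scale,
                                         name=f"blk{idx}.mha")
        self.drop_attn = nn.Dropout(cfg.dropout, rng)
        self.ln2 = nn.LayerNorm(D, name=f"blk{idx}.ln2")
        self.mlp = nn.Sequential(
            nn.Linear(D, cfg.mlp_dim, rng, name=f"blk{idx}.fc1"),
            nn.GELU(),
            nn.Dropout(cfg.dropout, rng),
            nn.Linear(cfg.mlp_dim, cfg.mlp_dim, rng, name=f"blk{idx}.fc2"),
            nn.GELU(),
            nn.Dropout(cfg.dropout, rng),
            nn.Linear(cfg.mlp_dim, D, rng, name=f"blk{idx}.fc3"),
            nn.Dropout(cfg.dropout, rng),
        )

    def forward(self, z, training=False):
        h = self.drop_attn(self.mha(self.ln1(z, training), training), training) + z
        return self.mlp(self.ln2(h, training), training) + h

    def backward(self, grad_out):
        g_h = grad_out + self.ln2.backward(self.mlp.backward(grad_out))
        return g_h + self.ln1.backward(self.mha.backward(
            self.drop_attn.backward(g_h)))


class ClassifierHead(nn.Module):
    """Layer norm then a linear map to class logits, applied to the class token."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.ln = nn.LayerNorm(cfg.embed_dim, name="head.ln")
        self.fc = nn.Linear(cfg.embed_dim, cfg.n_classes, rng,
                            name="head.fc")

    def forward(self, cls_state, training=False):
        return self.fc(self.ln(cls_state, training), training)

    def backward(self, grad_out):
        return self.ln.backward(self.fc.backward(grad_out))


class EcvtNet(nn.Module):
    """The full hybrid classifier; ablation variants reuse this class with
    conv-stage flags toggled or the conv stage removed entirely."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 flags: VariantFlags = VariantFlags(), name: str = "ecvt_net"):
        self.cfg = cfg
        self.name = name
        self.flags = flags
        if flags.use_conv:
            self.conv_block = ConvBlock(cfg, flags, rng)
            feature_len = cfg.input_len // cfg.pool_size if flags.use_pool \
                else cfg.input_len
            n_channels = cfg.n_kernels
        else:
            self.conv_block = None
            feature_len = cfg.input_len
            n_channels = 1
        self.patch_embed = PatchEmbed(n_channels, feature_len, cfg, rng)
        self.blocks = [TransformerBlock(cfg, rng, i) for i in range(cfg.depth)]
        self.head = ClassifierHead(cfg, rng)
        self.n_tokens = self.patch_embed.n_patches + 1

    def forward(self, x, training=False):
        """Beat matrix (batch, input_len) -> class logits (batch, n_classes)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != self.cfg.input_len:
            raise ValueError(
                f"expected beats of length {self.cfg.input_len}, got {x.shape[-1]}")
        x = x[:, None, :]                       # (B, 1, L)
        if self.conv_block is not None:
            x = self.conv_block(x, training)
        z = self.patch_embed(x, training)
        for blk in self.blocks:
            z = blk(z, training)
        return self.head(z[:, 0, :], training)

    def backward(self, grad_logits):
        B = grad_logits.shape[0]
        g_cls = self.head.backward(grad_logits)
        gz = np.zeros((B, self.n_tokens, self.cfg.embed_dim))
        gz[:, 0, :] = g_cls
        for blk in reversed(self.blocks):
            gz = blk.backward(gz)
        gx = self.patch_embed.backward(gz)
        if self.conv_block is not None:
            gx = self.conv_block.backward(gx)
        return gx[:, 0, :]

    def predict_proba(self, x):
        return nn.softmax(self.forward(np.asarray(x), training=False), axis=-1)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


class AlexNet1d(nn.Module):
    """1D adaptation of the classic five-conv / three-FC AlexNet layout,
    used as a CNN-only comparison baseline (comparison baseline, our
    adaptation: the original is a 2D image network)."""

    _CHANNELS = (16, 32, 64, 64, 32)
    _KERNELS = (11, 7, 5, 5, 3)
    _POOL_AFTER = (0, 1, 4)  # stage indices followed by a pool

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 name: str = "cnn_alexnet1d"):
        self.cfg = cfg
        self.name = name
        layers: list[nn.Module] = []
        in_ch, length = 1, cfg.input_len
        for i, (ch, k) in enumerate(zip(self._CHANNELS, self._KERNELS)):
            layers += [nn.Conv1d(in_ch, ch, k, rng, name=f"alex.conv{i}"),
                       nn.BatchNorm1d(ch, name=f"alex.bn{i}"),
                       nn.ReLU()]
            in_ch = ch
            if i in self._POOL_AFTER:
                if length % 2:          # drop the trailing odd sample
                    layers.append(_TrimLast())
                    length -= 1
                layers.append(nn.MaxPool1d(2))
                length //= 2
        self.features = nn.Sequential(*layers)
        self.flat_dim = in_ch * length
        self.classifier = nn.Sequential(
            nn.Linear(self.flat_dim, 256, rng, name="alex.fc1"),
            nn.ReLU(),
            nn.Linear(256, 128, rng, name="alex.fc2"),
            nn.ReLU(),
            nn.Linear(128, cfg.n_classes, rng, name="alex.fc3"),
        )

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        f = self.features(x[:, None, :], training)
        self._fshape = f.shape
        return self.classifier(f.reshape(f.shape[0], -1), training)

    def backward(self, grad_logits):
        g = self.classifier.backward(grad_logits)
        return self.features.backward(g.reshape(self._fshape))

    def predict_proba(self, x):
        return nn.softmax(self.forward(np.asarray(x), training=False), axis=-1)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


class _TrimLast(nn.Module):
    """Drop the final time sample so a pool of 2 divides evenly."""

    def forward(self, x, training=False):
        self._L = x.shape[2]
        return x[:, :, :-1]

    def backward(self, grad_out):
        g = np.zeros(grad_out.shape[:2] + (self._L,))
        g[:, :, :-1] = grad_out
        return g


def build_variant(name: str, cfg: ModelConfig, seed: int = 0):
    """Build one of the named model variants.

    ``ecvt_net`` is the full model; ``conv_vit``/``conv_bn_vit``/
    ``conv_bn_relu_vit`` progressively re-enable batch norm, ReLU and
    pooling after the convolution; ``vit_only`` patches the raw beat
    directly (10 patches of length 25 on a 250-sample beat);
    ``cnn_alexnet1d`` is the CNN-only baseline.
    """
    rng = np.random.default_rng(seed)
    if name == "ecvt_net":
        return EcvtNet(cfg, rng, VariantFlags(), name=name)
    if name == "conv_bn_relu_vit":
        return EcvtNet(cfg, rng, VariantFlags(use_pool=False), name=name)
    if name == "conv_bn_vit":
        return EcvtNet(cfg, rng, VariantFlags(use_relu=False, use_pool=False),
                       name=name)
    if name == "conv_vit":
        return EcvtNet(cfg, rng,
                       VariantFlags(use_bn=False, use_relu=False, use_pool=False),
                       name=name)
    if name == "vit_only":
        return EcvtNet(cfg, rng,
                       VariantFlags(use_conv=False, use_bn=False,
                                    use_relu=False, use_pool=False),
                       name=name)
    if name == "cnn_alexnet1d":
        return AlexNet1d(cfg, rng, name=name)
    raise ValueError(f"unknown variant {name!r}; valid names: {VARIANT_NAMES}")


def save_model(model, path) -> None:
    np.savez(path, **model.state_dict())


def load_model(model, path):
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
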