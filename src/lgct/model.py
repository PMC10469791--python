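"""The three-branch local-global convolutional transformer.

Each of the three frequency-band inputs (raw, mu, beta) is processed by an
identical, independently parameterised branch:

* temporal block — a 1-D temporal convolution and a local-windowed
  transformer encoder share the same receptive field (kernel length ==
  attention window); their outputs are fused (added by default), batch
  normalised, passed through the activation and average-pooled over time;
* spatial block — depthwise filters over all channels, plus two hemisphere
  paths whose difference (left minus right) captures the lateralisation of
  sensorimotor rhythms; midline electrodes are excluded from the hemisphere
  paths;
* T-Dense block — two densely connected branches (a CNN stack and a
  global-transformer stack, each layer fed the concatenation of all earlier
  outputs), concatenated and reduced by a pointwise convolution.

Branch outputs are flattened, concatenated and classified by a single fully
connected softmax layer.

Ablation variants: ``wo_trans`` removes both attention paths, ``wo_diff_hemi``
removes the hemisphere-difference paths, ``wo_tdense`` replaces the dense
units by plain CNN stacks of equal depth.
"""

from __future__ import annotations

import functools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .attention import (
    AttentionConfig,
    positional_encoding,
    transformer_encoder_layer,
)
from .autodiff import Tensor, concat, dropout, einsum, pad_last, softmax, unfold
from .data import Montage
from .utils import derive_seed

__all__ = [
    "ModelConfig",
    "ConfigError",
    "LGCTModel",
    "build_model",
    "make_ablation_variant",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "reference_config",
    "small_config",
    "VARIANTS",
]

VARIANTS = ("full", "wo_trans", "wo_diff_hemi", "wo_tdense")

_VARIANT_ALIASES = {
    "full": "full",
    "w/o_trans": "wo_trans",
    "wo_trans": "wo_trans",
    "w/o_diff-hemi": "wo_diff_hemi",
    "wo_diff_hemi": "wo_diff_hemi",
    "w/o_t-dense": "wo_tdense",
    "wo_tdense": "wo_tdense",
    "w/o_tdense": "wo_tdense",
}


class ConfigError(ValueError):
    """Invalid model configuration; carries the offending field name."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class ModelConfig:
    """All architecture hyperparameters in one place.

    The temporal kernel length and the local-attention window are a single
    knob: both paths of the temporal block see the same receptive field.
    """

    n_channels: int
    n_samples: int
    n_classes: int
    n_bands: int = 3
    temporal_filters: int = 8
    temporal_kernel: int = 25  # samples; == local attention window
    pool_len: int = 75
    pool_stride: int = 15
    token_embed_dim: int = 16
    n_heads: int = 2
    spatial_filters: int = 8  # per spatial path
    tdense_layers: int = 3
    tdense_growth: int = 8
    tdense_kernel: int = 5
    reduce_filters: int = 16
    activation: str = "elu"
    dropout_rate: float = 0.5
    temporal_fusion: str = "add"  # {"add", "concat"}
    dtype: str = "float32"  # compute/parameter precision
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels", "must be positive")
        if self.n_samples < self.temporal_kernel:
            raise ConfigError("n_samples", "shorter than the temporal kernel")
        if self.n_classes < 2:
            raise ConfigError("n_classes", "need at least 2 classes")
        if self.n_bands != 3:
            raise ConfigError("n_bands", "the architecture takes exactly 3 bands")
        if self.temporal_kernel % 2 == 0 or self.temporal_kernel < 1:
            raise ConfigError("temporal_kernel", "must be odd and positive "
                              "(it doubles as the local attention window)")
        if self.pool_len > self.n_samples or self.pool_len < 1:
            raise ConfigError("pool_len", "must be in [1, n_samples]")
        if self.pool_stride < 1:
            raise ConfigError("pool_stride", "must be positive")
        if self.token_embed_dim % (2 * self.n_heads) != 0:
            raise ConfigError("token_embed_dim",
                              "must be even and divisible by n_heads")
        if self.tdense_layers < 2:
            raise ConfigError("tdense_layers", "dense connectivity needs >= 2")
        if self.tdense_growth % self.n_heads != 0 or self.tdense_growth % 2 != 0:
            raise ConfigError("tdense_growth",
                              "must be even and divisible by n_heads")
        if self.tdense_kernel % 2 == 0:
            raise ConfigError("tdense_kernel", "must be odd ('same' padding)")
        if self.activation not in ("elu", "relu"):
            raise ConfigError("activation", f"unsupported: {self.activation!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate", "must be in [0, 1)")
        if self.temporal_fusion not in ("add", "concat"):
            raise ConfigError("temporal_fusion", "must be 'add' or 'concat'")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError("dtype", "must be 'float32' or 'float64'")

    @property
    def pooled_len(self) -> int:
        return (self.n_samples - self.pool_len) // self.pool_stride + 1

    def local_attention(self) -> AttentionConfig:
        d = self.token_embed_dim
        return AttentionConfig(self.n_heads, d, d // self.n_heads,
                               d // self.n_heads, "local", self.temporal_kernel)

    def global_attention(self) -> AttentionConfig:
        g = self.tdense_growth
        return AttentionConfig(self.n_heads, g, g // self.n_heads,
                               g // self.n_heads, "global", None)


def reference_config(n_channels: int, n_samples: int, n_classes: int,
                     seed: int = 0) -> ModelConfig:
    """The frozen reference hyperparameters (0.1-s kernel at 250 Hz)."""
    return ModelConfig(n_channels=n_channels, n_samples=n_samples,
                       n_classes=n_classes, seed=seed)


def small_config(n_channels: int, n_samples: int, n_classes: int,
                 seed: int = 0) -> ModelConfig:
    """A reduced configuration for CPU-scale experiments and simulations."""
    return ModelConfig(
        n_channels=n_channels, n_samples=n_samples, n_classes=n_classes,
        temporal_filters=4, temporal_kernel=13, pool_len=40, pool_stride=10,
        token_embed_dim=8, spatial_filters=4, tdense_growth=4,
        tdense_kernel=5, reduce_filters=8, dropout_rate=0.25, seed=seed,
    )


# ---------------------------------------------------------------------------
# building blocks (functional, on autodiff Tensors)
# ---------------------------------------------------------------------------


def _conv1d_same(x: Tensor, w: Tensor, b: Tensor | None, spec: str) -> Tensor:
    """'Same'-padded 1-D convolution along the last axis via unfold+einsum."""
    k = w.shape[-1]
    left = (k - 1) // 2
    xu = unfold(pad_last(x, left, k - 1 - left), k)
    out = einsum(spec, xu, w)
    if b is not None:
        shape = [1] * out.ndim
        shape[1] = -1
        out = out + b.reshape(shape)
    return out


def _avg_pool_time(x: Tensor, pool_len: int, stride: int) -> Tensor:
    return unfold(x, pool_len, stride).mean(axis=-1)


def _batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, channel_axis: int = 1,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    axes = tuple(a for a in range(x.ndim) if a != channel_axis)
    shape = [1] * x.ndim
    shape[channel_axis] = -1
    if training:
        mean = x.mean(axis=axes, keepdims=True)
        var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] \
            + momentum * mean.data.reshape(-1)
        running["var"] = (1 - momentum) * running["var"] \
            + momentum * var.data.reshape(-1)
    else:
        mean = Tensor(running["mean"].reshape(shape))
        var = Tensor(running["var"].reshape(shape))
    xhat = (x - mean) / ((var + eps) ** 0.5)
    return xhat * gamma.reshape(shape) + beta.reshape(shape)


def _act(x: Tensor, name: str) -> Tensor:
    return x.elu() if name == "elu" else x.relu()


@functools.lru_cache(maxsize=8)
def _pe_const(seq_len: int, d: int, dtype: str = "float64") -> Tensor:
    return Tensor(positional_encoding(seq_len, d).astype(dtype))


class LGCTModel:
    """Built network: parameter store, batch-norm buffers and forward pass."""

    def __init__(self, cfg: ModelConfig, variant: str = "full"):
        cfg.validate()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        self.dtype = np.dtype(cfg.dtype)
        self.params: dict[str, Tensor] = {}
        self.buffers: dict[str, dict[str, np.ndarray]] = {}
        self.attention_calls = 0
        self._rng_init = np.random.default_rng(derive_seed(cfg.seed, "init"))
        self.rng_dropout = np.random.default_rng(derive_seed(cfg.seed, "dropout"))
        self._montage: Montage | None = None
        for b in range(cfg.n_bands):
            self._init_branch(b)
        self._init_head()

    # -- parameter initialisation --------------------------------------
    def _param(self, name: str, shape, fan_in: int, fan_out: int,
               zero: bool = False, one: bool = False) -> None:
        if zero:
            data = np.zeros(shape)
        elif one:
            data = np.ones(shape)
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            data = self._rng_init.uniform(-limit, limit, size=shape)
        self.params[name] = Tensor(data.astype(self.dtype), requires_grad=True)

    def _bn(self, name: str, width: int) -> None:
        self._param(f"{name}/bn_g", (width,), 0, 0, one=True)
        self._param(f"{name}/bn_b", (width,), 0, 0, zero=True)
        self.buffers[name] = {"mean": np.zeros(width, dtype=self.dtype),
                              "var": np.ones(width, dtype=self.dtype)}

    def _encoder_params(self, prefix: str, attn: AttentionConfig) -> None:
        h, dm, dk, dv = attn.n_heads, attn.d_model, attn.d_k, attn.d_v
        self._param(f"{prefix}/w_q", (h, dm, dk), dm, dk)
        self._param(f"{prefix}/w_k", (h, dm, dk), dm, dk)
        self._param(f"{prefix}/w_v", (h, dm, dv), dm, dv)
        self._param(f"{prefix}/w_o", (h * dv, dm), h * dv, dm)
        self._param(f"{prefix}/b_o", (dm,), 0, 0, zero=True)
        self._param(f"{prefix}/ln1_g", (dm,), 0, 0, one=True)
        self._param(f"{prefix}/ln1_b", (dm,), 0, 0, zero=True)
        self._param(f"{prefix}/ln2_g", (dm,), 0, 0, one=True)
        self._param(f"{prefix}/ln2_b", (dm,), 0, 0, zero=True)
        d_ff = 2 * dm
        self._param(f"{prefix}/w_ff1", (dm, d_ff), dm, d_ff)
        self._param(f"{prefix}/b_ff1", (d_ff,), 0, 0, zero=True)
        self._param(f"{prefix}/w_ff2", (d_ff, dm), d_ff, dm)
        self._param(f"{prefix}/b_ff2", (dm,), 0, 0, zero=True)

    def _encoder_param_dict(self, prefix: str) -> dict[str, Tensor]:
        keys = ("w_q", "w_k", "w_v", "w_o", "b_o", "ln1_g", "ln1_b", "ln2_g",
                "ln2_b", "w_ff1", "b_ff1", "w_ff2", "b_ff2")
        return {k: self.params[f"{prefix}/{k}"] for k in keys}

    def _init_branch(self, b: int) -> None:
        cfg = self.cfg
        pre = f"b{b}"
        F, k, E = cfg.temporal_filters, cfg.temporal_kernel, cfg.token_embed_dim
        # temporal block
        self._param(f"{pre}/temporal/conv_w", (F, k), k, F)
        self._param(f"{pre}/temporal/conv_b", (F,), 0, 0, zero=True)
        if self.variant != "wo_trans":
            self._param(f"{pre}/temporal/lift_w", (E,), 1, E)
            self._param(f"{pre}/temporal/lift_b", (E,), 0, 0, zero=True)
            self._encoder_params(f"{pre}/temporal/enc", cfg.local_attention())
            self._param(f"{pre}/temporal/proj_w", (E, F), E, F)
            self._param(f"{pre}/temporal/proj_b", (F,), 0, 0, zero=True)
        Ft = self._temporal_width()
        self._bn(f"{pre}/temporal", Ft)
        # spatial block
        C, S = cfg.n_channels, cfg.spatial_filters
        self._param(f"{pre}/spatial/w_all", (S, C), C, S)
        self._param(f"{pre}/spatial/b_all", (S,), 0, 0, zero=True)
        # hemisphere-path weights are created in bind_montage(), once the
        # left/right channel partition is known
        self._bn(f"{pre}/spatial", self._spatial_width())
        # T-Dense block
        D0, g, L, kt = self._spatial_width(), cfg.tdense_growth, \
            cfg.tdense_layers, cfg.tdense_kernel
        if self.variant == "wo_tdense":
            for i in range(L):
                self._param(f"{pre}/tdense/plain{i}/w", (D0, D0, kt), D0 * kt, D0)
                self._param(f"{pre}/tdense/plain{i}/b", (D0,), 0, 0, zero=True)
                self._bn(f"{pre}/tdense/plain{i}", D0)
            unit_width = D0
        else:
            for i in range(L):
                width = D0 + i * g
                self._param(f"{pre}/tdense/cnn{i}/w", (g, width, kt), width * kt, g)
                self._param(f"{pre}/tdense/cnn{i}/b", (g,), 0, 0, zero=True)
                self._bn(f"{pre}/tdense/cnn{i}", g)
            unit_width = D0 + L * g
            if self.variant != "wo_trans":
                for i in range(L):
                    width = D0 + i * g
                    self._param(f"{pre}/tdense/trans{i}/proj_w", (g, width), width, g)
                    self._param(f"{pre}/tdense/trans{i}/proj_b", (g,), 0, 0,
                                zero=True)
                    self._encoder_params(f"{pre}/tdense/trans{i}/enc",
                                         cfg.global_attention())
                    self._bn(f"{pre}/tdense/trans{i}", g)
                unit_width = 2 * (D0 + L * g)
        self._param(f"{pre}/reduce/w", (cfg.reduce_filters, unit_width),
                    unit_width, cfg.reduce_filters)
        self._param(f"{pre}/reduce/b", (cfg.reduce_filters,), 0, 0, zero=True)
        self._bn(f"{pre}/reduce", cfg.reduce_filters)

    def _temporal_width(self) -> int:
        F = self.cfg.temporal_filters
        if self.cfg.temporal_fusion == "concat" and self.variant != "wo_trans":
            return 2 * F
        return F

    def _spatial_width(self) -> int:
        FS = self._temporal_width() * self.cfg.spatial_filters
        return FS if self.variant == "wo_diff_hemi" else 2 * FS

    def _init_head(self) -> None:
        cfg = self.cfg
        d_in = cfg.n_bands * cfg.reduce_filters * cfg.pooled_len
        self._param("head/w", (d_in, cfg.n_classes), d_in, cfg.n_classes)
        self._param("head/b", (cfg.n_classes,), 0, 0, zero=True)

    # -- montage binding (hemisphere paths need the channel partition) --
    def bind_montage(self, montage: Montage) -> None:
        """Attach the montage; creates the hemisphere-path parameters."""
        if montage.n_channels != self.cfg.n_channels:
            raise ConfigError("n_channels",
                              f"montage has {montage.n_channels} channels, "
                              f"config says {self.cfg.n_channels}")
        if self.variant != "wo_diff_hemi" and len(montage.left_idx) == 0:
            raise ValueError("montage has no hemisphere pairs; use the "
                             "wo_diff_hemi variant for midline-only montages")
        self._montage = montage
        if self.variant == "wo_diff_hemi":
            return
        S, Ch = self.cfg.spatial_filters, len(montage.left_idx)
        for b in range(self.cfg.n_bands):
            for side in ("left", "right"):
                name = f"b{b}/spatial/w_{side}"
                if name not in self.params:
                    self._param(name, (S, Ch), Ch, S)
                    self._param(f"b{b}/spatial/b_{side}", (S,), 0, 0, zero=True)
                elif self.params[name].shape != (S, Ch):
                    raise ConfigError("n_channels",
                                      "montage hemisphere size changed after build")

    @property
    def montage(self) -> Montage | None:
        return self._montage

    # -- forward -------------------------------------------------------
    def forward(self, bands: list[np.ndarray], training: bool = False) -> Tensor:
        """bands: three (trials, channels, samples) arrays -> (trials, classes)
        class probabilities."""
        cfg = self.cfg
        if len(bands) != cfg.n_bands:
            raise ValueError(f"expected {cfg.n_bands} band arrays, got {len(bands)}")
        feats = []
        for b, x in enumerate(bands):
            x = np.asarray(x, dtype=self.dtype)
            if x.ndim != 3 or x.shape[1] != cfg.n_channels \
                    or x.shape[2] != cfg.n_samples:
                raise ValueError(
                    f"band {b}: expected (n, {cfg.n_channels}, {cfg.n_samples}), "
                    f"got {x.shape}")
            feats.append(self._branch(b, Tensor(x), training))
        fused = concat(feats, axis=-1)
        logits = fused @ self.params["head/w"] + self.params["head/b"]
        return softmax(logits, axis=-1)

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        return dropout(x, self.cfg.dropout_rate, self.rng_dropout, training)

    def _encoder(self, x: Tensor, prefix: str, attn: AttentionConfig,
                 training: bool) -> Tensor:
        self.attention_calls += 1
        out = transformer_encoder_layer(x, attn,
                                        self._encoder_param_dict(prefix),
                                        activation=self.cfg.activation)
        return self._dropout(out, training)

    def _branch(self, b: int, x: Tensor, training: bool) -> Tensor:
        h = self._temporal_block(b, x, training)
        feat = self._spatial_block(b, h, training)
        red = self._tdense_block(b, feat, training)
        return red.reshape(x.shape[0],
                           self.cfg.reduce_filters * self.cfg.pooled_len)

    def _temporal_block(self, b: int, x: Tensor, training: bool,
                        pool: bool = True) -> Tensor:
        """(n, C, T) -> (n, Ft, C, Tp); pool=False skips the pooling stage
        (used by locality probes)."""
        cfg = self.cfg
        p = self.params
        pre = f"b{b}"
        n = x.shape[0]
        conv = _conv1d_same(x, p[f"{pre}/temporal/conv_w"], None, "bctk,fk->bfct")
        conv = conv + p[f"{pre}/temporal/conv_b"].reshape(1, -1, 1, 1)
        if self.variant != "wo_trans":
            tok = x.reshape(n, cfg.n_channels, cfg.n_samples, 1) \
                * p[f"{pre}/temporal/lift_w"] + p[f"{pre}/temporal/lift_b"]
            tok = tok + _pe_const(cfg.n_samples, cfg.token_embed_dim,
                                  cfg.dtype)
            enc = self._encoder(tok, f"{pre}/temporal/enc",
                                cfg.local_attention(), training)
            proj = enc @ p[f"{pre}/temporal/proj_w"] + p[f"{pre}/temporal/proj_b"]
            trans = proj.transpose(0, 3, 1, 2)  # (n, F, C, T)
            if cfg.temporal_fusion == "add":
                h = conv + trans
            else:
                h = concat([conv, trans], axis=1)
        else:
            h = conv
        h = _batchnorm(h, p[f"{pre}/temporal/bn_g"], p[f"{pre}/temporal/bn_b"],
                       self.buffers[f"{pre}/temporal"], training)
        h = _act(h, cfg.activation)
        if pool:
            h = _avg_pool_time(h, cfg.pool_len, cfg.pool_stride)
        return h

    def _spatial_block(self, b: int, h: Tensor, training: bool) -> Tensor:
        """(n, Ft, C, Tp) -> (n, D0, Tp) with D0 the concatenated all-channel
        and hemisphere-difference feature count."""
        cfg = self.cfg
        p = self.params
        pre = f"b{b}"
        n = h.shape[0]
        s_all = einsum("bfct,sc->bfst", h, p[f"{pre}/spatial/w_all"]) \
            + p[f"{pre}/spatial/b_all"].reshape(1, 1, -1, 1)
        Ft = self._temporal_width()
        s_all = s_all.reshape(n, Ft * cfg.spatial_filters, cfg.pooled_len)
        if self.variant != "wo_diff_hemi":
            if self._montage is None:
                raise RuntimeError("hemisphere paths require bind_montage() first")
            li = np.asarray(self._montage.left_idx)
            ri = np.asarray(self._montage.right_idx)
            hl = h[:, :, li, :]
            hr = h[:, :, ri, :]
            s_l = einsum("bfct,sc->bfst", hl, p[f"{pre}/spatial/w_left"]) \
                + p[f"{pre}/spatial/b_left"].reshape(1, 1, -1, 1)
            s_r = einsum("bfct,sc->bfst", hr, p[f"{pre}/spatial/w_right"]) \
                + p[f"{pre}/spatial/b_right"].reshape(1, 1, -1, 1)
            diff = (s_l - s_r).reshape(n, Ft * cfg.spatial_filters, cfg.pooled_len)
            feat = concat([s_all, diff], axis=1)
        else:
            feat = s_all
        feat = _batchnorm(feat, p[f"{pre}/spatial/bn_g"], p[f"{pre}/spatial/bn_b"],
                          self.buffers[f"{pre}/spatial"], training)
        return _act(feat, cfg.activation)

    def _tdense_block(self, b: int, feat: Tensor, training: bool) -> Tensor:
        cfg = self.cfg
        p = self.params
        pre = f"b{b}"
        unit = self._tdense_unit(b, feat, training)
        red = einsum("bdt,rd->brt", unit, p[f"{pre}/reduce/w"]) \
            + p[f"{pre}/reduce/b"].reshape(1, -1, 1)
        red = _batchnorm(red, p[f"{pre}/reduce/bn_g"], p[f"{pre}/reduce/bn_b"],
                         self.buffers[f"{pre}/reduce"], training)
        return _act(red, cfg.activation)

    def _tdense_unit(self, b: int, feat: Tensor, training: bool) -> Tensor:
        cfg = self.cfg
        p = self.params
        pre = f"b{b}"
        L, g, kt = cfg.tdense_layers, cfg.tdense_growth, cfg.tdense_kernel
        if self.variant == "wo_tdense":
            h = feat
            for i in range(L):
                z = _conv1d_same(h, p[f"{pre}/tdense/plain{i}/w"],
                                 p[f"{pre}/tdense/plain{i}/b"], "bdtk,gdk->bgt")
                z = _batchnorm(z, p[f"{pre}/tdense/plain{i}/bn_g"],
                               p[f"{pre}/tdense/plain{i}/bn_b"],
                               self.buffers[f"{pre}/tdense/plain{i}"], training)
                h = self._dropout(_act(z, cfg.activation), training)
            return h
        # CNN dense branch
        cat = feat
        for i in range(L):
            z = _conv1d_same(cat, p[f"{pre}/tdense/cnn{i}/w"],
                             p[f"{pre}/tdense/cnn{i}/b"], "bdtk,gdk->bgt")
            z = _batchnorm(z, p[f"{pre}/tdense/cnn{i}/bn_g"],
                           p[f"{pre}/tdense/cnn{i}/bn_b"],
                           self.buffers[f"{pre}/tdense/cnn{i}"], training)
            z = self._dropout(_act(z, cfg.activation), training)
            cat = concat([cat, z], axis=1)
        cnn_out = cat
        if self.variant == "wo_trans":
            return cnn_out
        # global-transformer dense branch
        attn = cfg.global_attention()
        pe = _pe_const(cfg.pooled_len, g, cfg.dtype)
        cat = feat
        for i in range(L):
            z = einsum("bdt,gd->bgt", cat, p[f"{pre}/tdense/trans{i}/proj_w"]) \
                + p[f"{pre}/tdense/trans{i}/proj_b"].reshape(1, -1, 1)
            tokens = z.transpose(0, 2, 1) + pe
            enc = self._encoder(tokens, f"{pre}/tdense/trans{i}/enc", attn,
                                training)
            z = enc.transpose(0, 2, 1)
            z = _batchnorm(z, p[f"{pre}/tdense/trans{i}/bn_g"],
                           p[f"{pre}/tdense/trans{i}/bn_b"],
                           self.buffers[f"{pre}/tdense/trans{i}"], training)
            z = self._dropout(z, training)
            cat = concat([cat, z], axis=1)
        trans_out = cat
        return concat([cnn_out, trans_out], axis=1)

    # -- parameter plumbing --------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All state needed to reproduce outputs: params + BN buffers."""
        out = {name: t.data for name, t in self.params.items()}
        for name, buf in self.buffers.items():
            out[f"{name}/running_mean"] = buf["mean"]
            out[f"{name}/running_var"] = buf["var"]
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.params.items():
            arr = state[name]
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = arr.astype(self.dtype).copy()
        for name, buf in self.buffers.items():
            buf["mean"] = state[f"{name}/running_mean"].astype(self.dtype).copy()
            buf["var"] = state[f"{name}/running_var"].astype(self.dtype).copy()


def build_model(cfg: ModelConfig, montage: Montage | None = None,
                variant: str = "full") -> LGCTModel:
    """Build the network; all parameters are initialised from cfg.seed."""
    model = LGCTModel(cfg, variant=variant)
    if montage is not None:
        model.bind_montage(montage)
    return model


def make_ablation_variant(cfg: ModelConfig, which: str,
                          montage: Montage | None = None) -> LGCTModel:
    key = _VARIANT_ALIASES.get(which.lower())
    if key is None:
        raise ValueError(f"unknown ablation variant {which!r}; "
                         f"expected one of {sorted(set(_VARIANT_ALIASES))}")
    return build_model(cfg, montage=montage, variant=key)


def count_parameters(model: LGCTModel) -> int:
    """Trainable scalar parameters (batch-norm scale/shift included,
    running statistics excluded)."""
    return int(sum(t.size for t in model.params.values()))


# ---------------------------------------------------------------------------
# checkpointing: config.json + params.json (name/shape/offset index) +
# params.bin (little-endian float64, concatenated in index order)
# ---------------------------------------------------------------------------


def save_checkpoint(model: LGCTModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"model": asdict(model.cfg), "variant": model.variant}
    if model.montage is not None:
        meta["montage"] = list(model.montage.channel_names)
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    state = model.state_arrays()
    index, blobs, offset = [], [], 0
    for name in sorted(state):
        arr = np.ascontiguousarray(state[name])
        arr = arr.astype(arr.dtype.newbyteorder("<"))
        index.append({"name": name, "shape": list(arr.shape),
                      "dtype": arr.dtype.str, "offset": offset})
        blobs.append(arr.tobytes())
        offset += arr.nbytes
    (path / "params.json").write_text(json.dumps(index))
    (path / "params.bin").write_bytes(b"".join(blobs))


def load_checkpoint(path) -> LGCTModel:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    cfg = ModelConfig(**meta["model"])
    montage = Montage.from_labels(meta["montage"]) if "montage" in meta else None
    model = build_model(cfg, montage=montage, variant=meta["variant"])
    raw = (path / "params.bin").read_bytes()
    state = {}
    for entry in json.loads((path / "params.json").read_text()):
        shape = tuple(entry["shape"])
        n = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(raw, dtype=entry.get("dtype", "<f8"), count=n,
                            offset=entry["offset"]).reshape(shape)
        state[entry["name"]] = arr
    model.load_state_arrays(state)
    return model
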