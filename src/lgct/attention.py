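"""Scaled dot-product and multi-head self-attention, local (banded) versus
global attention patterns, and sinusoidal positional encoding.

Two equivalent realisations of local attention are provided: a banded
boolean mask over the full score matrix (transparent, used at test scale)
and a sliding-window implementation that never materialises the n x n score
matrix (used inside the model for long raw-EEG sequences). Both agree to
float precision.

Functions accept numpy arrays or autodiff Tensors; with plain arrays the
result is a plain array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "AttentionConfig",
    "AttentionMask",
    "scaled_dot_product_attention",
    "multi_head_attention",
    "local_attention_mask",
    "positional_encoding",
    "transformer_encoder_layer",
    "local_attention_windowed",
]

_NEG = -1e30  # additive mask logit; underflows to exactly zero weight


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters of one multi-head attention block."""

    n_heads: int = 2
    d_model: int = 16
    d_k: int = 8
    d_v: int = 8
    mode: str = "global"  # {"local", "global"}
    window: int | None = None  # odd, local mode only

    def __post_init__(self):
        if self.n_heads < 1 or self.d_k < 1 or self.d_v < 1 or self.d_model < 1:
            raise ValueError("attention dimensions must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown attention mode {self.mode!r}")
        if self.mode == "local":
            if self.window is None or self.window < 1 or self.window % 2 == 0:
                raise ValueError("local attention requires an odd window >= 1")


@dataclass
class AttentionMask:
    """Boolean matrix of allowed (query row, key column) score positions."""

    seq_len: int
    allowed: np.ndarray

    def __post_init__(self):
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.shape != (self.seq_len, self.seq_len):
            raise ValueError("mask must be seq_len x seq_len")
        if not self.allowed.diagonal().all():
            raise ValueError("the diagonal must always be allowed")
        if not self.allowed.any(axis=1).all():
            raise ValueError("every query row needs at least one allowed key")


def local_attention_mask(seq_len: int, window: int) -> AttentionMask:
    """Banded mask: position i attends to j iff |i - j| <= (window-1)/2."""
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = (window - 1) // 2
    idx = np.arange(seq_len)
    allowed = np.abs(idx[:, None] - idx[None, :]) <= half
    return AttentionMask(seq_len, allowed)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def scaled_dot_product_attention(Q, K, V, mask: AttentionMask | None = None):
    """softmax(Q K^T / sqrt(d_k)) V, with optional masking of score positions.

    Q: (..., n, d_k), K: (..., m, d_k), V: (..., m, d_v) -> (..., n, d_v).
    """
    plain = not isinstance(Q, Tensor)
    Qt, Kt, Vt = _wrap(Q), _wrap(K), _wrap(V)
    d_k = Qt.shape[-1]
    if Kt.shape[-1] != d_k:
        raise ValueError("Q and K must share the key dimension")
    scores = (Qt @ Kt.transpose(*range(Kt.ndim - 2), Kt.ndim - 1, Kt.ndim - 2)) \
        * float(1.0 / np.sqrt(d_k))
    if mask is not None:
        if mask.allowed.shape != (Qt.shape[-2], Kt.shape[-2]):
            raise ValueError("mask shape does not match (n, m)")
        scores = scores + Tensor(np.where(mask.allowed, 0.0, _NEG))
    weights = softmax(scores, axis=-1)
    out = weights @ Vt
    return out.data if plain else out


def positional_encoding(seq_len: int, d: int) -> np.ndarray:
    """Sinusoidal position code: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d)). Added to token embeddings by
    the caller."""
    if d % 2 != 0:
        raise ValueError(f"embedding dimension must be even, got {d}")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i2 = np.arange(0, d, 2, dtype=np.float64)
    angle = pos / np.power(10000.0, i2 / d)
    pe = np.empty((seq_len, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def multi_head_attention(X, cfg: AttentionConfig, params: dict,
                         mask: AttentionMask | None = None):
    """Concat(head_1..head_h) W^O with learned per-head Q/K/V projections.

    params: w_q, w_k (h, d_model, d_k); w_v (h, d_model, d_v);
    w_o (h*d_v, d_model); optional b_o (d_model,).
    """
    plain = not isinstance(X, Tensor)
    Xt = _wrap(X)
    h, dm, dk, dv = cfg.n_heads, cfg.d_model, cfg.d_k, cfg.d_v
    w_q, w_k, w_v, w_o = (params[k] for k in ("w_q", "w_k", "w_v", "w_o"))
    for name, w, shape in (("w_q", w_q, (h, dm, dk)), ("w_k", w_k, (h, dm, dk)),
                           ("w_v", w_v, (h, dm, dv)), ("w_o", w_o, (h * dv, dm))):
        if tuple(w.shape) != shape:
            raise ValueError(f"{name} has shape {tuple(w.shape)}, expected {shape}")
    heads = []
    for i in range(h):
        Qi = Xt @ w_q[i]
        Ki = Xt @ w_k[i]
        Vi = Xt @ w_v[i]
        heads.append(scaled_dot_product_attention(Qi, Ki, Vi, mask))
    out = concat(heads, axis=-1) @ w_o
    if "b_o" in params:
        out = out + params["b_o"]
    return out.data if plain else out


def local_attention_windowed(Q, K, V, window: int):
    """Banded local attention without the full n x n score matrix.

    Q, K: (..., n, d_k); V: (..., n, d_v). Equivalent to masking with
    local_attention_mask(n, window), but computed per diagonal offset on
    contiguous slices (a fused op with a hand-derived backward), so memory
    stays O(n * window) instead of O(n^2).
    """
    plain = not isinstance(Q, Tensor)
    Qt, Kt, Vt = _wrap(Q), _wrap(K), _wrap(V)
    n = Qt.shape[-2]
    if window >= 2 * n - 1:
        out = scaled_dot_product_attention(Qt, Kt, Vt)
        return out.data if plain else out
    out = _banded_attention(Qt, Kt, Vt, window)
    return out.data if plain else out


def _band_ranges(n: int, window: int):
    half = (window - 1) // 2
    for j, off in enumerate(range(-half, half + 1)):
        lo, hi = max(0, -off), min(n, n - off)  # rows i with 0 <= i+off < n
        yield j, off, lo, hi


def _banded_attention(Q: Tensor, K: Tensor, V: Tensor, window: int) -> Tensor:
    qd, kd, vd = Q.data, K.data, V.data
    n, d_k = qd.shape[-2], qd.shape[-1]
    scale = float(1.0 / np.sqrt(d_k))
    S = np.full(qd.shape[:-1] + (window,), -np.inf, dtype=qd.dtype)
    for j, off, lo, hi in _band_ranges(n, window):
        S[..., lo:hi, j] = np.einsum(
            "...nd,...nd->...n", qd[..., lo:hi, :], kd[..., lo + off:hi + off, :]
        ) * scale
    S -= S.max(axis=-1, keepdims=True)
    W = np.exp(S)
    W /= W.sum(axis=-1, keepdims=True)
    out_data = np.zeros(qd.shape[:-1] + (vd.shape[-1],), dtype=qd.dtype)
    for j, off, lo, hi in _band_ranges(n, window):
        out_data[..., lo:hi, :] += W[..., lo:hi, j:j + 1] * vd[..., lo + off:hi + off, :]

    def bw(g):
        dW = np.zeros_like(W)
        dV = np.zeros_like(vd) if V.requires_grad else None
        for j, off, lo, hi in _band_ranges(n, window):
            dW[..., lo:hi, j] = np.einsum(
                "...nd,...nd->...n", g[..., lo:hi, :], vd[..., lo + off:hi + off, :])
            if dV is not None:
                dV[..., lo + off:hi + off, :] += W[..., lo:hi, j:j + 1] * g[..., lo:hi, :]
        dS = W * (dW - (dW * W).sum(axis=-1, keepdims=True))
        if Q.requires_grad:
            dQ = np.zeros_like(qd)
            for j, off, lo, hi in _band_ranges(n, window):
                dQ[..., lo:hi, :] += dS[..., lo:hi, j:j + 1] \
                    * kd[..., lo + off:hi + off, :]
            Q._accum(dQ * scale)
        if K.requires_grad:
            dK = np.zeros_like(kd)
            for j, off, lo, hi in _band_ranges(n, window):
                dK[..., lo + off:hi + off, :] += dS[..., lo:hi, j:j + 1] \
                    * qd[..., lo:hi, :]
            K._accum(dK * scale)
        if dV is not None:
            V._accum(dV)

    return Tensor._make(out_data, (Q, K, V), bw)


def transformer_encoder_layer(X, cfg: AttentionConfig, params: dict,
                              activation: str = "elu",
                              windowed: bool = True):
    """Post-norm encoder layer: attention + residual + layer norm, then a
    position-wise feed-forward (width 2*d_model) + residual + layer norm.

    Extra params beyond multi_head_attention's: ln1_g, ln1_b, ln2_g, ln2_b
    (d_model,); w_ff1 (d_model, d_ff), b_ff1, w_ff2 (d_ff, d_model), b_ff2.
    """
    plain = not isinstance(X, Tensor)
    Xt = _wrap(X)
    n = Xt.shape[-2]
    if cfg.mode == "local" and cfg.window < 2 * n - 1:
        if windowed:
            att = _mha_local_windowed(Xt, cfg, params)
        else:
            att = multi_head_attention(Xt, cfg, params,
                                       local_attention_mask(n, cfg.window))
    else:
        att = multi_head_attention(Xt, cfg, params, None)
    from .autodiff import layer_norm

    h = layer_norm(Xt + att, params["ln1_g"], params["ln1_b"])
    ff = h @ params["w_ff1"] + params["b_ff1"]
    ff = ff.elu() if activation == "elu" else ff.relu()
    ff = ff @ params["w_ff2"] + params["b_ff2"]
    out = layer_norm(h + ff, params["ln2_g"], params["ln2_b"])
    return out.data if plain else out


def _mha_local_windowed(Xt: Tensor, cfg: AttentionConfig, params: dict) -> Tensor:
    """Multi-head attention with the sliding-window local realisation,
    all heads batched along a dedicated axis."""
    n = Xt.shape[-2]
    Xe = Xt.reshape(*Xt.shape[:-2], 1, n, cfg.d_model)  # head broadcast axis
    Q = Xe @ params["w_q"]  # (..., h, n, d_k)
    K = Xe @ params["w_k"]
    V = Xe @ params["w_v"]
    att = local_attention_windowed(Q, K, V, cfg.window)  # (..., h, n, d_v)
    nd = att.ndim
    axes = tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1)
    att = att.transpose(*axes)  # (..., n, h, d_v)
    att = att.reshape(*att.shape[:-2], cfg.n_heads * cfg.d_v)
    out = att @ params["w_o"]
    if "b_o" in params:
        out = out + params["b_o"]
    return out
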