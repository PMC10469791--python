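"""Attention maths against an independently coded brute-force oracle."""

import numpy as np
import pytest

from lgct.attention import (AttentionConfig, AttentionMask,
                            local_attention_mask, local_attention_windowed,
                            multi_head_attention, positional_encoding,
                            scaled_dot_product_attention,
                            transformer_encoder_layer)
from lgct.autodiff import Tensor


def brute_force_attention(Q, K, V, allowed=None):
    """Row-by-row softmax loop; deliberately no vectorisation."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        logits = np.array([float(Q[i] @ K[j]) / np.sqrt(Q.shape[1])
                           for j in range(m)])
        if allowed is not None:
            logits[~allowed[i]] = -np.inf
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        out[i] = sum(w[j] * V[j] for j in range(m))
    return out


def encoder_params(cfg, rng, scale=0.3):
    h, dm, dk, dv = cfg.n_heads, cfg.d_model, cfg.d_k, cfg.d_v
    p = {
        "w_q": Tensor(scale * rng.normal(size=(h, dm, dk))),
        "w_k": Tensor(scale * rng.normal(size=(h, dm, dk))),
        "w_v": Tensor(scale * rng.normal(size=(h, dm, dv))),
        "w_o": Tensor(scale * rng.normal(size=(h * dv, dm))),
        "b_o": Tensor(np.zeros(dm)),
        "w_ff1": Tensor(scale * rng.normal(size=(dm, 2 * dm))),
        "b_ff1": Tensor(np.zeros(2 * dm)),
        "w_ff2": Tensor(scale * rng.normal(size=(2 * dm, dm))),
        "b_ff2": Tensor(np.zeros(dm)),
    }
    for ln in ("ln1", "ln2"):
        p[f"{ln}_g"] = Tensor(np.ones(dm))
        p[f"{ln}_b"] = Tensor(np.zeros(dm))
    return p


class TestScaledDotProduct:
    def test_single_key_returns_value(self, rng):
        Q = rng.normal(size=(1, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 2))
        assert np.allclose(scaled_dot_product_attention(Q, K, V), V)

    def test_identical_keys_average_values(self, rng):
        K = np.tile(rng.normal(size=(1, 3)), (2, 1))
        V = rng.normal(size=(2, 4))
        out = scaled_dot_product_attention(rng.normal(size=(3, 3)), K, V)
        assert np.allclose(out, V.mean(axis=0, keepdims=True))

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            n, m, dk, dv = rng.integers(1, 17, size=4)
            Q, K = rng.normal(size=(n, dk)), rng.normal(size=(m, dk))
            V = rng.normal(size=(m, dv))
            got = scaled_dot_product_attention(Q, K, V)
            assert np.abs(got - brute_force_attention(Q, K, V)).max() < 1e-6

    def test_masked_positions_get_exactly_zero_weight(self, rng):
        n = 4
        allowed = np.eye(n, dtype=bool)
        allowed[:, 0] = True
        mask = AttentionMask(n, allowed)
        V = np.eye(n)
        out = scaled_dot_product_attention(rng.normal(size=(n, 2)),
                                           rng.normal(size=(n, 2)), V, mask)
        # weights can only land on the diagonal and column 0
        assert np.all(out[:, 1:][~allowed[:, 1:]] == 0.0)

    def test_rows_are_probability_vectors(self, rng):
        n = 8
        V = np.eye(n)  # output rows == attention weight rows
        out = scaled_dot_product_attention(rng.normal(size=(n, 5)),
                                           rng.normal(size=(n, 5)), V,
                                           local_attention_mask(n, 3))
        assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-6
        assert (out >= 0).all() and (out <= 1).all()


class TestLocalMask:
    def test_window3_seq5_enumeration(self):
        mask = local_attention_mask(5, 3)
        assert mask.allowed.sum() == 13
        assert list(mask.allowed.sum(axis=1)) == [2, 3, 3, 3, 2]
        assert np.array_equal(mask.allowed, mask.allowed.T)

    def test_wide_window_equals_global(self):
        mask = local_attention_mask(4, 2 * 4 - 1)
        assert mask.allowed.all()

    def test_window1_identity(self, rng):
        mask = local_attention_mask(5, 1)
        assert np.array_equal(mask.allowed, np.eye(5, dtype=bool))
        V = rng.normal(size=(5, 3))
        out = scaled_dot_product_attention(rng.normal(size=(5, 2)),
                                           rng.normal(size=(5, 2)), V, mask)
        assert np.allclose(out, V)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            local_attention_mask(5, 4)

    def test_all_masked_row_rejected(self):
        allowed = np.ones((3, 3), dtype=bool)
        allowed[1] = False
        with pytest.raises(ValueError):
            AttentionMask(3, allowed)


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(3, 8)
        assert np.allclose(pe[0], [0, 1] * 4)

    def test_position_one_first_dim_is_sin1(self):
        for d in (4, 10, 64):
            assert abs(positional_encoding(2, d)[1, 0] - np.sin(1.0)) < 1e-12

    def test_sin_cos_pairs_on_unit_circle(self):
        pe = positional_encoding(50, 16)
        assert np.allclose(pe[:, 0::2] ** 2 + pe[:, 1::2] ** 2, 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(4, 7)


class TestMultiHead:
    def test_single_head_identity_projections_reduce_to_sdpa(self, rng):
        d = 4
        cfg = AttentionConfig(1, d, d, d, "global", None)
        eye = Tensor(np.eye(d)[None])
        X = rng.normal(size=(6, d))
        params = {"w_q": eye, "w_k": eye, "w_v": eye,
                  "w_o": Tensor(np.eye(d))}
        out = multi_head_attention(X, cfg, params)
        assert np.allclose(out, scaled_dot_product_attention(X, X, X), atol=1e-12)

    def test_two_heads_preserve_model_width(self, rng):
        cfg = AttentionConfig(2, 8, 4, 4, "global", None)
        params = {k: Tensor(rng.normal(size=s)) for k, s in
                  [("w_q", (2, 8, 4)), ("w_k", (2, 8, 4)), ("w_v", (2, 8, 4)),
                   ("w_o", (8, 8))]}
        for n in (1, 5, 9):
            assert multi_head_attention(rng.normal(size=(n, 8)), cfg,
                                        params).shape == (n, 8)

    def test_matches_per_head_loop_oracle(self, rng):
        cfg = AttentionConfig(3, 6, 2, 5, "global", None)
        params = {"w_q": Tensor(rng.normal(size=(3, 6, 2))),
                  "w_k": Tensor(rng.normal(size=(3, 6, 2))),
                  "w_v": Tensor(rng.normal(size=(3, 6, 5))),
                  "w_o": Tensor(rng.normal(size=(15, 6)))}
        X = rng.normal(size=(7, 6))
        heads = []
        for i in range(3):
            Qi = X @ params["w_q"].data[i]
            Ki = X @ params["w_k"].data[i]
            Vi = X @ params["w_v"].data[i]
            heads.append(brute_force_attention(Qi, Ki, Vi))
        want = np.concatenate(heads, axis=1) @ params["w_o"].data
        assert np.abs(multi_head_attention(X, cfg, params) - want).max() < 1e-6

    def test_bad_parameter_shape_rejected(self, rng):
        cfg = AttentionConfig(2, 8, 4, 4, "global", None)
        params = {"w_q": Tensor(np.zeros((2, 8, 3))),
                  "w_k": Tensor(np.zeros((2, 8, 4))),
                  "w_v": Tensor(np.zeros((2, 8, 4))),
                  "w_o": Tensor(np.zeros((8, 8)))}
        with pytest.raises(ValueError, match="w_q"):
            multi_head_attention(rng.normal(size=(3, 8)), cfg, params)


class TestEncoderLayer:
    def test_shape_preserved(self, rng):
        cfg = AttentionConfig(2, 6, 3, 3, "global", None)
        p = encoder_params(cfg, rng)
        X = rng.normal(size=(4, 9, 6))
        assert transformer_encoder_layer(X, cfg, p).shape == X.shape

    def test_local_wide_window_equals_global(self, rng):
        n = 7
        cfg_local = AttentionConfig(2, 6, 3, 3, "local", 2 * n - 1)
        cfg_global = AttentionConfig(2, 6, 3, 3, "global", None)
        p = encoder_params(cfg_local, rng)
        X = rng.normal(size=(n, 6))
        local = transformer_encoder_layer(X, cfg_local, p)
        glob = transformer_encoder_layer(X, cfg_global, p)
        assert np.abs(local - glob).max() < 1e-6

    def test_windowed_equals_banded_mask(self, rng):
        cfg = AttentionConfig(2, 6, 3, 3, "local", 5)
        p = encoder_params(cfg, rng)
        X = rng.normal(size=(3, 12, 6))
        fast = transformer_encoder_layer(X, cfg, p, windowed=True)
        ref = transformer_encoder_layer(X, cfg, p, windowed=False)
        assert np.abs(fast - ref).max() < 1e-6

    def test_zeroed_output_projection_leaves_feedforward_path(self, rng):
        from lgct.autodiff import layer_norm

        cfg = AttentionConfig(2, 6, 3, 3, "global", None)
        p = encoder_params(cfg, rng)
        p["w_o"] = Tensor(np.zeros((6, 6)))
        X = rng.normal(size=(5, 6))
        got = transformer_encoder_layer(X, cfg, p)
        # with zero attention output the layer is LN(x) -> FFN -> LN
        h = layer_norm(Tensor(X), p["ln1_g"], p["ln1_b"])
        ff = (h @ p["w_ff1"] + p["b_ff1"]).elu() @ p["w_ff2"] + p["b_ff2"]
        want = layer_norm(h + ff, p["ln2_g"], p["ln2_b"]).data
        assert np.allclose(got, want, atol=1e-12)

    def test_local_attention_respects_receptive_field(self, rng):
        """Perturbing a sample outside position t's window leaves the
        encoder output at t unchanged."""
        cfg = AttentionConfig(2, 6, 3, 3, "local", 5)
        p = encoder_params(cfg, rng)
        X = rng.normal(size=(20, 6))
        t, far = 10, 16  # |t - far| > (window-1)/2
        base = transformer_encoder_layer(X, cfg, p)
        X2 = X.copy()
        X2[far] += 3.0
        pert = transformer_encoder_layer(X2, cfg, p)
        assert np.allclose(pert[t], base[t], atol=1e-12)
        assert not np.allclose(pert[far], base[far])


def test_windowed_matches_masked_on_random_instances(rng):
    for _ in range(20):
        n = int(rng.integers(2, 17))
        d = int(rng.integers(1, 7))
        window = int(rng.choice([1, 3, 5, 7, 9]))
        Q, K = rng.normal(size=(2, n, d)), rng.normal(size=(2, n, d))
        V = rng.normal(size=(2, n, d))
        got = local_attention_windowed(Q, K, V, window)
        mask = local_attention_mask(n, window)
        want = scaled_dot_product_attention(Q, K, V, mask)
        assert np.abs(got - want).max() < 1e-6
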