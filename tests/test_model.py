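"""Architecture contracts: shapes, fusion, hemisphere paths, dense
connectivity, ablation variants, parameter counts, checkpoints."""

import numpy as np
import pytest

from lgct.autodiff import Tensor
from lgct.data import Montage
from lgct.model import (ConfigError, ModelConfig, build_model,
                        count_parameters, load_checkpoint,
                        make_ablation_variant, save_checkpoint, small_config)

MONT6 = Montage.from_labels(["FC3", "FC4", "C3", "C4", "CP3", "CP4"])


def cfg6(n_classes=2, **over):
    base = small_config(6, 120, n_classes, seed=5)
    base.pool_len = 30
    base.pool_stride = 10
    for k, v in over.items():
        setattr(base, k, v)
    return base


@pytest.fixture(scope="module")
def model6():
    return build_model(cfg6(), MONT6)


def bands_for(cfg, n=3, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.normal(size=(n, cfg.n_channels, cfg.n_samples))
            for _ in range(cfg.n_bands)]


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_classes", 1),
        ("temporal_kernel", 12),
        ("pool_len", 10_000),
        ("token_embed_dim", 6),
        ("tdense_layers", 1),
        ("activation", "swish"),
        ("dropout_rate", 1.5),
        ("dtype", "float16"),
    ])
    def test_bad_field_named_in_error(self, field, value):
        cfg = cfg6()
        setattr(cfg, field, value)
        with pytest.raises(ConfigError, match=field):
            build_model(cfg, MONT6)

    def test_montage_channel_mismatch(self):
        with pytest.raises(ConfigError, match="n_channels"):
            build_model(cfg6(), Montage.from_labels(["C3", "C4"]))


class TestForward:
    @pytest.mark.parametrize("n_classes", [2, 4])
    def test_softmax_output_contract(self, n_classes):
        cfg = cfg6(n_classes)
        model = build_model(cfg, MONT6)
        out = model.forward(bands_for(cfg, n=4)).data
        assert out.shape == (4, n_classes)
        assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-6
        assert (out >= 0).all()

    def test_same_seed_same_parameters_and_outputs(self):
        cfg = cfg6()
        a = build_model(cfg6(), MONT6)
        b = build_model(cfg6(), MONT6)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data), k
        x = bands_for(cfg)
        assert np.array_equal(a.forward(x).data, b.forward(x).data)

    def test_eval_mode_is_deterministic_bitwise(self, model6):
        x = bands_for(model6.cfg)
        out1 = model6.forward(x, training=False).data
        out2 = model6.forward(x, training=False).data
        assert np.array_equal(out1, out2)

    def test_branches_are_independent(self):
        cfg = cfg6()
        model = build_model(cfg, MONT6)
        x = bands_for(cfg)
        before = model._branch(1, Tensor(x[1].astype(np.float32)), False).data
        for name, t in model.params.items():
            if name.startswith("b0/"):
                t.data = t.data + 1.0  # perturb band-0 branch only
        after = model._branch(1, Tensor(x[1].astype(np.float32)), False).data
        assert np.array_equal(before, after)

    def test_every_parameter_gets_gradient(self):
        cfg = cfg6()
        model = build_model(cfg, MONT6)
        out = model.forward(bands_for(cfg, n=4), training=True)
        y = np.eye(2, dtype=np.float32)[[0, 1, 0, 1]]
        loss = -((out + 1e-12).log() * Tensor(y)).sum()
        loss.backward()
        dead = [k for k, t in model.params.items()
                if t.grad is None or not np.any(t.grad)]
        assert dead == []


class TestTemporalBlock:
    def test_pooled_length_formula(self, model6):
        cfg = model6.cfg
        x = Tensor(np.random.default_rng(0).normal(
            size=(2, cfg.n_channels, cfg.n_samples)).astype(np.float32))
        out = model6._temporal_block(0, x, False)
        want_t = (cfg.n_samples - cfg.pool_len) // cfg.pool_stride + 1
        assert out.shape == (2, cfg.temporal_filters, cfg.n_channels, want_t)

    def test_zeroed_projection_reduces_to_cnn_path(self):
        cfg = cfg6()
        full = build_model(cfg, MONT6)
        for b in range(3):
            full.params[f"b{b}/temporal/proj_w"].data[:] = 0.0
            full.params[f"b{b}/temporal/proj_b"].data[:] = 0.0
        wo = build_model(cfg6(), MONT6, variant="wo_trans")
        for b in range(3):  # matched conv weights
            for suffix in ("conv_w", "conv_b", "bn_g", "bn_b"):
                wo.params[f"b{b}/temporal/{suffix}"].data = \
                    full.params[f"b{b}/temporal/{suffix}"].data.copy()
        x = Tensor(np.random.default_rng(3).normal(
            size=(2, 6, cfg.n_samples)).astype(np.float32))
        got = full._temporal_block(0, x, False).data
        want = wo._temporal_block(0, x, False).data
        assert np.allclose(got, want, atol=1e-6)

    def test_receptive_fields_of_both_paths_agree(self, model6):
        """A perturbation farther than (kernel-1)/2 from position t leaves
        the pre-pooling temporal features at t unchanged."""
        cfg = model6.cfg
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6, cfg.n_samples)).astype(np.float32)
        base = model6._temporal_block(0, Tensor(x), False, pool=False).data
        t, far = 60, 90  # |t - far| = 30 > (13-1)/2
        x2 = x.copy()
        x2[:, :, far] += 5.0
        pert = model6._temporal_block(0, Tensor(x2), False, pool=False).data
        assert np.allclose(pert[..., t], base[..., t], atol=1e-5)
        assert not np.allclose(pert[..., far], base[..., far])


class TestSpatialBlock:
    def test_hemisphere_difference_is_antisymmetric(self):
        cfg = cfg6()
        model = build_model(cfg, MONT6)
        for b in range(3):
            model.params[f"b{b}/spatial/w_right"].data = \
                model.params[f"b{b}/spatial/w_left"].data.copy()
            model.params[f"b{b}/spatial/b_right"].data = \
                model.params[f"b{b}/spatial/b_left"].data.copy()
        rng = np.random.default_rng(0)
        h = rng.normal(size=(2, cfg.temporal_filters, 6, cfg.pooled_len))
        # right channels exactly mirror left channels
        h[:, :, list(MONT6.right_idx), :] = h[:, :, list(MONT6.left_idx), :]
        feat = model._spatial_block(0, Tensor(h.astype(np.float32)), False).data
        n_all = cfg.temporal_filters * cfg.spatial_filters
        diff_part = feat[:, n_all:, :]
        # after BN+ELU a zero pre-activation maps to a constant per feature
        assert np.allclose(diff_part.std(axis=(0, 2)), 0.0, atol=1e-6)

    def test_ku_montage_hemisphere_path_sizes(self, ku_montage):
        cfg = small_config(20, 120, 2, seed=0)
        cfg.pool_len, cfg.pool_stride = 30, 10
        model = build_model(cfg, ku_montage)
        assert model.params["b0/spatial/w_left"].shape == (4, 9)
        assert model.params["b0/spatial/w_right"].shape == (4, 9)
        assert len(ku_montage.midline_idx) == 2  # Cz, CPz excluded

    def test_wo_diff_hemi_uses_all_channel_path_only(self):
        cfg = cfg6()
        model = build_model(cfg, MONT6, variant="wo_diff_hemi")
        assert not any("w_left" in k or "w_right" in k for k in model.params)
        rng = np.random.default_rng(0)
        h = Tensor(rng.normal(size=(2, cfg.temporal_filters, 6,
                                    cfg.pooled_len)).astype(np.float32))
        feat = model._spatial_block(0, h, False)
        assert feat.shape[1] == cfg.temporal_filters * cfg.spatial_filters


class TestTDense:
    def test_dense_layer_input_widths(self, model6):
        cfg = model6.cfg
        d0 = model6._spatial_width()
        g, kt = cfg.tdense_growth, cfg.tdense_kernel
        for i in range(cfg.tdense_layers):
            w = model6.params[f"b0/tdense/cnn{i}/w"]
            assert w.shape == (g, d0 + i * g, kt)

    def test_reduce_conv_sets_feature_count(self, model6):
        cfg = model6.cfg
        d0 = model6._spatial_width()
        rng = np.random.default_rng(0)
        feat = Tensor(rng.normal(size=(2, d0, cfg.pooled_len)).astype(np.float32))
        out = model6._tdense_block(0, feat, False)
        assert out.shape == (2, cfg.reduce_filters, cfg.pooled_len)

    def test_wo_tdense_differs_from_full(self):
        cfg = cfg6()
        full = build_model(cfg, MONT6)
        plain = build_model(cfg6(), MONT6, variant="wo_tdense")
        x = bands_for(cfg)
        assert not np.allclose(full.forward(x).data, plain.forward(x).data)


class TestVariants:
    def test_parameter_counts_strictly_decrease(self):
        counts = {v: count_parameters(make_ablation_variant(cfg6(), v, MONT6))
                  for v in ("full", "w/o_trans", "w/o_Diff-hemi")}
        assert counts["w/o_trans"] < counts["full"]
        assert counts["w/o_Diff-hemi"] < counts["full"]

    def test_wo_trans_never_calls_attention(self):
        cfg = cfg6()
        model = make_ablation_variant(cfg, "w/o_trans", MONT6)
        model.forward(bands_for(cfg), training=True)
        assert model.attention_calls == 0

    def test_full_model_does_call_attention(self, model6):
        calls_before = model6.attention_calls
        model6.forward(bands_for(model6.cfg))
        assert model6.attention_calls > calls_before

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_ablation_variant(cfg6(), "w/o_everything", MONT6)


class TestParameterCount:
    def test_head_layer_closed_form(self, model6):
        cfg = model6.cfg
        d_in = 3 * cfg.reduce_filters * cfg.pooled_len
        got = model6.params["head/w"].size + model6.params["head/b"].size
        assert got == d_in * cfg.n_classes + cfg.n_classes

    def test_temporal_conv_closed_form(self, model6):
        cfg = model6.cfg
        got = model6.params["b0/temporal/conv_w"].size \
            + model6.params["b0/temporal/conv_b"].size
        assert got == cfg.temporal_filters * cfg.temporal_kernel \
            + cfg.temporal_filters

    def test_total_matches_manual_sum(self, model6):
        manual = sum(int(np.prod(t.shape)) for t in model6.params.values())
        assert count_parameters(model6) == manual
        # batch-norm running stats are not trainable parameters
        n_buffers = sum(b["mean"].size + b["var"].size
                        for b in model6.buffers.values())
        assert n_buffers > 0
        assert count_parameters(model6) == manual  # unchanged by buffers


def test_checkpoint_roundtrip_bitexact(tmp_path, model6):
    x = bands_for(model6.cfg)
    want = model6.forward(x).data
    save_checkpoint(model6, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt")
    assert loaded.variant == model6.variant
    got = loaded.forward(x).data
    assert np.array_equal(got, want)
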