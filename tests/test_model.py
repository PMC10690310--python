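"""Architecture contracts: shapes, tiling equivalence, tokens, checkpoints."""

import numpy as np
import pytest

from slivit import (BackboneConfig, IntegratorConfig, SlivitConfig, SlivitModel,
                    Volume, build_backbone, build_pretrain_model, compact_config,
                    compact_integrator_config, convnext_tiny_config,
                    extract_feature_maps, forward_volume, integrate_and_predict,
                    load_checkpoint, save_checkpoint, stem_only_config,
                    tile_volume, tokenize_and_embed)
from slivit import nn
from slivit.preprocess import ElongatedImage


def _compact_model(max_n=16, head="binary", seed=0):
    cfg = SlivitConfig(backbone=compact_config(),
                       integrator=compact_integrator_config(max_n=max_n),
                       head=head)
    return SlivitModel(cfg, seed=seed)


class TestBackboneConfig:
    def test_tiny_variant_geometry(self):
        cfg = convnext_tiny_config()
        assert cfg.downsample_factor == 32
        assert cfg.feature_side == 8
        assert cfg.feature_dim == 768
        assert cfg.stage_depths == (3, 3, 9, 3)
        assert cfg.stage_widths == (96, 192, 384, 768)

    def test_compact_preset_keeps_8x8_grid(self):
        cfg = compact_config()
        assert cfg.feature_side == 8

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(input_side=100)

    def test_integrator_head_divisibility(self):
        with pytest.raises(ValueError):
            IntegratorConfig(token_dim=65, heads=4)


class TestBackboneShapes:
    def test_single_slice_full_tiny(self):
        bb = build_backbone(convnext_tiny_config(), seed=0)
        x = np.random.default_rng(0).standard_normal((1, 256, 256, 3)).astype("f4")
        with nn.no_grad():
            out = bb(nn.Tensor(x))
        assert out.shape == (1, 8, 8, 768)

    def test_tall_tiled_input_49_slices(self):
        # stem-only variant (same stem/transition geometry, full widths)
        bb = build_backbone(stem_only_config(), seed=0)
        x = np.random.default_rng(1).standard_normal((1, 12544, 256, 3)).astype("f4")
        with nn.no_grad():
            out = bb(nn.Tensor(x))
        assert out.shape == (1, 392, 8, 768)  # 392 = 49 * 8

    def test_eval_determinism(self):
        bb = build_backbone(compact_config(), seed=0)
        x = np.random.default_rng(2).standard_normal((2, 64, 64, 3)).astype("f4")
        with nn.no_grad():
            a = bb(nn.Tensor(x)).data
            b = bb(nn.Tensor(x)).data
        np.testing.assert_array_equal(a, b)

    def test_transferred_init_round_trip(self):
        cfg = compact_config()
        src = build_backbone(cfg, seed=3)
        dst = build_backbone(cfg, init="transferred", weights=src.state_dict(),
                             seed=99)
        x = np.random.default_rng(3).standard_normal((1, 64, 64, 3)).astype("f4")
        with nn.no_grad():
            np.testing.assert_array_equal(src(nn.Tensor(x)).data,
                                          dst(nn.Tensor(x)).data)

    def test_transferred_shape_mismatch(self):
        src = build_backbone(compact_config(), seed=0)
        bad = {k: v[..., :-1] if v.ndim else v for k, v in src.state_dict().items()}
        with pytest.raises(ValueError):
            build_backbone(compact_config(), init="transferred", weights=bad)


class TestExtractFeatureMaps:
    def test_split_arithmetic(self):
        bb = build_backbone(compact_config(), seed=0)
        pixels = np.random.default_rng(0).standard_normal((4 * 64, 64, 3)).astype("f4")
        stack = extract_feature_maps(bb, ElongatedImage(pixels, 4))
        assert stack.shape == (4, 8, 8, 24)

    def test_single_slice_equals_direct_forward(self):
        bb = build_backbone(compact_config(), seed=0)
        pixels = np.random.default_rng(1).standard_normal((64, 64, 3)).astype("f4")
        stack = extract_feature_maps(bb, ElongatedImage(pixels, 1))
        with nn.no_grad():
            direct = bb(nn.Tensor(pixels[None])).data[0]
        np.testing.assert_array_equal(stack[0], direct)

    def test_height_contract(self):
        bb = build_backbone(compact_config(), seed=0)
        with pytest.raises(ValueError):
            extract_feature_maps(bb, ElongatedImage(np.zeros((100, 64, 3), "f4"), 2))

    def test_stem_only_tiled_equals_per_slice(self):
        # with every spatial kernel equal to its stride, receptive fields
        # cannot cross tile boundaries: block i of the tiled forward must
        # equal the forward of slice i alone
        bb = build_backbone(stem_only_config(compact_config()), seed=5)
        rng = np.random.default_rng(6)
        slices = rng.standard_normal((5, 64, 64, 3)).astype("f4")
        tiled = extract_feature_maps(bb, ElongatedImage(slices.reshape(-1, 64, 3), 5))
        for i in range(5):
            solo = extract_feature_maps(bb, ElongatedImage(slices[i], 1))[0]
            assert np.abs(tiled[i] - solo).max() < 1e-5

    def test_zeroing_slice_only_changes_its_map(self):
        bb = build_backbone(stem_only_config(compact_config()), seed=5)
        rng = np.random.default_rng(7)
        slices = rng.standard_normal((4, 64, 64, 3)).astype("f4")
        base = extract_feature_maps(bb, ElongatedImage(slices.reshape(-1, 64, 3), 4))
        mod = slices.copy()
        mod[2] = 0.0
        changed = extract_feature_maps(bb, ElongatedImage(mod.reshape(-1, 64, 3), 4))
        assert np.abs(changed[2] - base[2]).max() > 1e-3
        for i in (0, 1, 3):
            np.testing.assert_allclose(changed[i], base[i], atol=1e-6)


class TestTokenization:
    def test_sequence_lengths(self):
        model = _compact_model(max_n=64)
        for n in (1, 49):
            stack = np.zeros((n, 8, 8, 24), dtype=np.float32)
            tokens = tokenize_and_embed(model, stack)
            assert tokens.shape == (n + 1, 32)

    def test_positional_initialization_shows_through(self):
        # zero the shared tokenizer and feed zero maps: token i must be the
        # vector filled with its 0-based slice index
        model = _compact_model(max_n=16)
        model.tokenizer.weight.data[:] = 0.0
        model.tokenizer.bias.data[:] = 0.0
        tokens = tokenize_and_embed(model, np.zeros((5, 8, 8, 24), "f4"))
        for i in range(5):
            np.testing.assert_allclose(tokens[i + 1], float(i), atol=1e-6)

    def test_shared_affine_tokenizer(self):
        # two identical maps at different positions differ only by position
        model = _compact_model(max_n=16)
        stack = np.repeat(np.random.default_rng(0)
                          .standard_normal((1, 8, 8, 24)).astype("f4"), 3, axis=0)
        tokens = tokenize_and_embed(model, stack)
        np.testing.assert_allclose(tokens[2] - tokens[1], 1.0, atol=1e-5)

    def test_max_n_enforced(self):
        model = _compact_model(max_n=4)
        with pytest.raises(ValueError):
            tokenize_and_embed(model, np.zeros((5, 8, 8, 24), "f4"))


class TestIntegration:
    def test_binary_head_scalar_logit(self):
        model = _compact_model()
        tokens = np.random.default_rng(0).standard_normal((9, 32)).astype("f4")
        out = integrate_and_predict(model, tokens)
        assert out.shape == (1,) and np.isfinite(out).all()

    def test_multiclass_head_four_logits(self):
        model = _compact_model(head="multiclass_4")
        tokens = np.random.default_rng(1).standard_normal((9, 32)).astype("f4")
        assert integrate_and_predict(model, tokens).shape == (4,)

    def test_permutation_equivariance_with_equal_positions(self):
        model = _compact_model(max_n=16)
        rng = np.random.default_rng(2)
        tokens = rng.standard_normal((9, 32)).astype("f4")
        perm = np.concatenate([[0], 1 + rng.permutation(8)])
        out_a = integrate_and_predict(model, tokens)
        out_b = integrate_and_predict(model, tokens[perm])
        assert np.abs(out_a - out_b).max() < 1e-5

    def test_token_dim_mismatch(self):
        model = _compact_model()
        with pytest.raises(ValueError):
            integrate_and_predict(model, np.zeros((5, 16), "f4"))

    def test_depth_is_five(self):
        model = _compact_model()
        assert len(model.blocks) == 5


class TestForwardVolume:
    @pytest.mark.parametrize("n", [4, 32, 49])
    def test_variable_n_scalar_output(self, n):
        model = _compact_model(max_n=64)
        vol = Volume("v", np.random.default_rng(n).random((n, 20, 24)))
        out = forward_volume(model, vol, stretch=False)
        assert out.shape == (1,) and np.isfinite(out).all()

    def test_duplicate_volumes_identical_predictions(self):
        model = _compact_model(max_n=8)
        x = np.random.default_rng(0).standard_normal((1, 8 * 64, 64, 3)).astype("f4")
        batch = np.concatenate([x, x, x, x])
        with nn.no_grad():
            out = model(batch).data
        assert np.all(out == out[0])

    def test_end_to_end_gradient_reaches_stem(self):
        model = _compact_model(max_n=4)
        x = np.random.default_rng(1).standard_normal((2, 4 * 64, 64, 3)).astype("f4")
        loss = nn.bce_with_logits(model(x).reshape(2), np.array([0.0, 1.0]))
        loss.backward()
        stem_grad = model.backbone.stem.proj.weight.grad
        assert stem_grad is not None and np.abs(stem_grad).max() > 0


class TestPretrainModel:
    def test_four_logits_and_pool_width(self):
        bb = build_backbone(compact_config(), seed=0)
        clf = build_pretrain_model(bb, n_classes=4)
        x = np.random.default_rng(0).standard_normal((2, 64, 64, 3)).astype("f4")
        with nn.no_grad():
            out = clf(x)
            pooled = clf.backbone(nn.Tensor(x)).mean(axis=1).mean(axis=1)
        assert out.shape == (2, 4)
        assert pooled.shape == (2, bb.config.feature_dim)

    def test_full_config_pools_768_features(self):
        bb = build_backbone(convnext_tiny_config(), seed=0)
        clf = build_pretrain_model(bb)
        x = np.random.default_rng(1).standard_normal((1, 256, 256, 3)).astype("f4")
        with nn.no_grad():
            out = clf(x)
        assert out.shape == (1, 4)
        assert bb.config.feature_dim == 768


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, tmp_path):
        model = _compact_model(max_n=8, seed=4)
        cfg = model.config
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, cfg, extra={"note": "test"})
        state, manifest = load_checkpoint(path)
        assert manifest["config"]["integrator"]["depth"] == 5
        fresh = SlivitModel(SlivitConfig.from_dict(manifest["config"]), seed=99)
        fresh.load_state_dict(state)
        x = np.random.default_rng(5).standard_normal((1, 8 * 64, 64, 3)).astype("f4")
        with nn.no_grad():
            np.testing.assert_array_equal(model(x).data, fresh(x).data)

    def test_backbone_group_loads_standalone(self, tmp_path):
        from slivit import backbone_state

        model = _compact_model(seed=6)
        save_checkpoint(model, tmp_path / "m.npz", model.config)
        state, _ = load_checkpoint(tmp_path / "m.npz")
        bb = build_backbone(compact_config(), init="transferred",
                            weights=backbone_state(state))
        x = np.random.default_rng(6).standard_normal((1, 64, 64, 3)).astype("f4")
        with nn.no_grad():
            np.testing.assert_array_equal(
                bb(nn.Tensor(x)).data,
                model.backbone(nn.Tensor(x)).data)
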