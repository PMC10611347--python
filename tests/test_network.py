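"""Full-model assembly: shape contracts, lattice combinatorics, ablation
equivalence against an independently wired plain UNet, and gradient flow."""

import numpy as np
import pytest

from tla_unet import ModelConfig, TrainConfig, TransformerConfig, build_model, \
    desk_scale_config
from tla_unet.autograd import Tensor, concat
from tla_unet.losses import deep_supervision_loss, one_hot
from tla_unet.nn import make_optimizer


DESK_TF = TransformerConfig(patch_size=4, hidden_size=64, n_layers=2,
                            mlp_size=128, n_heads=4)


def small_cfg(**overrides):
    base = dict(n_classes=3, input_size=32, depth=2, base_width=8,
                transformer=TransformerConfig(patch_size=4, hidden_size=16,
                                              n_layers=1, mlp_size=32,
                                              n_heads=2))
    base.update(overrides)
    return ModelConfig(**base)


class TestConfigValidation:
    def test_reference_configuration_is_accepted(self):
        cfg = ModelConfig()     # 224 input, depth 4, patch 16
        assert cfg.n_tokens == 196
        assert cfg.bottleneck_hw == (14, 14)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            ModelConfig(n_classes=1)

    def test_input_not_divisible_by_depth_rejected(self):
        with pytest.raises(ValueError, match="2\\^depth"):
            ModelConfig(input_size=100, depth=4)

    def test_patch_must_cover_bottleneck_stride(self):
        with pytest.raises(ValueError, match="patch"):
            ModelConfig(input_size=224, depth=4,
                        transformer=TransformerConfig(patch_size=8))

    def test_larger_transformer_scale_has_more_parameters(self):
        small = build_model(small_cfg())
        bigger = build_model(small_cfg(
            transformer=TransformerConfig(patch_size=4, hidden_size=32,
                                          n_layers=2, mlp_size=64, n_heads=2)))
        assert bigger.n_parameters() > small.n_parameters()


class TestEncoder:
    def test_skip_and_bottleneck_geometry(self, rng):
        model = build_model(desk_scale_config())
        model.eval()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        skips, bottleneck = model.encoder(x)
        assert [s.shape for s in skips] == [(1, 16, 64, 64), (1, 32, 32, 32)]
        assert bottleneck.shape == (1, 32, 16, 16)

    def test_se_switch_off_gives_raw_stage_outputs(self, rng):
        cfg = small_cfg(use_se=False)
        model = build_model(cfg)
        assert model.encoder.se is None

    def test_zero_image_gives_finite_outputs(self):
        model = build_model(small_cfg())
        model.eval()
        out = model(np.zeros((1, 1, 32, 32)))
        assert np.isfinite(out.main_logits.data).all()


class TestDecoder:
    def test_lattice_node_count_and_side_output_count(self):
        cfg = ModelConfig(n_classes=3, input_size=64, depth=4, base_width=4,
                          transformer=TransformerConfig(patch_size=16,
                                                        hidden_size=16,
                                                        n_layers=1,
                                                        mlp_size=32,
                                                        n_heads=2))
        model = build_model(cfg)
        assert len(model.nodes) == 4 + 3 + 2 + 1
        model.eval()
        out = model(np.zeros((1, 1, 64, 64)))
        assert len(out.side_logits) == 4
        assert len(out.aux_node_logits) == 3
        for s in out.side_logits:
            assert s.shape == (1, 3, 64, 64)

    def test_every_head_matches_input_resolution(self, rng):
        model = build_model(desk_scale_config())
        model.eval()
        out = model(rng.normal(size=(2, 1, 64, 64)))
        for logits in out.all_outputs():
            assert logits.shape == (2, 4, 64, 64)


class TestModelForward:
    def test_softmax_is_normalized_per_pixel(self, rng):
        model = build_model(desk_scale_config())
        model.eval()
        probs = model(rng.normal(size=(1, 1, 64, 64))).probabilities()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, rng):
        model = build_model(desk_scale_config())
        model.eval()
        x = rng.normal(size=(1, 1, 64, 64))
        out1 = model(x).main_logits.data
        out2 = model(x).main_logits.data
        np.testing.assert_array_equal(out1, out2)

    def test_wrong_input_size_rejected(self, rng):
        model = build_model(desk_scale_config())
        with pytest.raises(ValueError, match="expected"):
            model(rng.normal(size=(1, 1, 32, 32)))

    def test_builds_are_reproducible_from_seed(self, rng):
        m1 = build_model(desk_scale_config())
        m2 = build_model(desk_scale_config())
        x = rng.normal(size=(1, 1, 64, 64))
        m1.eval(), m2.eval()
        np.testing.assert_array_equal(m1(x).main_logits.data,
                                      m2(x).main_logits.data)


class TestAblationEquivalence:
    def test_all_switches_off_equals_independent_plain_unet_wiring(self, rng):
        """With UNet++/TLA/side/SE off, the forward pass must equal a plain
        UNet assembled by hand from the model's own stages."""
        cfg = small_cfg(use_unetpp=False, use_tla=False,
                        use_side_outputs=False, use_se=False)
        model = build_model(cfg)
        model.eval()
        image = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        out = model(image)
        assert out.side_logits == [] and out.aux_node_logits == []

        # independent wiring: encoder -> transformer grid -> bottom-up
        # concat/double-conv decoder -> 1x1 head
        x = Tensor(image)
        skips, bottleneck = model.encoder(x)
        tokens = model.patch_embed(bottleneck)
        tokens, _ = model.transformer(tokens)
        feat = model.tokens_to_grid(tokens, model.patch_embed.grid_shape)
        for level in range(cfg.depth - 1, -1, -1):
            skip = skips[level]
            up = feat.bilinear_resize(skip.shape[-2:])
            feat = model.nodes[(level, 1)](concat([skip, up], axis=1))
        expected = model.main_head(feat).data
        np.testing.assert_array_equal(out.main_logits.data, expected)

    def test_switches_change_the_forward_pass(self, rng):
        """Each enabled component must actually participate: toggling any
        switch changes the architecture (parameter sets differ)."""
        full = build_model(small_cfg())
        for flag in ("use_unetpp", "use_side_outputs", "use_tla", "use_se"):
            ablated = build_model(small_cfg(**{flag: False}))
            assert len(ablated.parameters()) < len(full.parameters()), flag


class TestGradientFlow:
    def test_one_step_reaches_every_parameter_group(self, rng):
        cfg = small_cfg(se_reduction=2, attention_reduction=2)
        model = build_model(cfg)
        model.train()
        images = rng.normal(size=(4, 1, 32, 32)).astype(np.float32)
        targets = one_hot(rng.integers(0, 3, size=(4, 32, 32)), 3).astype(np.float32)
        loss = deep_supervision_loss(model(images), Tensor(targets))
        loss.backward()
        missing = [name for name, p in model.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert missing == []
        opt = make_optimizer("sgd", model.parameters(), TrainConfig())
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        opt.step()
        changed = [n for n, p in model.named_parameters()
                   if not np.array_equal(before[n], p.data)]
        assert len(changed) == len(before)
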