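"""Architecture contracts: shapes, bounds, parameter counts, the
skip-connection ablation equivalence and the pointwise baseline's
time-equivariance."""

import numpy as np
import pytest

from leadconv.models import (
    ConfigError,
    ModelConfig,
    OneToAllModel,
    assemble_one_to_all,
    build_bottleneck,
    build_decoder,
    build_encoder,
    build_model,
    build_pointwise_baseline,
    describe,
    load_checkpoint,
    save_checkpoint,
)


def tiny_config(**kw):
    base = dict(family="unet", reference_lead="II", target_leads=("I", "III"),
                encoder_scheme="shared", depth=2, base_channels=2,
                kernel_size=5, input_length=32)
    base.update(kw)
    return ModelConfig(**base)


class TestModelConfig:
    def test_reference_cannot_be_target(self):
        with pytest.raises(ConfigError):
            tiny_config(target_leads=("II", "I"))

    def test_default_targets_are_the_other_eleven(self):
        cfg = ModelConfig(reference_lead="II", input_length=32, depth=2)
        assert len(cfg.target_leads) == 11
        assert "II" not in cfg.target_leads

    def test_kernel_must_be_odd(self):
        with pytest.raises(ConfigError):
            tiny_config(kernel_size=8)

    def test_padded_length(self):
        assert tiny_config(depth=3, input_length=625).padded_length == 632
        # 5000 = 8 * 625: the full-rate 5 s window needs no padding at depth 3
        assert ModelConfig(depth=3, input_length=5000).padded_length == 5000
        assert tiny_config(input_length=32).padded_length == 32


class TestEncoder:
    def test_indivisible_length_is_config_error(self):
        with pytest.raises(ConfigError, match="divisible"):
            build_encoder(ModelConfig(depth=3, input_length=625))

    def test_feature_lengths_halve_per_block(self, rng):
        cfg = tiny_config(depth=3, input_length=4096, base_channels=2)
        enc = build_encoder(cfg, rng)
        z, skips = enc.forward(rng.standard_normal((1, 2, 4096)), train=False)
        assert [s.shape[2] for s in skips] == [4096, 2048, 1024]
        assert z.shape == (8, 2, 512)

    def test_single_block_encoder(self, rng):
        cfg = tiny_config(depth=1, base_channels=16, input_length=32)
        enc = build_encoder(cfg, rng)
        z, skips = enc.forward(rng.standard_normal((1, 2, 32)), train=False)
        assert len(skips) == 1 and z.shape[0] == 16


class TestBottleneck:
    def test_length_preserved_and_channels_doubled(self, rng):
        cfg = tiny_config(depth=2, base_channels=4)
        bott = build_bottleneck(cfg, rng)
        x = rng.standard_normal((8, 3, 8))  # 4 * 2**(2-1) = 8 channels in
        y = bott.forward(x, train=False)
        assert y.shape == (16, 3, 8)
        assert np.all(np.isfinite(y))


class TestDecoder:
    def test_output_length_matches_input_and_tanh_bound(self, rng):
        cfg = tiny_config(depth=2, base_channels=2, input_length=32)
        dec = build_decoder(cfg, with_skips=False, with_aux_heads=False, rng=rng)
        z = rng.standard_normal((8, 3, 8))
        y, aux = dec.forward(z, skips=None, train=False)
        assert y.shape == (3, 32)
        assert np.max(np.abs(y)) < 1.0
        assert aux == []

    def test_aux_heads_emit_per_block_resolutions(self, rng):
        cfg = tiny_config(depth=3, base_channels=2, input_length=64,
                          family="lrn")
        dec = build_decoder(cfg, with_skips=False, with_aux_heads=True, rng=rng)
        z = rng.standard_normal((16, 2, 8))
        y, aux = dec.forward(z, skips=None, train=False)
        assert [a.shape[2] for a in aux] == [16, 32, 64]
        assert y.shape == (2, 64)


class TestOneToAllAssembly:
    def test_shared_has_fewer_parameters_than_individual(self):
        shared = assemble_one_to_all(tiny_config(encoder_scheme="shared"))
        indiv = assemble_one_to_all(tiny_config(encoder_scheme="individual"))
        assert shared.n_parameters < indiv.n_parameters

    def test_unet_has_more_parameters_than_ae(self):
        unet = assemble_one_to_all(tiny_config(family="unet"))
        ae = assemble_one_to_all(tiny_config(family="ae"))
        assert unet.n_parameters > ae.n_parameters

    def test_pointwise_not_assemblable(self):
        with pytest.raises(ConfigError):
            OneToAllModel(tiny_config(family="pointwise"))

    def test_individual_pairs_are_independent(self, rng):
        model = assemble_one_to_all(tiny_config(encoder_scheme="individual"),
                                    seed=0)
        x = rng.uniform(-1, 1, (2, 32))
        before, _ = model.forward(x)
        for p in (model.encoders["I"].params()
                  + model.bottlenecks["I"].params()
                  + model.decoders["I"].params()):
            p.data[...] = 0.0
        after, _ = model.forward(x)
        np.testing.assert_array_equal(before["III"], after["III"])
        assert not np.array_equal(before["I"], after["I"])

    def test_forward_contract(self, rng):
        model = assemble_one_to_all(tiny_config(), seed=0)
        x = rng.uniform(-1, 1, (4, 32))
        preds, aux = model.forward(x)
        assert set(preds) == {"I", "III"}
        for y in preds.values():
            assert y.shape == (4, 32)
            assert np.max(np.abs(y)) < 1.0
        again, _ = model.forward(x)
        for lead in preds:
            np.testing.assert_array_equal(preds[lead], again[lead])

    def test_wrong_length_rejected(self, rng):
        model = assemble_one_to_all(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(rng.uniform(-1, 1, (2, 31)))

    def test_lrn_aux_outputs_per_target(self, rng):
        model = assemble_one_to_all(tiny_config(family="lrn", depth=3,
                                                input_length=64), seed=0)
        preds, aux = model.forward(rng.uniform(-1, 1, (2, 64)))
        for lead in ("I", "III"):
            assert len(aux[lead]) == 3

    def test_padding_round_trip_for_indivisible_length(self, rng):
        model = assemble_one_to_all(tiny_config(depth=3, input_length=625),
                                    seed=0)
        preds, _ = model.forward(rng.uniform(-1, 1, (2, 625)))
        assert preds["I"].shape == (2, 625)


def test_skip_ablation_unet_equals_ae(rng):
    """With the skip-connection input channels zeroed and all remaining
    parameters copied, the U-Net computes exactly the autoencoder's map."""
    cfg_u = tiny_config(family="unet")
    cfg_a = tiny_config(family="ae")
    unet = assemble_one_to_all(cfg_u, seed=0)
    ae = assemble_one_to_all(cfg_a, seed=0)
    ae_params = ae.params()
    unet_params = unet.params()
    assert len(ae_params) == len(unet_params)
    k = cfg_u.kernel_size
    for pa, pu in zip(ae_params, unet_params):
        if pa.data.shape == pu.data.shape:
            pu.data[...] = pa.data
        else:
            # first decoder-block convolution: zero the skip columns
            n_keep = pa.data.shape[1]
            pu.data[...] = 0.0
            pu.data[:, :n_keep] = pa.data
    x = rng.uniform(-1, 1, (3, 32))
    yu, _ = unet.forward(x)
    ya, _ = ae.forward(x)
    for lead in yu:
        np.testing.assert_allclose(yu[lead], ya[lead], atol=1e-6)


class TestPointwiseBaseline:
    def test_constant_input_gives_constant_output(self):
        model = build_pointwise_baseline(tiny_config(family="pointwise"),
                                         seed=0)
        x = np.full((2, 32), 0.3)
        preds, _ = model.forward(x)
        for y in preds.values():
            assert np.ptp(y) == 0.0

    def test_time_permutation_equivariance(self, rng):
        model = build_pointwise_baseline(tiny_config(family="pointwise"),
                                         seed=0)
        x = rng.uniform(-1, 1, (1, 32))
        perm = rng.permutation(32)
        y, _ = model.forward(x)
        y_perm, _ = model.forward(x[:, perm])
        for lead in y:
            np.testing.assert_allclose(y_perm[lead], y[lead][:, perm],
                                       atol=1e-6)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigError):
            build_pointwise_baseline(tiny_config(family="pointwise"),
                                     hidden_width=0)


def test_checkpoint_round_trip(tmp_path, rng):
    for family in ("unet", "lrn", "pointwise"):
        model = build_model(tiny_config(family=family), seed=4)
        x = rng.uniform(-1, 1, (2, 32))
        before, _ = model.forward(x)
        save_checkpoint(model, tmp_path / f"{family}.npz",
                        manifest_hash="abc123")
        back, meta = load_checkpoint(tmp_path / f"{family}.npz")
        assert meta["manifest_hash"] == "abc123"
        assert back.config == model.config
        after, _ = back.forward(x)
        for lead in before:
            np.testing.assert_array_equal(before[lead], after[lead])


def test_describe_mentions_family_and_parameters():
    model = build_model(tiny_config(), seed=0)
    text = describe(model)
    assert "unet" in text and "parameters" in text
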