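"""Architecture builders: parameter accounting, output contracts, dense wiring."""

import numpy as np
import pytest

from hepaseg import (ArchitectureConfig, build_hybrid_wnet, build_unet3d,
                     count_parameters, reshape_2d_to_3d, reshape_3d_to_2d)
from hepaseg.errors import ConfigError, ResourceError
from tests.conftest import tiny_hybrid_config


# hand closed forms: a conv is k^d*cin*cout (+cout with bias); a BN is 4*cout,
# half of which (moving mean/var) is non-trainable
def conv(k, cin, cout, d=3, bias=True):
    return k ** d * cin * cout + (cout if bias else 0)


def bn(c):
    return 4 * c


class TestParameterClosedForms:
    def test_first_standard_block_hand_count(self):
        cfg = ArchitectureConfig(style="standard", layers=1, conv_blocks_initial=1,
                                 filters_initial=8)
        model = build_unet3d(cfg)
        recs = {r["name"]: r for r in model.graph}
        c = recs["enc0/b0/conv"]
        b = recs["enc0/b0/bn"]
        assert c["params_trainable"] == 2 * 27 * 8 + 8       # conv with bias
        assert b["params_trainable"] + b["params_non_trainable"] == 32
        assert b["params_non_trainable"] == 16               # running statistics
        block_total = sum(r["params_trainable"] + r["params_non_trainable"]
                          for r in (c, b))
        assert block_total == 472
        assert (c["params_trainable"] + b["params_trainable"]) == 456

    def test_standard_one_layer_total(self):
        cfg = ArchitectureConfig(style="standard", layers=1, conv_blocks_initial=1,
                                 filters_initial=8)
        # enc0: 2->8; bottom (16 filters): 8->16; dec0: cat(16+8)->8; 1x1 head
        expected = (conv(3, 2, 8) + bn(8)
                    + conv(3, 8, 16) + bn(16)
                    + conv(3, 24, 8) + bn(8)
                    + conv(1, 8, 2))
        total, tr, nt = build_unet3d(cfg).parameter_counts
        assert total == expected
        assert nt == (8 + 16 + 8) * 2
        assert tr == total - nt

    def test_standard_two_blocks_total(self):
        cfg = ArchitectureConfig(style="standard", layers=1, conv_blocks_initial=2,
                                 filters_initial=8)
        expected = (conv(3, 2, 8) + bn(8) + conv(3, 8, 8) + bn(8)
                    + conv(3, 8, 16) + bn(16) + conv(3, 16, 16) + bn(16)
                    + conv(3, 24, 8) + bn(8) + conv(3, 8, 8) + bn(8)
                    + conv(1, 8, 2))
        assert build_unet3d(cfg).parameter_counts[0] == expected

    def test_residual_one_layer_total(self):
        cfg = ArchitectureConfig(style="residual", layers=1, conv_blocks_initial=1,
                                 filters_initial=8)
        # each channel-changing block adds a 1x1 projection for the skip
        expected = (conv(3, 2, 8) + bn(8) + conv(1, 2, 8)
                    + conv(3, 8, 16) + bn(16) + conv(1, 8, 16)
                    + conv(3, 24, 8) + bn(8) + conv(1, 24, 8)
                    + conv(1, 8, 2))
        assert build_unet3d(cfg).parameter_counts[0] == expected

    def test_dense_one_layer_total(self):
        cfg = ArchitectureConfig(style="dense", layers=1, conv_blocks_initial=2,
                                 filters_initial=8, growth_rate=4, filters_max=128)
        # dense block: BN on the concatenated input, then conv; block k emits
        # filters + k*growth channels; level output is the full concatenation
        expected = (
            bn(2) + conv(3, 2, 8) + bn(10) + conv(3, 10, 12)            # enc0
            + bn(22) + conv(3, 22, 16) + bn(38) + conv(3, 38, 20)       # bottom
            + bn(80) + conv(3, 80, 8) + bn(88) + conv(3, 88, 12)        # dec0
            + conv(1, 100, 2))                                          # head
        assert build_unet3d(cfg).parameter_counts[0] == expected

    def test_tiny_hybrid_first_3d_conv(self, tiny_hybrid):
        recs = {r["name"]: r for r in tiny_hybrid.graph}
        c = recs["enc3d/l0/b0/conv"]
        cin = 2 + tiny_hybrid.config.feature_channels
        assert c["params_trainable"] == 27 * cin * 4     # bias-free

    def test_total_equals_trainable_plus_non_trainable(self, tiny_hybrid):
        total, tr, nt = count_parameters(tiny_hybrid)
        assert total == tr + nt


class TestConfig:
    def test_filters_double_per_level_capped(self):
        cfg = ArchitectureConfig(filters_initial=8, filters_max=128)
        assert cfg.filters_at(2) == 32
        assert cfg.filters_at(5) == 128

    def test_blocks_increase_capped(self):
        cfg = ArchitectureConfig(conv_blocks_initial=2, conv_block_increase=2,
                                 conv_blocks_max=4)
        assert [cfg.blocks_at(n) for n in range(3)] == [2, 4, 4]

    def test_dense_unbounded_without_growth_rejected(self):
        with pytest.raises(ConfigError):
            ArchitectureConfig(style="dense", filters_max=None, growth_rate=None)

    def test_builders_reject_wrong_style(self):
        with pytest.raises(ConfigError):
            build_unet3d(ArchitectureConfig(style="hybrid_wnet"))
        with pytest.raises(ConfigError):
            build_hybrid_wnet(ArchitectureConfig(style="standard"))

    def test_missing_pretrained_weights_raise(self, tmp_path):
        with pytest.raises(ResourceError):
            build_hybrid_wnet(tiny_hybrid_config(),
                              pretrained=tmp_path / "imagenet.npz")

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = tiny_hybrid_config()
        path = tmp_path / "arch.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert ArchitectureConfig.from_yaml(path) == cfg


class TestForwardContracts:
    @pytest.mark.parametrize("style", ["standard", "residual", "dense"])
    def test_probabilities_sum_to_one(self, style):
        cfg = ArchitectureConfig(style=style, layers=1, conv_blocks_initial=1,
                                 filters_initial=4,
                                 growth_rate=0 if style == "dense" else None)
        model = build_unet3d(cfg, rng_seed=1)
        rng = np.random.default_rng(0)
        p = model.forward(rng.normal(size=(6, 12, 12)).astype(np.float32),
                          np.ones((6, 12, 12), np.float32))
        assert p.shape == (6, 12, 12, 2)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-5)

    def test_full_slab_forward_shape(self):
        """A whole 32x120x120 two-channel slab maps to per-voxel probabilities."""
        cfg = ArchitectureConfig(style="standard", layers=1, conv_blocks_initial=1,
                                 filters_initial=4)
        model = build_unet3d(cfg, rng_seed=0)
        rng = np.random.default_rng(1)
        p = model.forward(rng.normal(size=(32, 120, 120)).astype(np.float32),
                          np.ones((32, 120, 120), np.float32))
        assert p.shape == (32, 120, 120, 2)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_unet_variable_input_sizes(self, seed):
        cfg = ArchitectureConfig(style="standard", layers=2, conv_blocks_initial=1,
                                 filters_initial=4)
        model = build_unet3d(cfg, rng_seed=0)
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 14, size=3))
        p = model.forward(rng.normal(size=shape).astype(np.float32),
                          np.ones(shape, np.float32))
        assert p.shape == shape + (2,)

    @pytest.mark.parametrize("shape", [(6, 24, 24), (10, 36, 44), (7, 17, 30),
                                       (12, 40, 40), (5, 25, 19)])
    def test_hybrid_variable_input_sizes(self, tiny_hybrid, shape):
        rng = np.random.default_rng(0)
        p = tiny_hybrid.forward(rng.normal(size=shape).astype(np.float32),
                                np.ones(shape, np.float32))
        assert p.shape == shape + (2,)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-5)

    def test_hybrid_2d_head_output(self, tiny_hybrid):
        rng = np.random.default_rng(2)
        shape = (4, 24, 24)
        p = tiny_hybrid.forward(rng.normal(size=shape).astype(np.float32),
                                np.ones(shape, np.float32), head="out2d")
        assert p.shape == shape + (2,)


class TestDenseWiring:
    def test_dense_input_channels_grow_linearly(self):
        """Within a dense level the k-th conv input grows by filters+k*growth."""
        cfg = ArchitectureConfig(style="dense", layers=1, conv_blocks_initial=3,
                                 filters_initial=8, growth_rate=4, filters_max=256)
        model = build_unet3d(cfg)
        recs = [r for r in model.graph if r["name"].startswith("enc0/b")
                and r["kind"] == "conv"]
        cins = [r["in_channels"] for r in recs]
        couts = [r["out_channels"] for r in recs]
        assert couts == [8, 12, 16]
        assert np.all(np.diff(cins) == np.array(couts[:-1]))  # concat growth

    def test_hybrid_3d_convs_see_all_same_scale_outputs(self, tiny_hybrid):
        """Global dense connectivity: full-resolution conv inputs accumulate
        every previous full-resolution output, including the upsampled path."""
        recs = [r for r in tiny_hybrid.graph if r["kind"] == "conv"
                and r["scope"] == "3d" and r["kernel"] == (3, 3, 3)
                and r["scale"] == 1]
        cins = [r["in_channels"] for r in recs]
        assert all(b > a for a, b in zip(cins, cins[1:]))
        # decoder convs at scale 1 see encoder outputs + the upsampled deep path
        enc_out = 2 + tiny_hybrid.config.feature_channels + 2 * 4
        assert cins[2] > enc_out


class TestReshape:
    def test_batch_to_stacked_slices(self):
        x = np.zeros((8, 32, 120, 120, 1), np.float32)
        assert reshape_3d_to_2d(x).shape == (256, 120, 120, 1)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 4, 6, 5, 2)).astype(np.float32)
        np.testing.assert_array_equal(reshape_2d_to_3d(reshape_3d_to_2d(x), 3), x)

    def test_single_slice_volume(self):
        x = np.zeros((1, 1, 8, 8, 2))
        assert reshape_3d_to_2d(x).shape == (1, 8, 8, 2)

    def test_slice_ordering_is_patient_major(self):
        x = np.arange(2 * 3).reshape(2, 3, 1, 1, 1).astype(float)
        flat = reshape_3d_to_2d(x)[:, 0, 0, 0]
        np.testing.assert_array_equal(flat, [0, 1, 2, 3, 4, 5])


class TestFreezingCounts:
    def test_freezing_2d_moves_counts_not_total(self, tiny_hybrid):
        total0, tr0, nt0 = tiny_hybrid.parameter_counts
        tiny_hybrid.freeze(["2d"])
        total1, tr1, nt1 = tiny_hybrid.parameter_counts
        assert total1 == total0
        assert tr1 < tr0 and nt1 > nt0
        scope_2d = sum(r["params_trainable"] + r["params_non_trainable"]
                       for r in tiny_hybrid.graph if r["scope"].startswith("2d"))
        assert nt1 - nt0 == tr0 - tr1
        tiny_hybrid.unfreeze()
        assert tiny_hybrid.parameter_counts == (total0, tr0, nt0)


@pytest.fixture(scope="module")
def full_hybrid():
    return build_hybrid_wnet(ArchitectureConfig(style="hybrid_wnet"))


class TestFullScaleHybrid:
    """Full-size build: backbone anchored to the canonical DenseNet-121 counts."""

    def test_backbone_matches_densenet121_reference_counts(self, full_hybrid):
        enc = [r for r in full_hybrid.graph if r["scope"] == "2d.encoder"]
        total = sum(r["params_trainable"] + r["params_non_trainable"] for r in enc)
        nt = sum(r["params_non_trainable"] for r in enc)
        assert total == 7_037_504          # DenseNet-121, classifier excluded
        assert nt == 83_648                # its batch-norm running statistics

    def test_2d_features_have_32_channels(self, full_hybrid):
        recs = {r["name"]: r for r in full_hybrid.graph}
        assert recs["dec2d/s4/c1"]["out_channels"] == 32
        assert recs["enc3d/l0/b0/conv"]["in_channels"] == 34   # image+liver+features

    def test_counts_consistent_and_documented_readings(self, full_hybrid):
        total, tr, nt = full_hybrid.parameter_counts
        assert total == tr + nt
        # the two printed readings of the 3D filter count bracket ~14.5M
        assert total == 13_875_092
        alt = build_hybrid_wnet(ArchitectureConfig(style="hybrid_wnet", filters_3d=32))
        assert alt.parameter_counts[0] == 15_335_636
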