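import numpy as np
import pytest

from dgtta.autodiff import Tensor
from dgtta.gin import gin_augment
from dgtta.network import UNet3D
from dgtta.pretrain import (FeaturePipeline, SegmentationModel, TrainConfig,
                            apply_feature_pipeline, normalize_volume, predict,
                            pretrain)
from dgtta.ssc import compute_ssc


class TestFeaturePipeline:
    def test_mode_none_is_identity(self, small_volume):
        out = apply_feature_pipeline(small_volume, FeaturePipeline("none"))
        np.testing.assert_array_equal(out[0], small_volume.data)
        assert out.shape[0] == 1

    def test_gin_inactive_at_test_time(self, small_volume):
        fp = FeaturePipeline("gin+ssc")
        test_out = apply_feature_pipeline(small_volume, fp, "test")
        ssc_out = apply_feature_pipeline(small_volume, FeaturePipeline("ssc"), "test")
        np.testing.assert_array_equal(test_out, ssc_out)

    def test_gin_then_ssc_composition_at_train_time(self, small_volume):
        fp = FeaturePipeline("gin+ssc")
        got = apply_feature_pipeline(small_volume, fp, "train",
                                     np.random.default_rng(77))
        manual = compute_ssc(gin_augment(small_volume.data, fp.gin_cfg,
                                         np.random.default_rng(77))).data
        np.testing.assert_allclose(got, manual, atol=1e-12)

    def test_channel_counts(self):
        assert FeaturePipeline("none").in_channels == 1
        assert FeaturePipeline("gin").in_channels == 1
        assert FeaturePipeline("ssc").in_channels == 12
        assert FeaturePipeline("gin+ssc").in_channels == 12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            FeaturePipeline("fourier")

    def test_train_gin_without_rng_rejected(self, small_volume):
        with pytest.raises(ValueError):
            apply_feature_pipeline(small_volume, FeaturePipeline("gin"), "train")


class TestNetwork:
    def test_channel_mismatch_rejected(self, rng):
        net = UNet3D(1, 3, 4)
        with pytest.raises(ValueError, match="channels"):
            net.forward(Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32)))

    def test_output_simplex(self, rng):
        net = UNet3D(1, 4, 4)
        probs = net.predict_probs(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert probs.shape == (4, 8, 8, 8)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = UNet3D(1, 3, 4, rng=np.random.default_rng(2))
        model = SegmentationModel(net, FeaturePipeline("ssc"), [0, 1, 2])
        model.save(tmp_path / "m.ckpt")
        back = SegmentationModel.load(tmp_path / "m.ckpt")
        assert back.feature_pipeline.mode == "ssc"
        assert back.class_ids == [0, 1, 2]
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_probs(x),
                                      back.net.predict_probs(x))

    def test_parameter_subsets(self):
        net = UNet3D(1, 3, 4)
        all_names = set(net.parameter_names("all"))
        norm = set(net.parameter_names("normalization_only"))
        enc = set(net.parameter_names("encoder_only"))
        assert norm < all_names and enc < all_names
        assert all(n.startswith("n_") for n in norm)
        assert not any(n.startswith(("dec", "n_dec", "head")) for n in enc)


class TestPretrain:
    def test_loss_decreases_over_epochs(self, tiny_model):
        _, log = tiny_model
        assert log["epoch_loss"][-1] < log["epoch_loss"][0]

    def test_training_is_deterministic(self, tiny_phantoms, tiny_train_cfg):
        train_set = [(src, lm) for lm, src, _ in tiny_phantoms[:1]]
        cfg = TrainConfig(patch_size=(16, 16, 16), batch_size=1, epochs=1,
                          iters_per_epoch=4, seed=9)
        _, log1 = pretrain(train_set, FeaturePipeline("none"), cfg)
        _, log2 = pretrain(train_set, FeaturePipeline("none"), cfg)
        assert log1["iter_loss"] == log2["iter_loss"]

    def test_empty_train_set_rejected(self, tiny_train_cfg):
        with pytest.raises(ValueError):
            pretrain([], FeaturePipeline("none"), tiny_train_cfg)

    def test_misaligned_labels_rejected(self, tiny_phantoms, tiny_train_cfg):
        lm, src, _ = tiny_phantoms[0]
        import dgtta.core as core
        bad = core.LabelMap(lm.data[:-2], lm.spacing)
        with pytest.raises(ValueError):
            pretrain([(src, bad)], FeaturePipeline("none"), tiny_train_cfg)


class TestPredict:
    def test_single_patch_equals_direct_forward(self, tiny_model, tiny_phantoms):
        model, _ = tiny_model
        _, src, _ = tiny_phantoms[2]
        pm = predict(model, src, patch_size=src.shape)
        feat = apply_feature_pipeline(normalize_volume(src),
                                      model.feature_pipeline, "test")
        direct = model.net.predict_probs(feat.astype(np.float32))
        np.testing.assert_allclose(pm.data, direct, atol=1e-6)

    def test_tiled_close_to_untiled(self, tiny_model, tiny_phantoms):
        # per-patch normalization statistics make tiling and whole-volume
        # inference agree only approximately; the bound reflects that
        model, _ = tiny_model
        _, src, _ = tiny_phantoms[2]
        whole = predict(model, src, patch_size=src.shape)
        tiled = predict(model, src, patch_size=(16, 16, 16))
        assert np.abs(whole.data - tiled.data).mean() <= 0.05

    def test_volume_smaller_than_patch_padded(self, tiny_model, rng):
        from dgtta.core import Volume
        model, _ = tiny_model
        v = Volume(rng.normal(size=(12, 12, 12)))
        pm = predict(model, v, patch_size=(16, 16, 16))
        assert pm.shape == (12, 12, 12)
        np.testing.assert_allclose(pm.data.sum(axis=0), 1.0, atol=1e-5)
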