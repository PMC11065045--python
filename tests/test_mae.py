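"""Masked-autoencoder core: patchify, masking, encoding, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maepick import (MaeConfig, MaskedAutoencoder, mse_loss, patchify,
                     random_mask, unpatchify)
from maepick.train import param_hash


class TestPatchify:
    def test_standard_vit_geometry(self):
        img = np.random.default_rng(0).normal(size=(224, 224))
        patches = patchify(img, 16)
        assert patches.shape == (196, 256)

    def test_small_image_count(self):
        patches = patchify(np.zeros((32, 32)), 16)
        assert patches.shape == (4, 256)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(1, 4), st.integers(1, 3), st.sampled_from([4, 8]))
    def test_round_trip_identity(self, gmul, batch, p):
        size = gmul * p
        imgs = np.random.default_rng(gmul + batch).normal(size=(batch, size, size))
        np.testing.assert_array_equal(unpatchify(patchify(imgs, p), p), imgs)

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            patchify(np.zeros((30, 30)), 16)


class TestRandomMask:
    def test_mask_count_and_conservation(self, rng):
        mb = random_mask(196, 0.75, rng, batch_size=8)
        assert (mb.mask_index.sum(axis=1) == 147).all()
        assert (~mb.mask_index).sum(axis=1).max() == 49
        for b in range(8):
            assert sorted(mb.ids_restore[b]) == list(range(196))

    def test_zero_ratio_keeps_everything_in_order(self, rng):
        mb = random_mask(16, 0.0, rng, batch_size=2)
        assert mb.mask_index.sum() == 0
        np.testing.assert_array_equal(mb.ids_keep[0], np.arange(16))

    def test_determinism_and_ratio_validation(self):
        m1 = random_mask(64, 0.5, 123, batch_size=3)
        m2 = random_mask(64, 0.5, 123, batch_size=3)
        np.testing.assert_array_equal(m1.mask_index, m2.mask_index)
        with pytest.raises(ValueError, match="mask_ratio"):
            random_mask(64, 1.0, 0)

    def test_accepts_patch_array(self, rng):
        patches = np.zeros((5, 64, 16))
        mb = random_mask(patches, 0.25, rng)
        assert mb.mask_index.shape == (5, 64)
        assert (mb.mask_index.sum(axis=1) == 16).all()


class TestEncode:
    def test_identical_inputs_identical_latents(self, tiny_model, rng):
        img = rng.normal(size=(32, 32))
        z1 = tiny_model.embed(img)
        z2 = tiny_model.embed(img)
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (1, 16)
        assert np.isfinite(z1).all()

    def test_different_masks_different_latents(self, tiny_model, rng):
        img = rng.normal(size=(1, 32, 32))
        m1 = random_mask(16, 0.75, np.random.default_rng(0))
        m2 = random_mask(16, 0.75, np.random.default_rng(5))
        assert not np.array_equal(m1.ids_keep, m2.ids_keep)
        _, z1 = tiny_model.encode(img, m1)
        _, z2 = tiny_model.encode(img, m2)
        assert np.abs(z1.data - z2.data).max() > 1e-6

    def test_wrong_input_size_raises(self, tiny_model):
        with pytest.raises(ValueError, match="32x32"):
            tiny_model.encode(np.zeros((64, 64)))

    def test_cls_pooling_shape(self):
        cfg = MaeConfig(input_size=32, patch_size=8, embed_dim=16, depth=1,
                        n_heads=2, decoder_embed_dim=8, decoder_depth=1,
                        pooling="cls_token")
        model = MaskedAutoencoder(cfg, seed=1)
        tokens, latent = model.encode(np.zeros((2, 32, 32)))
        assert latent.shape == (2, 16)
        assert tokens.shape == (2, 16, 16)  # cls token stripped from tokens


class TestReconstructionLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        from maepick._autodiff import Tensor

        target = rng.normal(size=(2, 16, 64)).astype(np.float32)
        mask = random_mask(16, 0.5, rng, batch_size=2)
        assert mse_loss(Tensor(target), target, mask).item() == 0.0

    def test_constant_offset_unit_loss(self, rng):
        from maepick._autodiff import Tensor

        target = rng.normal(size=(2, 16, 64)).astype(np.float32)
        mask = random_mask(16, 0.5, rng, batch_size=2)
        loss = mse_loss(Tensor(target + 1.0), target, mask)
        assert abs(loss.item() - 1.0) < 1e-6

    def test_matches_naive_loop_over_masked_patches(self, rng):
        from maepick._autodiff import Tensor

        pred = rng.normal(size=(3, 16, 64)).astype(np.float32)
        target = rng.normal(size=(3, 16, 64)).astype(np.float32)
        mask = random_mask(16, 0.75, rng, batch_size=3)
        expected_terms = [
            (pred[b, p] - target[b, p]) ** 2
            for b in range(3) for p in range(16) if mask.mask_index[b, p]
        ]
        expected = np.concatenate(expected_terms).mean()
        got = mse_loss(Tensor(pred), target, mask).item()
        assert abs(got - expected) < 1e-6


class TestTraining:
    def test_reconstruction_improves_on_small_crop_set(self):
        """200 optimizer steps on 20 crops at least halve the masked MSE.

        Crop noise is kept low (sigma 0.05) so the irreducible noise
        floor does not dominate the reconstruction target.
        """
        from maepick import TrainPlan, pretrain
        from maepick.train import RegionCrop

        rng = np.random.default_rng(0)
        crops = []
        for _ in range(20):
            base = np.zeros((32, 32), np.float32)
            cx, cy = rng.integers(10, 22, size=2)
            yy, xx = np.mgrid[0:32, 0:32]
            base += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / 18.0)
            base += 0.05 * rng.normal(size=(32, 32))
            crops.append(RegionCrop(base, (16.0, 16.0), "unlabeled"))
        cfg = MaeConfig(input_size=32, patch_size=8, embed_dim=32, depth=2,
                        n_heads=2, decoder_embed_dim=16, decoder_depth=1)
        model = MaskedAutoencoder(cfg, seed=0)
        plan = TrainPlan(pretrain_steps=200, batch_size=16, seed=0)
        log = pretrain(model, crops, plan)
        assert log.l_mse.iloc[-10:].mean() < 0.5 * log.l_mse.iloc[0]


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, tmp_path, rng):
        img = rng.normal(size=(32, 32))
        before = tiny_model.embed(img)
        path = tiny_model.save(tmp_path / "ckpt.npz")
        loaded = MaskedAutoencoder.load(path)
        assert param_hash(loaded) == param_hash(tiny_model)
        np.testing.assert_array_equal(loaded.embed(img), before)
        assert loaded.cfg == tiny_model.cfg

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            MaeConfig(input_size=224, patch_size=15)
        with pytest.raises(ValueError, match="mask_ratio"):
            MaeConfig(mask_ratio=1.2)
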