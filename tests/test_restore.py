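"""Occlusion restoration: the cGAN contract and the geometric baseline."""

import numpy as np
import pytest

from grainscan import restore, synth, traits
from grainscan.restore import (
    Restorer,
    RestorerConfig,
    build_discriminator,
    build_generator,
    restore_baseline,
    train,
)
from tests.conftest import MM150, MM600


def _small_cfg(**kw):
    kw.setdefault("image_size", 64)
    kw.setdefault("base_channels", 8)
    kw.setdefault("batch_size", 4)
    return RestorerConfig(**kw)


def _clean_crop(size=64, seed=0):
    rng = np.random.default_rng(seed)
    model = synth.sample_grain(synth.GrainDistribution(), rng)
    crop, mask = synth.render_grain(model, MM150, rng=rng, crop_size=(size, size))
    return crop, mask


class TestGeneratorContract:
    def test_output_shape_matches_input(self):
        gen = build_generator(_small_cfg(), seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        assert gen.forward(x).shape == (1, 3, 64, 64)
        # fully convolutional: native restoration size also passes through
        big = np.random.default_rng(1).random((1, 3, 256, 256))
        assert gen.forward(big).shape == (1, 3, 256, 256)

    def test_feature_schedule_halving_doubling(self):
        gen = build_generator(RestorerConfig(image_size=256, base_channels=8))
        sched = gen.feature_schedule()
        sizes = [s for _, _, s in sched]
        assert sizes == [256, 256, 128, 64, 32, 64, 128, 256, 256]
        chans = [c for _, c, c_ in zip([n for n, _, _ in sched],
                                       [c for _, c, _ in sched], sizes)]
        assert [c for _, c, _ in sched] == [3, 8, 16, 32, 32, 16, 8, 8, 3]

    def test_incompatible_size_rejected(self):
        gen = build_generator(_small_cfg())
        with pytest.raises(ValueError):
            gen.forward(np.zeros((1, 3, 60, 60)))
        with pytest.raises(ValueError):
            RestorerConfig(image_size=100)

    def test_identity_overfit_monotone(self):
        clean, _ = _clean_crop(seed=3)
        x = restore._to_nchw(clean)
        gen = build_generator(_small_cfg(), seed=0)
        errors = gen.fit_l1(x, x, steps=200, lr=1e-3, checkpoint_every=25)
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_gradient_check_conv(self):
        """Finite-difference check of the conv layer's backward pass."""
        from grainscan import _nn

        rng = np.random.default_rng(0)
        conv = _nn.Conv2d(2, 3, k=3, stride=2, pad=1, rng=rng)
        x = rng.random((1, 2, 8, 8))
        out = conv.forward(x)
        dout = rng.random(out.shape)
        dx = conv.backward(dout)
        eps = 1e-6
        for idx in [(0, 0, 3, 3), (0, 1, 0, 7)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = ((conv.forward(xp) * dout).sum() - (conv.forward(xm) * dout).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestDiscriminatorContract:
    def test_patch_map_is_30x30_at_256(self):
        disc = build_discriminator(RestorerConfig(image_size=256, base_channels=4))
        out = disc.forward(np.zeros((256, 256, 3), np.uint8),
                           np.zeros((256, 256, 3), np.uint8))
        assert out.patch_scores.shape == (30, 30)
        assert 0.0 < out.global_score < 1.0
        assert np.all((out.patch_scores > 0) & (out.patch_scores < 1))

    def test_patch_grid_one_degenerates_to_global(self):
        disc = build_discriminator(_small_cfg(patch_grid=1))
        out = disc.forward(np.zeros((64, 64, 3), np.uint8),
                           np.zeros((64, 64, 3), np.uint8))
        assert out.patch_scores.shape == (1, 1)

    def test_separation_after_toy_training(self):
        pairs = synth.generate_pairs(8, (0.2, 0.4), seed=5, size=64,
                                     mm_per_px=MM150)
        cfg = _small_cfg()
        restorer = train(pairs, cfg, seed=0, steps=50, checkpoint_every=50)
        # rebuild the training discriminator is internal; instead check the
        # trained generator moved toward the clean target
        assert restorer.history[-1]["val_l1"] < restorer.history[0]["val_l1"]


class TestTraining:
    def test_smoke_training_lowers_validation_error(self):
        pairs = synth.generate_pairs(20, (0.15, 0.35), seed=11, size=64,
                                     mm_per_px=MM150)
        restorer = train(pairs, _small_cfg(), seed=0, steps=100,
                         checkpoint_every=25)
        untrained = restorer.history[0]["val_l1"]
        trained = restorer.history[-1]["val_l1"]
        assert trained < untrained

    def test_identity_dataset_learns_identity(self):
        pairs = synth.generate_pairs(8, (0.0, 0.0), seed=13, size=64,
                                     mm_per_px=MM150)
        restorer = train(pairs, _small_cfg(), seed=0, steps=150,
                         checkpoint_every=25)
        untrained = restorer.history[0]["val_l1"]
        trained = restorer.history[-1]["val_l1"]
        assert trained * 5 < untrained

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], _small_cfg(), seed=0)

    def test_config_roundtrip(self, tmp_path):
        cfg = _small_cfg(patch_grid=4, l1_weight=50.0)
        cfg.to_json(tmp_path / "cfg.json")
        assert RestorerConfig.from_json(tmp_path / "cfg.json") == cfg

    def test_weights_roundtrip(self, tmp_path):
        pairs = synth.generate_pairs(4, (0.0, 0.0), seed=1, size=64,
                                     mm_per_px=MM150)
        restorer = train(pairs, _small_cfg(), seed=0, steps=5,
                         checkpoint_every=5)
        restorer.save(tmp_path / "w.npz")
        loaded = Restorer.load(tmp_path / "w.npz", _small_cfg())
        out_a = restorer.restore(pairs[0].occluded)
        out_b = loaded.restore(pairs[0].occluded)
        assert np.array_equal(out_a, out_b)

    def test_default_config_matches_training_recipe(self):
        cfg = RestorerConfig()
        assert cfg.image_size == 256
        assert cfg.batch_size == 64
        assert cfg.optimizer == "Adam"
        assert cfg.lr == 0.0002
        assert cfg.max_epochs == 500


class TestGeometricBaseline:
    def _end_occluded(self, ratio=0.3, side=False, seed=0):
        """A grain with a strip occluder over one end (or one side)."""
        rng = np.random.default_rng(seed)
        model = synth.GrainModel(8.6, 2.8, orientation=0.0, shape_n=2.0,
                                 noise_sd=5.0)
        clean, mask = synth.render_grain(model, MM600, rng=rng,
                                         crop_size=(256, 256))
        ys, xs = np.nonzero(mask)
        occ = np.zeros_like(mask)
        if side:
            # cover the lower flank of the grain
            cut = np.quantile(ys, 1.0 - ratio)
            occ[int(cut) : ys.max() + 7, xs.min() - 6 : xs.max() + 7] = True
        else:
            # cover one end of the grain
            cut = np.quantile(xs, 1.0 - ratio)
            occ[ys.min() - 6 : ys.max() + 7, int(cut) : xs.max() + 7] = True
        occluded = clean.copy()
        occluded[occ] = synth.BRANCH_RGB
        return model, clean, occluded, occ, mask

    def test_zero_occlusion_identity(self):
        _, clean, _, _, _ = self._end_occluded(0.3)
        out = restore_baseline(clean, np.zeros(clean.shape[:2], bool))
        assert np.array_equal(out, clean)

    def test_end_occlusion_length_recovered(self):
        model, clean, occluded, occ, _ = self._end_occluded(0.3)
        restored = restore_baseline(occluded, occ)
        t = traits.extract_grain_traits(restored, MM600)
        assert t.length == pytest.approx(model.length, rel=0.03)

    def test_side_occlusion_width_recovered(self):
        model, clean, occluded, occ, _ = self._end_occluded(0.3, side=True)
        restored = restore_baseline(occluded, occ)
        t = traits.extract_grain_traits(restored, MM600)
        assert t.width == pytest.approx(model.width, rel=0.05)

    def test_never_shrinks_visible_silhouette(self):
        pairs = synth.generate_pairs(5, (0.2, 0.4), seed=21, mm_per_px=MM600)
        for p in pairs:
            restored = restore_baseline(p.occluded, p.occluder_mask)
            visible = p.grain_mask & ~p.occluder_mask
            gray = traits.red_channel(restored)
            fg = traits.binarize(gray, traits.otsu_threshold(gray))
            assert np.all(fg[visible])

    def test_too_little_visible_fails_explicitly(self):
        _, _, occluded, occ, mask = self._end_occluded(0.3)
        # occlude almost everything
        big = np.ones_like(occ)
        big[:10] = False
        with pytest.raises(ValueError):
            restore_baseline(occluded, big)

    def test_deterministic(self):
        _, _, occluded, occ, _ = self._end_occluded(0.25, seed=4)
        a = restore_baseline(occluded, occ)
        b = restore_baseline(occluded, occ)
        assert np.array_equal(a, b)


class TestRestorationImprovesFidelity:
    def test_psnr_ssim_ordering_on_pairs(self):
        """Restored crops must sit closer to the clean reference than the
        occluded inputs, in both PSNR and SSIM (paired means)."""
        from grainscan import metrics

        pairs = synth.generate_pairs(10, (0.25, 0.35), seed=31, mm_per_px=MM600)
        d_psnr, d_ssim = [], []
        for p in pairs:
            restored = restore_baseline(p.occluded, p.occluder_mask)
            d_psnr.append(metrics.psnr(p.clean, restored)
                          - metrics.psnr(p.clean, p.occluded))
            d_ssim.append(metrics.ssim(p.clean, restored)
                          - metrics.ssim(p.clean, p.occluded))
        assert np.mean(d_psnr) > 0
        assert np.mean(d_ssim) > 0
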