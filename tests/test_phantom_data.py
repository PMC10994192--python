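"""Phantom generator: determinism, allocation, noise statistics, mask fidelity."""

import numpy as np
import pytest

from umsrep.phantom_data import (NoiseSpec, PhantomConfig, PhantomConfigError,
                                 add_noise, generate_phantoms,
                                 largest_remainder_counts, save_phantoms)


class TestGeneration:
    def test_seeded_determinism_bit_identical(self):
        cfg = PhantomConfig(image_size=32, n_samples=20, abnormal_fraction=0.4,
                            noise=NoiseSpec("gaussian", 15), seed=7)
        a = generate_phantoms(cfg)
        b = generate_phantoms(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)
            assert (sa.class_label, sa.quality_label) == (sb.class_label, sb.quality_label)

    def test_zero_samples_gives_empty_collection(self):
        assert generate_phantoms(PhantomConfig(n_samples=0)) == []

    def test_exact_class_counts_from_largest_remainder(self):
        samples = generate_phantoms(PhantomConfig(image_size=32, n_samples=100,
                                                  abnormal_fraction=0.5, seed=0))
        labels = [s.class_label for s in samples]
        assert labels.count("abnormal") == 50
        assert labels.count("normal") == 50

    @pytest.mark.parametrize("n,mix,expected", [
        (10, {"a": 0.5, "b": 0.3, "c": 0.2}, {"a": 5, "b": 3, "c": 2}),
        (7, {"a": 0.5, "b": 0.5}, {"a": 4, "b": 3}),     # tie -> declaration order
        (5, {"a": 1.0, "b": 0.0}, {"a": 5, "b": 0}),
    ])
    def test_largest_remainder_allocation(self, n, mix, expected):
        assert largest_remainder_counts(n, mix) == expected

    def test_doppler_label_space_and_shapes(self):
        samples = generate_phantoms(PhantomConfig(image_size=48, style="doppler_like",
                                                  n_samples=30, seed=1))
        assert {s.class_label for s in samples} <= {"TR", "MV", "MA"}
        for s in samples:
            assert s.image.shape == s.mask.shape == (48, 48)
            assert set(np.unique(s.mask)) <= {0, 1}
            assert 0.0 <= s.image.min() and s.image.max() <= 1.0

    def test_lesions_lie_inside_the_organ_mask(self):
        cfg = PhantomConfig(image_size=64, n_samples=40,
                            class_mix={"normal": 0.0, "bacterial": 0.5, "viral": 0.5},
                            seed=2)
        for s in generate_phantoms(cfg):
            r0, c0, r1, c1 = s.lesion_bbox
            bright = s.clean_image > 0.7
            assert s.mask[r0:r1, c0:c1].size > 0
            # every bright lesion pixel sits inside the lung mask
            assert np.all(s.mask[bright & (s.clean_image > 0.7)] == 1)

    def test_low_quality_fraction_counts(self):
        samples = generate_phantoms(PhantomConfig(image_size=32, n_samples=20,
                                                  low_quality_fraction=0.25, seed=0))
        assert sum(s.quality_label == "low" for s in samples) == 5

    def test_linear_separability_of_clean_phantom_features(self):
        """Mean intensity + bright-area features separate normal vs abnormal."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        samples = generate_phantoms(PhantomConfig(image_size=64, n_samples=500,
                                                  abnormal_fraction=0.5, seed=5))
        feats = np.array([[s.clean_image.mean(), float(np.mean(s.clean_image > 0.65))]
                          for s in samples])
        y = np.array([s.class_label == "abnormal" for s in samples])
        acc = cross_val_score(LogisticRegression(), feats, y, cv=5).mean()
        assert acc >= 0.95

    @pytest.mark.parametrize("bad", [
        dict(image_size=8), dict(n_samples=-1), dict(abnormal_fraction=1.5),
        dict(style="mri_like"), dict(low_quality_fraction=-0.1),
        dict(class_mix={"normal": 0.5, "abnormal": 0.2}),
    ])
    def test_invalid_configuration_raises(self, bad):
        with pytest.raises(PhantomConfigError):
            cfg = PhantomConfig(**bad)
            cfg.resolved_mix()


class TestAddNoise:
    def test_sigma_zero_and_none_are_identity(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        np.testing.assert_array_equal(add_noise(img, NoiseSpec("gaussian", 0.0), 1), img)
        np.testing.assert_array_equal(add_noise(img, NoiseSpec("none"), 1), img)

    def test_gaussian_sample_std_matches_sigma(self):
        img = np.full((512, 512), 0.5, dtype=np.float32)
        noisy = add_noise(img, NoiseSpec("gaussian", 20.0), seed=0)
        std = float(((noisy - img) * 255.0).std())
        assert abs(std - 20.0) < 0.5

    def test_poisson_variance_tracks_mean(self):
        img = np.full((512, 512), 100 / 255.0, dtype=np.float32)
        noisy = add_noise(img, NoiseSpec("poisson"), seed=0)
        delta = (noisy - img) * 255.0
        assert abs(delta.var() - 100.0) < 3.0      # variance equals the mean
        assert abs(delta.mean()) < 0.2

    def test_output_clipped_to_unit_range(self):
        img = np.ones((32, 32), dtype=np.float32)
        noisy = add_noise(img, NoiseSpec("gaussian", 50.0), seed=0)
        assert noisy.max() <= 1.0 and noisy.min() >= 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(PhantomConfigError):
            NoiseSpec("gaussian", -1.0)


class TestRoundTrip:
    def test_png_round_trip_is_lossless_at_8_bit(self, tmp_path):
        from umsrep.image_io import load_dataset

        samples = generate_phantoms(PhantomConfig(image_size=32, n_samples=10, seed=0))
        manifest = save_phantoms(samples, tmp_path)
        source = load_dataset(manifest)
        assert len(source) == 10
        quantized = np.round(np.stack([s.image for s in samples]) * 255) / 255.0
        np.testing.assert_allclose(source.images, quantized, atol=1e-7)
        np.testing.assert_array_equal(source.masks, np.stack([s.mask for s in samples]))

    def test_split_allocation(self, tmp_path):
        samples = generate_phantoms(PhantomConfig(image_size=32, n_samples=20, seed=0))
        manifest = save_phantoms(samples, tmp_path, split_fractions=(0.7, 0.15, 0.15))
        import pandas as pd

        frame = pd.read_csv(manifest)
        assert frame["split"].value_counts().to_dict() == {"train": 14, "val": 3, "test": 3}
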