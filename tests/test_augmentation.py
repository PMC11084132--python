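import numpy as np
import pytest
import scipy.fft

from enosedx.augmentation import (AugmentationConfig, augment_dataset,
                                  nsa_augment, sda_augment)
from enosedx.errors import InvalidArgumentError, LeakageError
from enosedx.preprocess import BreathprintImage


def _rand_image(seed, sample_id="img", label="lung_cancer", partition=None):
    rng = np.random.default_rng(seed)
    return BreathprintImage(sample_id=sample_id, tensor=rng.standard_normal((14, 16, 16)),
                            label=label, partition=partition)


class TestNSA:
    def test_zero_noise_zero_shift_is_identity(self):
        img = _rand_image(0)
        cfg = AugmentationConfig(method="NSA", nsa_noise_sd=0.0, nsa_shift=0)
        out = nsa_augment(img, cfg, seed=1)
        np.testing.assert_allclose(out.tensor, img.tensor, atol=1e-9)
        assert out.label == img.label

    @pytest.mark.parametrize("k,s", [(33, 3), (200, 16), (5, 5)])
    def test_impulse_moves_backward_by_shift(self, k, s):
        tensor = np.zeros((14, 16, 16))
        flat = tensor.reshape(14, 256)
        flat[:, k] = 1.0
        img = BreathprintImage(sample_id="i", tensor=flat.reshape(14, 16, 16),
                               label="healthy_control")
        cfg = AugmentationConfig(method="NSA", nsa_noise_sd=0.0, nsa_shift=s)
        out = nsa_augment(img, cfg, seed=0).flat()
        assert out[0, k - s] == 1.0
        # edge replication fills the vacated tail with the last value
        np.testing.assert_array_equal(out[:, 256 - s:], np.zeros((14, s)))

    def test_mean_of_many_augmentations_recovers_original(self):
        img = _rand_image(3)
        cfg = AugmentationConfig(method="NSA", nsa_noise_sd=0.1, nsa_shift=0)
        n = 10_000
        acc = np.zeros_like(img.tensor)
        for i in range(n):
            acc += nsa_augment(img, cfg, seed=i).tensor
        mean = acc / n
        sd_per_channel = img.flat().std(axis=1) * 0.1
        se = (sd_per_channel / np.sqrt(n))[:, None, None]
        assert np.all(np.abs(mean - img.tensor) < 3.5 * se + 1e-12)

    def test_noise_free_nsa_commutes_with_channel_permutation(self):
        """The shift acts per channel, so it commutes with channel reordering."""
        img = _rand_image(4)
        cfg = AugmentationConfig(method="NSA", nsa_noise_sd=0.0, nsa_shift=5)
        perm = np.random.default_rng(0).permutation(14)
        permuted = BreathprintImage(sample_id="p", tensor=img.tensor[perm],
                                    label=img.label)
        a = nsa_augment(permuted, cfg, seed=9).tensor
        b = nsa_augment(img, cfg, seed=9).tensor[perm]
        np.testing.assert_array_equal(a, b)

    def test_excessive_shift_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AugmentationConfig(method="NSA", nsa_shift=256)


class TestSDA:
    def test_lambda_zero_is_identity(self):
        a, b = _rand_image(5), _rand_image(6)
        cfg = AugmentationConfig(method="SDA", sda_mix_lambda=0.0)
        out = sda_augment(a, b, cfg, seed=0)
        np.testing.assert_allclose(out.tensor, a.tensor, atol=1e-9)

    def test_equal_partners_are_a_fixed_point(self):
        a = _rand_image(7)
        cfg = AugmentationConfig(method="SDA", sda_mix_lambda="uniform")
        out = sda_augment(a, a, cfg, seed=3)
        np.testing.assert_allclose(out.tensor, a.tensor, atol=1e-9)

    def test_phase_spectrum_preserved_against_independent_dft(self):
        """Output phases match input phases, checked with scipy's FFT."""
        a, b = _rand_image(8), _rand_image(9)
        cfg = AugmentationConfig(method="SDA", sda_mix_lambda=0.7,
                                 sda_low_freq_fraction=0.25)
        out = sda_augment(a, b, cfg, seed=0)
        fa = scipy.fft.fft(a.flat(), axis=1)
        fo = scipy.fft.fft(out.flat(), axis=1)
        mask = np.abs(fo) > 1e-8
        phase_diff = np.angle(fo * np.conj(fa))
        assert np.abs(phase_diff[mask]).max() < 1e-7

    def test_mixed_band_amplitudes_lie_between_inputs(self):
        a, b = _rand_image(10), _rand_image(11)
        lam = 0.4
        cfg = AugmentationConfig(method="SDA", sda_mix_lambda=lam,
                                 sda_low_freq_fraction=0.25)
        out = sda_augment(a, b, cfg, seed=0)
        fa = np.abs(np.fft.rfft(a.flat(), axis=1))
        fb = np.abs(np.fft.rfft(b.flat(), axis=1))
        fo = np.abs(np.fft.rfft(out.flat(), axis=1))
        k = int(np.ceil(0.25 * fa.shape[1]))
        lo = np.minimum(fa, fb)[:, :k]
        hi = np.maximum(fa, fb)[:, :k]
        assert np.all(fo[:, :k] >= lo - 1e-8) and np.all(fo[:, :k] <= hi + 1e-8)

    def test_malformed_tensor_rejected_at_construction(self):
        # valid images always share (14, 16, 16); shape mismatches are
        # stopped at the container boundary
        with pytest.raises(InvalidArgumentError):
            BreathprintImage(sample_id="bad", tensor=np.zeros((14, 8, 8)))


class TestAugmentDataset:
    def test_ratio_one_exactly_doubles_every_class(self):
        images = (
            [_rand_image(i, f"a{i}", "lung_cancer") for i in range(7)]
            + [_rand_image(100 + i, f"b{i}", "healthy_control") for i in range(5)]
        )
        for method in ("NSA", "SDA"):
            out = augment_dataset(images, AugmentationConfig(method=method, seed=1))
            assert len(out) == 24
            from collections import Counter
            counts = Counter(img.label for img in out)
            assert counts["lung_cancer"] == 14 and counts["healthy_control"] == 10
            assert sum(img.augmented for img in out) == 12

    def test_training_cohort_size_doubles_at_unit_ratio(self):
        images = [_rand_image(i, f"s{i}") for i in range(118)]
        out = augment_dataset(images, AugmentationConfig(method="NSA", seed=0))
        assert len(out) == 236
        assert sum(img.augmented for img in out) == 118

    def test_single_image_sda_duplicates_itself(self):
        img = _rand_image(20, "solo")
        out = augment_dataset([img], AugmentationConfig(method="SDA", seed=0))
        assert len(out) == 2
        np.testing.assert_allclose(out[1].tensor, img.tensor, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            augment_dataset([], AugmentationConfig(method="NSA"))

    @pytest.mark.parametrize("partition", ["validation", "test"])
    def test_protected_partitions_refuse_augmentation(self, partition):
        images = [_rand_image(1, "v0", partition=partition)]
        with pytest.raises(LeakageError):
            augment_dataset(images, AugmentationConfig(method="NSA"))

    def test_dataset_augmentation_is_seeded_deterministic(self):
        images = [_rand_image(i, f"s{i}") for i in range(6)]
        cfg = AugmentationConfig(method="SDA", seed=33)
        a = augment_dataset(images, cfg)
        b = augment_dataset(images, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.tensor, y.tensor)
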