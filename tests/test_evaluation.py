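import numpy as np
import pytest

from enosedx.errors import InvalidArgumentError
from enosedx.evaluation import (bootstrap_ci, classification_metrics,
                                evaluate_condition, pca_embed, roc_auc,
                                roc_points, subgroup_accuracy, youden_threshold)
from enosedx.preprocess import BreathprintImage


def pairwise_auc(labels, scores):
    """Brute-force Mann-Whitney oracle: enumerate all case-control pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_small_fixture_matches_pairwise_enumeration(self):
        labels = [0, 1, 0, 1, 1]
        scores = [0.3, 0.2, 0.5, 0.7, 0.5]
        assert roc_auc(labels, scores) == pytest.approx(pairwise_auc(labels, scores))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_fixtures_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        labels = np.zeros(n)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 2)  # rounded to force some ties
        assert roc_auc(labels, scores) == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        assert roc_auc(labels, scores) == pytest.approx(roc_auc(labels, np.exp(3 * scores)))

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        scores = rng.random(25)  # continuous, ties almost surely absent
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        curve = roc_points(labels, rng.random(40))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


class TestClassificationMetrics:
    def test_perfect_scores_at_interior_threshold(self):
        sens, spec, acc, _ = classification_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 0.5)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_threshold_below_all_scores(self):
        sens, spec, acc, _ = classification_metrics([0, 1, 0, 1], [0.4, 0.6, 0.5, 0.7], 0.0)
        assert sens == 1.0 and spec == 0.0

    def test_ten_sample_fixture_matches_confusion_counts(self):
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        scores = np.array([0.1, 0.4, 0.6, 0.3, 0.5, 0.5, 0.7, 0.2, 0.9, 0.8])
        t = 0.5
        # by hand: predictions = score >= 0.5 (ties positive)
        tp, fn, tn, fp = 4, 1, 3, 2
        sens, spec, acc, _ = classification_metrics(labels, scores, t)
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))
        assert acc == pytest.approx((tp + tn) / 10)

    def test_youden_threshold_maximizes_j(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(30), 2)
        t = youden_threshold(labels, scores)
        js = []
        for cand in np.unique(scores):
            s, p, _, _ = classification_metrics(labels, scores, cand)
            js.append(s + p - 1)
        s, p, _, _ = classification_metrics(labels, scores, t)
        assert s + p - 1 == pytest.approx(max(js))


class TestBootstrap:
    def test_constant_metric_gives_zero_width_interval(self):
        lo, hi = bootstrap_ci(lambda l, s: 0.42, [0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8],
                              B=50, seed=0)
        assert lo == hi == 0.42

    def test_matches_independently_coded_stratified_resampler(self):
        """Dual implementation with the same documented seed-stream contract."""
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, 40).astype(float)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        B, alpha, seed = 2000, 0.05, 123

        lo, hi = bootstrap_ci(roc_auc, labels, scores, B=B, alpha=alpha, seed=seed)

        idx0 = np.flatnonzero(labels == 0)
        idx1 = np.flatnonzero(labels == 1)
        rng2 = np.random.default_rng(seed)
        vals = []
        for _ in range(B):
            r0 = idx0[rng2.integers(0, len(idx0), len(idx0))]
            r1 = idx1[rng2.integers(0, len(idx1), len(idx1))]
            take = np.concatenate([r0, r1])
            vals.append(pairwise_auc(labels[take], scores[take]))
        lo2 = np.quantile(vals, alpha / 2)
        hi2 = np.quantile(vals, 1 - alpha / 2)
        assert abs(lo - lo2) < 1e-12 and abs(hi - hi2) < 1e-12

    def test_quantile_nesting(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 30).astype(float)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        wide = bootstrap_ci(roc_auc, labels, scores, B=500, alpha=0.05, seed=1)
        narrow = bootstrap_ci(roc_auc, labels, scores, B=500, alpha=0.5, seed=1)
        assert wide[0] <= narrow[0] <= narrow[1] <= wide[1]

    def test_point_estimates_lie_inside_joint_resample_cis(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 60).astype(float)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.3 + rng.random(60) * 0.7, 0, 1)
        report = evaluate_condition("fixture", labels, scores, threshold=0.5,
                                    B=400, seed=2)
        for metric in ("auc", "sensitivity", "specificity", "accuracy"):
            lo, hi = report.ci[metric]
            assert lo <= getattr(report, metric) <= hi


class TestSubgroups:
    def _images(self):
        meta = [
            ("s1", "lung_cancer", 70, "male", "never"),
            ("s2", "lung_cancer", 50, "female", "ex"),
            ("s3", "lung_cancer", 66, "male", "current"),
            ("s4", "healthy_control", 40, "female", "never"),
            ("s5", "healthy_control", 80, "male", "never"),
            ("s6", "diseased_control", 67, "female", "ex"),
            ("s7", "diseased_control", 59, "male", "never"),
            ("s8", "lung_cancer", 72, "female", "never"),
            ("s9", "healthy_control", 33, "male", "current"),
            ("s10", "diseased_control", 61, "female", "never"),
            ("s11", "lung_cancer", 58, "male", "ex"),
            ("s12", "diseased_control", 77, "female", "never"),
        ]
        return [
            BreathprintImage(sample_id=sid, tensor=np.zeros((14, 16, 16)), label=lab,
                             covariates={"age": age, "sex": sex, "smoking": smoke})
            for sid, lab, age, sex, smoke in meta
        ]

    def test_all_correct_gives_unit_accuracy_everywhere(self):
        images = self._images()
        out = subgroup_accuracy(np.ones(len(images)), images, "sex", B=50, seed=0)
        assert all(v[0] == 1.0 for v in out.values())

    def test_counts_partition_the_samples(self):
        images = self._images()
        for grouping in ("age65", "sex", "smoking_ever", "label_group"):
            out = subgroup_accuracy(np.ones(len(images)), images, grouping, B=10, seed=0)
            assert sum(v[2] for v in out.values()) == len(images)

    def test_hand_computed_fixture(self):
        images = self._images()
        correct = np.array([1, 0, 1, 1, 1, 0, 1, 0, 1, 1, 1, 0], dtype=float)
        out = subgroup_accuracy(correct, images, "age65", B=10, seed=0)
        # by hand: age>=65 -> s1,s3,s5,s6,s8,s12 (correct 1,1,1,0,0,0 = 3/6)
        assert out["age>=65"][0] == pytest.approx(3 / 6)
        assert out["age>=65"][2] == 6
        assert out["age<65"][0] == pytest.approx(5 / 6)
        out = subgroup_accuracy(correct, images, "smoking_ever", B=10, seed=0)
        # ever smokers: s2,s3,s6,s9,s11 -> 0,1,0,1,1 = 3/5
        assert out["ever_smoker"][0] == pytest.approx(3 / 5)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(InvalidArgumentError):
            subgroup_accuracy([1], self._images()[:1], "zodiac_sign")


class TestPCA:
    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(20)
        X = rng.random((5, 6))
        imgs = [np.pad(row, (0, 14 * 256 - 6)).reshape(14, 16, 16) for row in X]
        # feed raw arrays; pca_embed flattens them
        _, frac = pca_embed(imgs)
        Xc = X - X.mean(axis=0)
        padded = np.zeros((5, 14 * 256))
        padded[:, :6] = Xc
        cov = padded.T @ padded / 4
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[:2] / eig.sum()
        np.testing.assert_allclose(frac, expected, atol=1e-10)
        assert frac[0] >= frac[1] >= 0

    def test_centred_planar_data_reproduced_up_to_rotation(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((10, 2))
        X -= X.mean(axis=0)
        imgs = [np.pad(row, (0, 14 * 256 - 2)).reshape(14, 16, 16) for row in X]
        coords, frac = pca_embed(imgs)
        # pairwise distances are preserved by a rigid rotation/reflection
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(coords), pdist(X), atol=1e-8)
        assert frac.sum() == pytest.approx(1.0)

    def test_duplicated_dataset_embeds_identically(self, tiny_images):
        coords, _ = pca_embed(tiny_images + tiny_images)
        n = len(tiny_images)
        np.testing.assert_allclose(coords[:n], coords[n:], atol=1e-8)

    def test_too_few_samples_rejected(self, tiny_images):
        with pytest.raises(InvalidArgumentError):
            pca_embed(tiny_images[:2])
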