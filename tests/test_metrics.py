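"""Evaluation metrics: confusion arithmetic, AUROC, PSNR/SSIM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bruitnet.bruit_synth import BruitParams, generate_bruit
from bruitnet.metrics import (
    compare_feature_types,
    confusion_and_metrics,
    evaluate,
    psnr,
    roc_auc,
    ssim,
)


class TestConfusionAndMetrics:
    def test_published_confusion_counts(self):
        # 240 abnormal (233 caught), 240 normal (238 correctly passed)
        y = np.array([1] * 240 + [0] * 240)
        p = np.array([1] * 233 + [0] * 7 + [0] * 238 + [1] * 2)
        report = confusion_and_metrics(y, p)
        assert (report.tp, report.fn, report.tn, report.fp) == (233, 7, 238, 2)
        assert round(report.precision, 2) == 0.99
        assert round(report.recall, 2) == 0.97
        assert round(report.f1, 2) == 0.98
        assert report.accuracy == pytest.approx(471 / 480)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        report = confusion_and_metrics(y, y)
        assert report.precision == report.recall == report.f1 == report.accuracy == 1.0

    def test_counts_match_brute_force_loop(self, rng):
        y = rng.integers(0, 2, size=20)
        p = rng.integers(0, 2, size=20)
        report = confusion_and_metrics(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (report.tp, report.fp, report.tn, report.fn) == (tp, fp, tn, fn)
        assert report.n == 20

    def test_no_predicted_positives_gives_nan_precision(self):
        report = confusion_and_metrics(np.array([1, 0]), np.array([0, 0]))
        assert np.isnan(report.precision)
        assert np.isnan(report.f1)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_identities(self, seed):
        r = np.random.default_rng(seed)
        y, p = r.integers(0, 2, 15), r.integers(0, 2, 15)
        rep = confusion_and_metrics(y, p)
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 15)
        if not (np.isnan(rep.precision) or np.isnan(rep.recall)) and rep.precision + rep.recall > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics(np.array([1]), np.array([1, 0]))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, fpr, tpr = roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_permuted_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=1000)
        s = rng.random(1000)
        auc, *_ = roc_auc(y, s)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pair_counting_oracle(self, rng):
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        s = rng.random(10)
        s[3] = s[7]  # force a tie
        auc, *_ = roc_auc(y, s)
        pos, neg = s[y == 1], s[y == 0]
        concordant = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auc == pytest.approx(concordant / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        a1, *_ = roc_auc(y, s)
        a2, *_ = roc_auc(y, np.exp(3 * s))
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.random.rand(5))

    def test_evaluate_combines_threshold_and_auroc(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.2, 0.6, 0.5, 0.9])
        report = evaluate(y, s, threshold=0.5)
        assert report.tp == 2 and report.fp == 1  # p >= 0.5 counted abnormal
        assert 0.0 <= report.auroc <= 1.0


class TestPsnr:
    def test_identical_images_infinite(self, rng):
        img = rng.random((8, 8))
        assert psnr(img, img) == np.inf

    def test_uniform_difference_20db(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 0.1)  # MSE = 0.01, MAX = 1
        assert psnr(a, b, max_value=1.0) == pytest.approx(20.0)

    def test_mse_one_is_zero_db(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        assert psnr(a, b, max_value=1.0) == pytest.approx(0.0)

    def test_decreases_with_mse(self, rng):
        a = rng.random((6, 6))
        assert psnr(a, a + 0.05) > psnr(a, a + 0.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        img = rng.random((8, 8))
        assert ssim(img, img) == pytest.approx(1.0)

    def test_equal_constant_images(self):
        a = np.full((5, 5), 0.4)
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        c1, c2 = 0.01**2, 0.03**2
        mx, my = a.mean(), b.mean()
        vx, vy = a.var(), b.var()
        cov = ((a - mx) * (b - my)).mean()
        expected = ((2 * mx * my + c1) * (2 * cov + c2)) / (
            (mx**2 + my**2 + c1) * (vx + vy + c2)
        )
        assert ssim(a, b, max_value=1.0) == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self, rng):
        a, b = rng.random((6, 6)), rng.random((6, 6))
        assert ssim(a, b) == pytest.approx(ssim(b, a))


@pytest.fixture(scope="module")
def small_classes():
    normals = [generate_bruit(BruitParams("normal", separation=0.8, seed=s)) for s in range(3)]
    abnormals = [generate_bruit(BruitParams("abnormal", separation=0.8, seed=50 + s)) for s in range(3)]
    return normals, abnormals


class TestCompareFeatureTypes:
    def test_three_feature_rows(self, small_classes):
        normals, abnormals = small_classes
        table = compare_feature_types(normals, abnormals, n_samples=4, seed=0)
        assert list(table["feature"]) == ["Mel", "MFCC", "Fused"]
        assert (table["n_pairs"] == 4).all()

    def test_self_comparison_identical_members(self, small_classes):
        normals, _ = small_classes
        one = [normals[0]]
        table = compare_feature_types(one, one, n_samples=1, seed=0)
        assert np.isinf(table["psnr"]).all()
        assert np.allclose(table["ssim"], 1.0)

    def test_between_class_ssim_below_within_class(self, small_classes):
        # the fused feature should look more different across classes than
        # within the normal class (averaged over seeded replicates)
        normals, abnormals = small_classes
        across, within = [], []
        for rep in range(3):
            t_across = compare_feature_types(normals, abnormals, 4, seed=rep)
            t_within = compare_feature_types(normals, normals[::-1], 4, seed=rep)
            across.append(float(t_across.loc[t_across.feature == "Fused", "ssim"].iloc[0]))
            within.append(float(t_within.loc[t_within.feature == "Fused", "ssim"].iloc[0]))
        assert np.mean(across) < np.mean(within)

    def test_too_many_pairs_rejected(self, small_classes):
        normals, abnormals = small_classes
        with pytest.raises(ValueError):
            compare_feature_types(normals, abnormals, n_samples=100, seed=0)
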