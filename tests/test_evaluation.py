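"""Classification metrics, bootstrap, McNemar, and explainability metrics."""

import numpy as np
import pytest

from cardialign.evaluation import (apply_band_mask, bootstrap_ci,
                                   classification_metrics, delta_kl_fraction,
                                   mcnemar_test)
from cardialign.priors import clinical_priors
from cardialign.sca import kl_per_sample


class TestClassificationMetrics:
    def test_direct_formulas(self):
        # TP=3, FN=1, TN=5, FP=1
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]
        counts, (acc, sens, spec) = classification_metrics(preds, labels)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (3, 1, 5, 1)
        assert acc == pytest.approx(0.8)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(5 / 6)

    def test_perfect_predictions(self):
        labels = [0, 1, 0, 1]
        _, (acc, sens, spec) = classification_metrics(labels, labels)
        assert acc == sens == spec == 1.0

    def test_matches_counting_loop(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200)
        counts, _ = classification_metrics(preds, labels)
        tp = sum(1 for p, l in zip(preds, labels) if p == 1 and l == 1)
        fn = sum(1 for p, l in zip(preds, labels) if p == 0 and l == 1)
        assert counts.tp == tp and counts.fn == fn

    def test_undefined_sensitivity_is_none(self):
        _, (_, sens, spec) = classification_metrics([0, 0], [0, 0])
        assert sens is None and spec == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            classification_metrics([0, 2], [0, 1])


class TestBootstrap:
    def test_constant_correct_gives_degenerate_ci(self):
        ci, _ = bootstrap_ci([1, 1, 0, 0], [1, 1, 0, 0], n_boot=50, seed=1)
        assert ci["acc"] == (1.0, 1.0)

    def test_single_replicate_collapses(self):
        preds = [1, 0, 1, 0]
        labels = [1, 1, 0, 0]
        ci, _ = bootstrap_ci(preds, labels, n_boot=1, seed=3)
        lo, hi = ci["acc"]
        assert lo == hi

    def test_matches_independent_resampler(self):
        """Same seed protocol, independently coded percentile bootstrap."""
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 20)
        preds = np.where(rng.random(20) < 0.8, labels, 1 - labels)
        ci, _ = bootstrap_ci(preds, labels, n_boot=200, seed=11)
        rng2 = np.random.default_rng(11)
        accs = []
        for _ in range(200):
            idx = rng2.integers(0, 20, 20)
            accs.append(np.mean(preds[idx] == labels[idx]))
        lo, hi = np.percentile(accs, [2.5, 97.5])
        assert ci["acc"] == pytest.approx((lo, hi), abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 50)
        preds = np.where(rng.random(50) < 0.7, labels, 1 - labels)
        ci, _ = bootstrap_ci(preds, labels, n_boot=500, seed=2)
        _, (acc, sens, spec) = classification_metrics(preds, labels)
        assert ci["acc"][0] <= acc <= ci["acc"][1]
        assert ci["sens"][0] <= sens <= ci["sens"][1]


class TestMcNemar:
    def test_no_discordance(self):
        p, (b, c) = mcnemar_test([1, 0], [1, 0], [1, 0])
        assert p == 1.0 and b == c == 0

    def test_exact_binomial_hand_value(self):
        """b=2, c=8 discordant pairs: p = 2 * sum_{k<=2} C(10,k) / 2^10."""
        labels = np.zeros(20, dtype=int)
        preds_a = np.zeros(20, dtype=int)
        preds_b = np.zeros(20, dtype=int)
        preds_b[:2] = 1   # a right, b wrong on 2
        preds_a[2:10] = 1  # a wrong, b right on 8
        p, (b, c) = mcnemar_test(preds_a, preds_b, labels)
        assert (b, c) == (2, 8)
        assert p == pytest.approx(112 / 1024, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        pa = np.where(rng.random(60) < 0.8, labels, 1 - labels)
        pb = np.where(rng.random(60) < 0.7, labels, 1 - labels)
        p1, _ = mcnemar_test(pa, pb, labels)
        p2, _ = mcnemar_test(pb, pa, labels)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_large_sample_uses_chi_square(self):
        labels = np.zeros(200, dtype=int)
        pa = np.zeros(200, dtype=int)
        pb = np.zeros(200, dtype=int)
        pa[:40] = 1
        pb[40:55] = 1  # b=15, c=40 -> chi-square branch
        p_chi, _ = mcnemar_test(pa, pb, labels)
        from scipy.stats import chi2
        expected = chi2.sf((abs(15 - 40) - 1) ** 2 / (15 + 40), 1)
        assert p_chi == pytest.approx(expected, rel=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            mcnemar_test([0, 1], [0], [0, 1])


class TestExplanationValues:
    def test_cross_class_prior_hand_value(self):
        """KL of the normal-shaped mass against the abnormal prior ~ 0.805."""
        p = np.array([[0.7, 0.2, 0.1, 0.0]])
        pi = clinical_priors().pi1[None, :]
        hand = (0.7 * np.log(0.7 / 0.15) + 0.2 * np.log(0.2 / 0.35)
                + 0.1 * np.log(0.1 / 0.5))
        assert hand == pytest.approx(0.805, abs=5e-4)
        assert kl_per_sample(p, pi)[0] == pytest.approx(hand, abs=1e-6)

    def test_uniform_cosine_is_one(self):
        from cardialign.evaluation import _cosine_rows
        assert _cosine_rows(np.full((1, 4), 0.25),
                            np.full((1, 4), 0.25))[0] == pytest.approx(1.0)


class TestDeltaKL:
    def test_strict_improvement_everywhere(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        model = base - 0.5
        out = delta_kl_fraction(base, model, [0, 0, 1, 1])
        assert out == {"normal": 100.0, "abnormal": 100.0}

    def test_identical_vectors_give_zero(self):
        base = np.ones(4)
        out = delta_kl_fraction(base, base, [0, 1, 0, 1])
        assert out == {"normal": 0.0, "abnormal": 0.0}

    def test_matches_counting_loop(self):
        rng = np.random.default_rng(3)
        base = rng.random(40)
        model = rng.random(40)
        labels = rng.integers(0, 2, 40)
        out = delta_kl_fraction(base, model, labels)
        for name, lbl in (("normal", 0), ("abnormal", 1)):
            cnt = sum(1 for i in range(40)
                      if labels[i] == lbl and base[i] - model[i] > 0)
            tot = np.sum(labels == lbl)
            assert out[name] == pytest.approx(100 * cnt / tot)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share the sample set"):
            delta_kl_fraction([1.0], [1.0, 2.0], [0, 1])


class TestBatchInvariance:
    def test_explanation_metrics_independent_of_batch_size(self):
        """Per-sample KL/cosine identical however the data are batched."""
        from cardialign.backbones import BackboneSpec, build_backbone
        from cardialign.evaluation import explanation_metrics
        from cardialign.features import Spectrogram
        from cardialign.priors import make_band_partition

        rng = np.random.default_rng(4)
        # varied lengths: batching then changes each sample's zero padding
        data = [(Spectrogram(np.abs(rng.normal(size=(5 + i, 128))) + 0.1),
                 i % 2) for i in range(7)]
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=1))
        part = make_band_partition(128, 4)
        table = clinical_priors()
        a = explanation_metrics(model, data, table, part, batch_size=7)
        b = explanation_metrics(model, data, table, part, batch_size=2)
        np.testing.assert_allclose(a["kl"], b["kl"], atol=1e-12)
        np.testing.assert_allclose(a["cos"], b["cos"], atol=1e-12)


class TestBandMask:
    def test_none_is_identity(self):
        X = np.random.default_rng(0).normal(size=(2, 1, 5, 128))
        assert apply_band_mask(X, "none") is X

    def test_masks_are_complementary(self):
        X = np.random.default_rng(1).normal(size=(2, 1, 5, 128))
        low = apply_band_mask(X, "low_band")
        high = apply_band_mask(X, "high_band")
        np.testing.assert_array_equal(low + high, X)
        assert np.all(low[..., 64:] == 0)
        assert np.all(high[..., :64] == 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mask mode"):
            apply_band_mask(np.zeros((1, 1, 2, 128)), "mid_band")
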