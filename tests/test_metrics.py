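import math

import numpy as np
import pytest

from octga import metrics as mx

from .oracles import confusion_by_loop, icc2_by_anova, pearson_by_formula, roc_by_sweep


class TestPixelConfusion:
    def test_perfect_agreement(self, rng):
        truth = np.zeros(100, bool)
        truth[:10] = True
        c = mx.pixel_confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_all_negative_prediction(self):
        truth = np.zeros(100, bool)
        truth[:10] = True
        c = mx.pixel_confusion(np.zeros(100, bool), truth)
        assert (c.fn, c.tn, c.tp, c.fp) == (10, 90, 0, 0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            p = rng.random((13, 7)) < 0.4
            t = rng.random((13, 7)) < 0.4
            c = mx.pixel_confusion(p, t)
            assert (c.tp, c.fp, c.fn, c.tn) == confusion_by_loop(p, t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mx.pixel_confusion(np.zeros((2, 2), bool), np.zeros((2, 3), bool))


class TestSummaryMetrics:
    def test_hand_computed_example(self):
        rep = mx.summary_metrics(mx.ConfusionCounts(tp=8, fp=2, fn=2, tn=88))
        assert rep.precision == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.f_score == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.96)
        assert rep.specificity == pytest.approx(88 / 90)

    def test_perfect_prediction_all_ones(self):
        rep = mx.summary_metrics(mx.ConfusionCounts(tp=5, fp=0, fn=0, tn=15))
        assert (
            rep.accuracy == rep.sensitivity == rep.specificity == rep.precision == rep.f_score == 1.0
        )

    def test_no_predictions_flags_precision_and_f_zero(self):
        rep = mx.summary_metrics(mx.ConfusionCounts(tp=0, fp=0, fn=7, tn=93))
        assert math.isnan(rep.precision) and "precision" in rep.undefined
        assert rep.f_score == 0.0

    def test_accuracy_is_prevalence_weighted_combination(self, rng):
        for _ in range(10):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 50, 4))
            rep = mx.summary_metrics(mx.ConfusionCounts(tp, fp, fn, tn))
            prev = (tp + fn) / (tp + fp + fn + tn)
            assert rep.accuracy == pytest.approx(
                prev * rep.sensitivity + (1 - prev) * rep.specificity
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mx.summary_metrics(mx.ConfusionCounts(0, 0, 0, 0))


class TestDetectionEval:
    def test_all_agree(self):
        pairs = [(True, True)] * 3 + [(False, False)] * 5
        _, rep = mx.detection_eval(pairs)
        assert rep.accuracy == 1.0

    def test_table_style_counts(self):
        # 86 of 100 positive volumes detected, 94 of 100 negatives rejected
        pairs = (
            [(True, True)] * 86 + [(False, True)] * 14 + [(False, False)] * 94 + [(True, False)] * 6
        )
        counts, rep = mx.detection_eval(pairs)
        assert rep.sensitivity == pytest.approx(0.86)
        assert rep.specificity == pytest.approx(0.94)

    def test_swapping_swaps_fp_fn(self, rng):
        pairs = [(bool(a), bool(b)) for a, b in rng.integers(0, 2, (30, 2))]
        c1, _ = mx.detection_eval(pairs)
        c2, _ = mx.detection_eval([(t, p) for p, t in pairs])
        assert (c1.fp, c1.fn) == (c2.fn, c2.fp)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.detection_eval([])


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert mx.pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert mx.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        r, p = mx.pearson(x, y)
        r0, p0 = pearson_by_formula(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            mx.pearson(np.ones(5), np.arange(5.0))


class TestICC:
    def test_identical_vectors_give_one(self, rng):
        x = rng.random(8)
        rep = mx.icc_agreement(x, x.copy())
        assert rep.icc == 1.0
        assert rep.icc_ci_low <= rep.icc <= rep.icc_ci_high

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        rep = mx.icc_agreement(x, y)
        assert abs(rep.icc) < 0.2

    def test_matches_anova_oracle(self, rng):
        x = rng.random(8) * 10
        y = x + rng.normal(0, 1, 8)
        rep = mx.icc_agreement(x, y)
        assert rep.icc == pytest.approx(icc2_by_anova(x, y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import warnings

        import pandas as pd
        import pingouin as pg

        x = rng.random(15) * 5
        y = x + rng.normal(0, 0.8, 15)
        rep = mx.icc_agreement(x, y)
        df = pd.DataFrame(
            {
                "t": np.tile(np.arange(15), 2),
                "r": np.repeat(["a", "b"], 15),
                "s": np.concatenate([x, y]),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.intraclass_corr(df, targets="t", raters="r", ratings="s").set_index("Type")
        assert rep.icc == pytest.approx(float(table.loc["ICC(A,1)", "ICC"]), abs=1e-10)
        lo, hi = table.loc["ICC(A,1)", "CI95"]
        assert rep.icc_ci_low == pytest.approx(lo, abs=0.005)
        assert rep.icc_ci_high == pytest.approx(hi, abs=0.005)

    def test_approaches_pearson_for_equal_mean_and_variance(self, rng):
        # a permutation of x shares its mean and variance exactly; the
        # ANOVA estimator then matches Pearson r up to O(1/n) finite-sample bias
        x = rng.normal(size=1000)
        y = rng.permutation(x)
        rep = mx.icc_agreement(x, y)
        assert rep.icc == pytest.approx(rep.pearson_r, abs=0.01)

    def test_ci_brackets_icc(self, rng):
        for _ in range(5):
            x = rng.random(12)
            y = x + rng.normal(0, 0.3, 12)
            rep = mx.icc_agreement(x, y)
            assert rep.icc_ci_low <= rep.icc <= rep.icc_ci_high
            assert rep.icc <= 1.0

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            mx.icc_agreement(rng.random(3), rng.random(3))


class TestROC:
    def test_perfectly_informative_confidences(self):
        truth = np.zeros((10, 10), bool)
        truth[:3] = True
        curve = mx.roc([truth.astype(float)], [truth])
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_confidences_near_half(self, rng):
        truth = rng.random((100, 100)) < 0.3
        conf = rng.random((100, 100))
        curve = mx.roc([conf], [truth])
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariant(self, rng):
        truth = rng.random(500) < 0.4
        conf = rng.random(500)
        a1 = mx.roc([conf], [truth]).auc
        a2 = mx.roc([conf**3], [truth]).auc  # strictly monotone on [0,1]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sweep_oracle(self, rng):
        truth = rng.random(200) < 0.35
        conf = np.round(rng.random(200), 2)  # force ties
        curve = mx.roc([conf], [truth])
        fpr0, tpr0, auc0 = roc_by_sweep(conf, truth)
        assert curve.auc == pytest.approx(auc0, abs=1e-10)
        mine = set(zip(np.round(curve.fpr, 12), np.round(curve.tpr, 12)))
        assert {(round(f, 12), round(t, 12)) for f, t in zip(fpr0, tpr0)} <= mine

    def test_endpoints_and_monotonicity(self, rng):
        truth = rng.random(300) < 0.5
        conf = np.clip(truth + rng.normal(0, 0.7, 300), 0, 1)
        curve = mx.roc([conf], [truth])
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            mx.roc([np.random.rand(10)], [np.zeros(10, bool)])


class TestDice:
    def test_dice_identities(self, rng):
        a = rng.random((8, 8)) < 0.4
        assert mx.dice(a, a) == 1.0
        assert mx.dice(np.zeros_like(a), np.zeros_like(a)) == 1.0
        if a.any():
            assert mx.dice(np.zeros_like(a), a) == 0.0
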