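"""ROC/AUC, DeLong, bootstrap, predictive values, LOOCV mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import deltarad as dr
from deltarad.evaluation import (
    ConfusionMatrix,
    confusion_from_predictions,
    delong_ci,
    report_table,
)

#: printed summary-performance rows (sensitivity, specificity, PPV, NPV in
#: percent) for the four methods, with 27 positives and 38 negatives
PRINTED_PERFORMANCE = {
    "precise": (74.1, 94.7, 90.9, 83.7),
    "parenclitic": (85.2, 73.7, 69.7, 87.5),
    "lasso": (70.4, 84.2, 76.0, 80.0),
    "rf": (92.6, 65.8, 65.8, 92.6),
}
N_POS, N_NEG = 27, 38


def pairwise_auc_oracle(scores, labels):
    """Exhaustive comparison of every (positive, negative) pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_and_tied(self):
        y = np.array([0, 0, 1, 1])
        assert dr.roc_auc(y.astype(float), y) == 1.0
        assert dr.roc_auc(np.ones(4), y) == 0.5

    def test_four_pair_enumeration(self):
        """(0,0,1,1) vs (0.1, 0.4, 0.35, 0.8): 3 of 4 pairs concordant."""
        assert dr.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 31))
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        r.shuffle(labels)
        scores = np.round(r.normal(size=n), 1)  # coarse -> many ties
        assert dr.roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        assert dr.roc_auc(scores, labels) == pytest.approx(
            dr.roc_auc(np.exp(scores), labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dr.roc_auc([0.1, 0.2], [1, 1])


def swap_permutation_p(a, b, labels, n_perm=20_000, seed=0):
    """Paired permutation oracle: swap the two methods' scores per sample
    with probability 1/2 and recompute the |AUC difference|."""
    rng = np.random.default_rng(seed)
    obs = abs(dr.roc_auc(a, labels) - dr.roc_auc(b, labels))
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(dr.roc_auc(aa, labels) - dr.roc_auc(bb, labels)) >= obs - 1e-12:
            count += 1
    return count / n_perm


class TestDeLong:
    def test_identical_scores_p_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.2, 0.8, 0.3, 0.7, 0.6, 0.1])
        res = dr.delong_test(s, s, y)
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_ci_contains_auc_and_shrinks_with_n(self):
        widths = {}
        for n in (40, 160):
            r = np.random.default_rng(7)
            y = np.repeat([0, 1], n // 2)
            s = r.normal(size=n) + y  # fixed separation
            auc, (lo, hi) = delong_ci(s, y)
            assert lo <= auc <= hi
            widths[n] = hi - lo
        assert widths[160] < widths[40]

    def test_p_close_to_permutation_oracle(self):
        """n=20 toy set: DeLong p within 0.05 of a 20,000-replicate paired
        permutation oracle."""
        r = np.random.default_rng(3)
        y = np.repeat([0, 1], 10)
        a = r.normal(size=20) + 1.2 * y
        b = r.normal(size=20) + 0.5 * y
        p_delong = dr.delong_test(a, b, y)["p"]
        p_perm = swap_permutation_p(a, b, y)
        assert abs(p_delong - p_perm) <= 0.05

    def test_null_p_values_uniform(self):
        """Under the null (independent noise scores) DeLong p-values are
        approximately U(0,1): KS statistic <= 0.1 over 500 replicates."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            y = np.repeat([0, 1], 20)
            a, b = rng.normal(size=40), rng.normal(size=40)
            pvals.append(dr.delong_test(a, b, y)["p"])
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks <= 0.1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            dr.delong_test([0.1, 0.2], [0.1], [0, 1])


class TestBootstrap:
    def test_perfect_classifier_degenerate_ci(self):
        y = np.repeat([0, 1], 10)
        res = dr.bootstrap_sens_spec(y, y, seed=0)
        assert res["sensitivity_ci"] == (1.0, 1.0)
        assert res["specificity_ci"] == (1.0, 1.0)

    def test_seeded_determinism(self):
        r = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        pred = r.integers(0, 2, 40)
        a = dr.bootstrap_sens_spec(pred, y, seed=5)
        b = dr.bootstrap_sens_spec(pred, y, seed=5)
        assert a == b

    @pytest.mark.parametrize("seed", range(20))
    def test_ci_contains_point_estimate(self, seed):
        r = np.random.default_rng(seed)
        y = np.repeat([0, 1], [15, 12])
        pred = r.integers(0, 2, 27)
        res = dr.bootstrap_sens_spec(pred, y, n_boot=500, seed=seed)
        lo, hi = res["sensitivity_ci"]
        assert lo - 1e-12 <= res["sensitivity"] <= hi + 1e-12
        lo, hi = res["specificity_ci"]
        assert lo - 1e-12 <= res["specificity"] <= hi + 1e-12

    def test_coverage_on_binomial_simulation(self):
        """Percentile intervals cover the true sensitivity >= 90% of the
        time (nominal 95%) on a 65-sample binomial simulation."""
        rng = np.random.default_rng(42)
        true_sens, true_spec = 0.8, 0.7
        y = np.repeat([1, 0], [27, 38])
        hits = 0
        reps = 500
        for i in range(reps):
            pred = np.where(
                y == 1,
                rng.random(65) < true_sens,
                rng.random(65) < 1 - true_spec,
            ).astype(int)
            res = dr.bootstrap_sens_spec(pred, y, n_boot=2000, seed=i)
            lo, hi = res["sensitivity_ci"]
            hits += lo <= true_sens <= hi
        assert hits / reps >= 0.90


class TestPredictiveValues:
    def test_printed_ppv_cell(self):
        out = dr.predictive_values(ConfusionMatrix(tp=20, fp=2, fn=7, tn=36))
        assert 100 * out["ppv"] == pytest.approx(90.9, abs=0.05)

    def test_printed_npv_cell(self):
        out = dr.predictive_values(ConfusionMatrix(tp=25, fp=13, fn=2, tn=25))
        assert 100 * out["npv"] == pytest.approx(92.6, abs=0.05)

    def test_perfect_matrix(self):
        out = dr.predictive_values(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        assert out["ppv"] == 1.0 and out["npv"] == 1.0
        assert out["ppv_ci"] == (1.0, 1.0)

    def test_ci_clipped_to_unit_interval(self):
        out = dr.predictive_values(ConfusionMatrix(tp=19, fp=1, fn=0, tn=0))
        assert 0.0 <= out["ppv_ci"][0] and out["ppv_ci"][1] <= 1.0

    def test_empty_denominator_undefined(self):
        out = dr.predictive_values(ConfusionMatrix(tp=0, fp=0, fn=3, tn=5))
        assert np.isnan(out["ppv"])


class TestReconstructConfusion:
    def test_sensitivity_cell(self):
        cm = dr.reconstruct_confusion(74.1, 94.7, N_POS, N_NEG)
        assert cm.tp == 20 and cm.tn == 36
        assert cm.fn == 7 and cm.fp == 2

    def test_boundary_cell(self):
        cm = dr.reconstruct_confusion(100.0, 50.0, 10, 2)
        assert cm.tp == 10 and cm.tn == 1

    def test_inconsistent_value_rejected(self):
        with pytest.raises(ValueError, match="consistent"):
            dr.reconstruct_confusion(50.0, 50.0, 3, 2)

    @pytest.mark.parametrize("method", sorted(PRINTED_PERFORMANCE))
    def test_printed_table_round_trip(self, method):
        """Printed PPV/NPV follow from printed sensitivity/specificity via
        the reconstructed integer confusion matrix, for every method."""
        sens, spec, ppv, npv = PRINTED_PERFORMANCE[method]
        cm = dr.reconstruct_confusion(sens, spec, N_POS, N_NEG)
        out = dr.predictive_values(cm)
        assert 100 * out["ppv"] == pytest.approx(ppv, abs=0.05)
        assert 100 * out["npv"] == pytest.approx(npv, abs=0.05)


class TestDichotomisation:
    @pytest.mark.parametrize("score,expected",
                             [(1, 0), (2, 0), (3, 0), (4, 1), (5, 1)])
    def test_cutoff_at_four(self, score, expected):
        assert dr.dichotomise_precise(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dr.dichotomise_precise(0)
        with pytest.raises(ValueError):
            dr.dichotomise_precise(6)
        with pytest.raises(ValueError):
            dr.dichotomise_precise(3.5)


class _PrevalenceModel:
    """Predicts its training prevalence for every sample."""

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.p_)
        return np.column_stack([1 - p, p])

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


class TestLoocv:
    def test_prediction_count(self):
        r = np.random.default_rng(0)
        X = r.normal(size=(64, 3))
        y = np.repeat([0, 1], 32)
        probs = dr.loocv(X, y, _PrevalenceModel())
        assert len(probs) == 64

    def test_constant_features_prevalence(self):
        X = np.zeros((10, 2))
        y = np.repeat([0, 1], 5)
        probs = dr.loocv(X, y, _PrevalenceModel())
        # each fold sees 9 samples; prevalence depends on held-out class
        assert probs[0] == pytest.approx(5 / 9)
        assert probs[-1] == pytest.approx(4 / 9)

    def test_heldout_label_flip_leaves_own_prediction_unchanged(self):
        """Leakage oracle: the held-out label must not influence its own
        prediction; a training label must."""
        from deltarad.modeling import make_rf
        r = np.random.default_rng(1)
        X = r.normal(size=(14, 3)) + np.repeat([0, 1], 7)[:, None]
        y = np.repeat([0, 1], 7)
        base = dr.loocv(X, y, make_rf())
        y_flip_own = y.copy()
        y_flip_own[0] = 1 - y_flip_own[0]
        flipped = dr.loocv(X, y_flip_own, make_rf())
        assert flipped[0] == pytest.approx(base[0])
        assert not np.allclose(np.delete(flipped, 0), np.delete(base, 0))

    def test_single_class_fold_rejected(self):
        X = np.zeros((4, 2))
        y = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError, match="single class"):
            dr.loocv(X, y, _PrevalenceModel())


class TestEvaluateReport:
    def test_report_structure_and_ranges(self):
        r = np.random.default_rng(9)
        y = np.repeat([0, 1], [20, 15])
        preds = {
            "a": np.clip(r.normal(0.5, 0.2, 35) + 0.2 * y, 0, 1),
            "b": r.random(35),
        }
        rep = dr.evaluate_predictions(preds, y, n_boot=200, seed=0)
        assert set(rep["methods"]) == {"a", "b"}
        for m in rep["methods"].values():
            assert 0 <= m["auc"] <= 1
            assert m["auc_ci"][0] <= m["auc"] <= m["auc_ci"][1]
            for key in ("sensitivity", "specificity", "ppv", "npv"):
                assert 0 <= m[key] <= 1 or np.isnan(m[key])
        assert len(rep["delong_comparisons"]) == 1
        tab = report_table(rep)
        assert list(tab.index) == ["a", "b"]
        assert (tab["auc"] <= 100).all()

    def test_confusion_from_predictions(self):
        cm = confusion_from_predictions([1, 1, 0, 0], [1, 0, 1, 0])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)
        assert cm.sensitivity == 0.5 and cm.specificity == 0.5
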