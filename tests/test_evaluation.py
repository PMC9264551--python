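import numpy as np
import pytest
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from bbbuq.evaluation import (
    ConfusionCounts,
    DEFAULT_FRACTIONS,
    bin_summary,
    classification_metrics,
    compare_runs,
    confusion_counts,
    mcc_from_counts,
    retention_curve,
    stratified_folds,
    threshold_summary,
)
from bbbuq.exceptions import (
    EmptyAfterFilter,
    LengthMismatch,
    MissingProbabilities,
    NonMonotoneEdges,
)
from bbbuq.uncertainty import random_uncertainty


class TestConfusionCounts:
    def test_perfect(self):
        y = [1] * 5 + [0] * 5
        c = confusion_counts(y, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_all_predicted_positive(self):
        c = confusion_counts([1, 1, 1, 0, 0], [1] * 5)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 0, 0)

    def test_substrate_panel_retally(self):
        """Re-tallying a 27-molecule panel with 10 TP / 3 FN / 1 FP / 13 TN
        outcomes reproduces the counts."""
        y = [1] * 13 + [0] * 14
        yhat = [1] * 10 + [0] * 3 + [1] * 1 + [0] * 13
        c = confusion_counts(y, yhat)
        assert (c.tp, c.fn, c.fp, c.tn) == (10, 3, 1, 13)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            confusion_counts([1, 0], [1])


class TestClassificationMetrics:
    def test_substrate_panel_values(self):
        m = classification_metrics(ConfusionCounts(tp=10, fn=3, fp=1, tn=13))
        assert m.mcc == pytest.approx(0.7096, abs=1e-3)
        assert m.bacc == pytest.approx(0.8489, abs=1e-3)

    def test_degenerate_all_zero(self):
        m = classification_metrics(ConfusionCounts(0, 0, 0, 0))
        assert m.mcc == 0.0  # zero-denominator convention

    def test_perfect_ranking_auc(self):
        y = [0, 0, 1, 1]
        p = [0.1, 0.2, 0.8, 0.9]
        m = classification_metrics(confusion_counts(y, [0, 0, 1, 1]), labels=y, probabilities=p)
        assert m.roc_auc == 1.0 and m.prc_auc == 1.0

    def test_auc_requires_both_inputs(self):
        with pytest.raises(MissingProbabilities):
            classification_metrics(ConfusionCounts(1, 1, 1, 1), labels=[1, 0])

    def test_agrees_with_sklearn_on_random_tables(self):
        """From-scratch formulas match the independent library implementation
        on 1000 random label/prediction pairs, degenerate tables included."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, size=n)
            yhat = rng.integers(0, 2, size=n)
            c = confusion_counts(y, yhat)
            m = classification_metrics(c)
            assert m.mcc == pytest.approx(matthews_corrcoef(y, yhat), abs=1e-12)
            if len(np.unique(y)) == 2:
                assert m.bacc == pytest.approx(balanced_accuracy_score(y, yhat), abs=1e-12)
            assert m.recall == pytest.approx(
                recall_score(y, yhat, zero_division=0), abs=1e-12
            )
            assert m.precision == pytest.approx(
                precision_score(y, yhat, zero_division=0), abs=1e-12
            )
            cm = confusion_matrix(y, yhat, labels=[0, 1])
            fp, tn = cm[0, 1], cm[0, 0]
            expected_fpr = fp / (fp + tn) if (fp + tn) else 0.0
            assert m.fpr == pytest.approx(expected_fpr, abs=1e-12)


def _brute_force_curve(y, yhat, u, fractions):
    """Independent re-implementation: explicit sort/slice/MCC/trapezoid."""
    order = sorted(range(len(u)), key=lambda i: (u[i], i))
    fr = sorted({float(f) for f in fractions}, reverse=True)
    mccs = []
    for f in fr:
        k = int(np.ceil(f * len(y)))
        keep = order[:k]
        ys = [y[i] for i in keep]
        ps = [yhat[i] for i in keep]
        tp = sum(1 for a, b in zip(ys, ps) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(ys, ps) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(ys, ps) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(ys, ps) if a == 1 and b == 0)
        if fp + fn == 0:
            mccs.append(1.0)
        else:
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mccs.append((tp * tn - fp * fn) / np.sqrt(den) if den else 0.0)
    xs = fr[::-1]
    area = np.trapezoid(mccs[::-1], x=xs)
    return fr, mccs, area / (xs[-1] - xs[0])


class TestRetentionCurve:
    def test_full_fraction_equals_global_mcc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=100)
        yhat = np.where(rng.random(100) < 0.8, y, 1 - y)
        u = rng.random(100)
        curve = retention_curve(y, yhat, u)
        assert curve.fractions[0] == 1.0
        assert curve.mcc_at[0] == pytest.approx(mcc_from_counts(confusion_counts(y, yhat)))
        assert curve.mcc_auc <= curve.mcc_at.max() + 1e-12

    def test_all_correct_gives_unit_auc(self):
        y = [1, 0] * 10
        curve = retention_curve(y, y, np.linspace(0, 1, 20))
        assert np.all(curve.mcc_at == 1.0)
        assert curve.mcc_auc == 1.0

    def test_errors_at_highest_uncertainty_nondecreasing(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 20)
        yhat = y.copy()
        err = rng.choice(50, size=8, replace=False)
        yhat[err] = 1 - yhat[err]
        u = rng.random(50) * 0.5
        u[err] = 0.5 + rng.random(8) * 0.5  # every error ranks above every success
        curve = retention_curve(y, yhat, u)
        assert np.all(np.diff(curve.mcc_at) >= -1e-12)  # nondecreasing as f shrinks

    def test_matches_brute_force_single_top_error(self):
        """n=10, one error carrying the single highest uncertainty: curve and
        area equal an independent enumeration of all ten filtered subsets."""
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        yhat = y.copy()
        yhat[3] = 1 - yhat[3]
        u = np.array([0.1, 0.2, 0.3, 0.95, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        curve = retention_curve(y, yhat, u)
        fr, mccs, auc = _brute_force_curve(list(y), list(yhat), list(u), DEFAULT_FRACTIONS)
        assert np.allclose(curve.fractions, fr)
        assert np.allclose(curve.mcc_at, mccs)
        assert curve.mcc_auc == pytest.approx(auc)

    def test_matches_brute_force_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, size=n)
            yhat = np.where(rng.random(n) < 0.75, y, 1 - y)
            u = np.round(rng.random(n), 2)  # coarse grid exercises ties
            curve = retention_curve(y, yhat, u)
            _, mccs, auc = _brute_force_curve(list(y), list(yhat), list(u), DEFAULT_FRACTIONS)
            assert np.allclose(curve.mcc_at, mccs)
            assert curve.mcc_auc == pytest.approx(auc)

    def test_random_uncertainty_curve_is_flat(self):
        """Over 200 random scorers on a fixed prediction set, the mean
        deviation of MCC(f) from MCC(1.0) is within 3 MC standard errors."""
        rng = np.random.default_rng(4)
        n = 400
        y = rng.integers(0, 2, size=n)
        yhat = np.where(rng.random(n) < 0.8, y, 1 - y)
        base = mcc_from_counts(confusion_counts(y, yhat))
        deviations = []
        for seed in range(200):
            u = random_uncertainty(n, seed=seed)
            deviations.append(retention_curve(y, yhat, u).mcc_at - base)
        dev = np.asarray(deviations)
        mean = dev.mean(axis=0)
        se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
        assert np.all(np.abs(mean) <= 3 * np.maximum(se, 1e-12))

    def test_empty_after_filter(self):
        with pytest.raises(EmptyAfterFilter):
            retention_curve([], [], [], fractions=[0.5])


class TestBinSummary:
    def test_single_populated_bin(self):
        y = [1] * 8
        bs = bin_summary(y, y, [0.05] * 8)
        assert bs.totals[0] == 8 and bs.totals[1:].sum() == 0
        assert bs.percentages["tp"][0] == 100.0

    def test_totals_conserved(self):
        rng = np.random.default_rng(5)
        n = 1000
        y = rng.integers(0, 2, size=n)
        yhat = rng.integers(0, 2, size=n)
        bs = bin_summary(y, yhat, rng.random(n))
        assert bs.totals.sum() == n
        pct = sum(bs.percentages[k] for k in ("tp", "tn", "fp", "fn"))
        assert np.all(np.abs(pct[bs.totals > 0] - 100.0) < 0.01)

    def test_last_bin_closed(self):
        bs = bin_summary([1], [1], [1.0])
        assert bs.totals[-1] == 1

    def test_non_monotone_edges(self):
        with pytest.raises(NonMonotoneEdges):
            bin_summary([1], [1], [0.5], edges=[0.0, 0.5, 0.5, 1.0])


class TestThresholdSummary:
    def test_whole_set_and_empty_set(self):
        y = [1, 1, 0, 0]
        yhat = [1, 0, 0, 1]
        n, err, rate = threshold_summary(y, yhat, [0.1, 0.2, 0.3, 0.4], cut=1.0)
        assert (n, err, rate) == (4, 2, 0.5)
        n, err, rate = threshold_summary(y, yhat, [0.6, 0.7, 0.8, 0.9], cut=0.5)
        assert (n, err, rate) == (0, 0, None)

    def test_low_uncertainty_subset_rate(self):
        """408 sub-threshold predictions with 22 errors give a 5.39% rate."""
        n_total, n_below, n_err = 600, 408, 22
        u = np.concatenate([np.full(n_below, 0.2), np.full(n_total - n_below, 0.8)])
        y = np.ones(n_total, dtype=int)
        yhat = y.copy()
        yhat[:n_err] = 0  # errors inside the confident subset
        n, err, rate = threshold_summary(y, yhat, u, cut=0.5)
        assert (n, err) == (408, 22)
        assert rate * 100 == pytest.approx(5.39, abs=0.01)


class TestPermutationInvariance:
    def test_metrics_curves_bins_unchanged(self):
        rng = np.random.default_rng(6)
        n = 200
        y = rng.integers(0, 2, size=n)
        yhat = np.where(rng.random(n) < 0.8, y, 1 - y)
        u = rng.random(n)
        perm = rng.permutation(n)
        c1, c2 = confusion_counts(y, yhat), confusion_counts(y[perm], yhat[perm])
        assert (c1.tp, c1.tn, c1.fp, c1.fn) == (c2.tp, c2.tn, c2.fp, c2.fn)
        r1 = retention_curve(y, yhat, u)
        r2 = retention_curve(y[perm], yhat[perm], u[perm])
        assert np.allclose(r1.mcc_at, r2.mcc_at) and r1.mcc_auc == pytest.approx(r2.mcc_auc)
        b1 = bin_summary(y, yhat, u)
        b2 = bin_summary(y[perm], yhat[perm], u[perm])
        assert np.array_equal(b1.totals, b2.totals)
        for k in ("tp", "tn", "fp", "fn"):
            assert np.array_equal(b1.counts[k], b2.counts[k])


class TestUtilities:
    def test_compare_runs(self):
        t, p = compare_runs([0.8, 0.82, 0.81], [0.6, 0.61, 0.59])
        assert t > 0 and p < 0.01

    def test_stratified_folds(self):
        y = np.array([1] * 30 + [0] * 12)
        folds = stratified_folds(y, k=3, seed=0)
        assert len(folds) == 3
        for tr, te in folds:
            assert 0.6 < y[tr].mean() < 0.8  # stratification keeps the imbalance
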