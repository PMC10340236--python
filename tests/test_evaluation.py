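import warnings

import numpy as np
import pytest

import oracles
from gastromut import evaluation as E
from gastromut.errors import ConfigurationError, UndefinedMetricError, ValidationError
from gastromut.models import ModelSpec, TrainingConfig


class TestMakeSplit:
    def test_sct_uses_everything(self):
        [(train, test)] = E.make_split(10, [0, 1] * 5, E.SplitPlan("SCT"))
        assert len(train) == len(test) == 10

    def test_ist_stratified_80_20(self):
        labels = np.array([0] * 50 + [1] * 50)
        [(train, test)] = E.make_split(100, labels, E.SplitPlan("IST", seed=1))
        assert len(train) == 80 and len(test) == 20
        assert labels[test].sum() == 10  # 10 of each class in the test set
        assert set(train) | set(test) == set(range(100))
        assert set(train) & set(test) == set()

    def test_kfold_partition(self):
        labels = np.array([0, 1] * 50)
        folds = E.make_split(100, labels, E.SplitPlan("KFOLD", k=10, seed=0))
        assert len(folds) == 10
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(100))
        for _, te in folds:
            assert len(te) == 10

    def test_too_small_class_rejected(self):
        with pytest.raises(ConfigurationError):
            E.make_split(12, [0] * 11 + [1], E.SplitPlan("KFOLD", k=10))

    def test_partition_and_stratification_properties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(40, 200))
            ratio = rng.uniform(0.3, 0.7)
            labels = (rng.random(n) < ratio).astype(int)
            if min(np.bincount(labels, minlength=2)) < 10:
                continue
            plan = E.SplitPlan("KFOLD", k=5, seed=int(rng.integers(1000)))
            folds = E.make_split(n, labels, plan)
            all_test = np.concatenate([te for _, te in folds])
            assert sorted(all_test) == list(range(n))
            class_ratio = labels.mean()
            for tr, te in folds:
                assert set(tr) & set(te) == set()
                # stratification: fold class count within 1 of the ideal
                ideal = class_ratio * len(te)
                assert abs(labels[te].sum() - ideal) <= 1 + 1e-9


class TestConfusion:
    def test_perfect_agreement(self):
        y = [1] * 5 + [0] * 5
        c = E.confusion(y, y)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        c = E.confusion(y, p)
        f = E.confusion(y, 1 - p)
        assert (c.TP, c.TN, c.FP, c.FN) == (f.FN, f.FP, f.TN, f.TP)

    def test_empty(self):
        c = E.confusion([], [])
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            E.confusion([1, 0], [1])

    def test_total_conservation(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=33)
        p = rng.integers(0, 2, size=33)
        assert E.confusion(y, p).total == 33


class TestMetrics:
    def test_perfect_classifier(self):
        m = E.metrics(E.ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m["accuracy"] == 1.0 and m["mcc"] == 1.0

    def test_worked_example(self):
        m = E.metrics(E.ConfusionCounts(TP=40, FN=10, TN=45, FP=5))
        assert m["sensitivity"] == pytest.approx(0.80)
        assert m["specificity"] == pytest.approx(0.90)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["mcc"] == pytest.approx(0.7035, abs=1e-4)

    def test_against_naive_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = E.metrics(E.ConfusionCounts(tp, tn, fp, fn))
            acc, sens, spec, mcc = oracles.metrics_naive(tp, tn, fp, fn)
            assert m["accuracy"] == pytest.approx(acc)
            assert m["sensitivity"] == pytest.approx(sens)
            assert m["specificity"] == pytest.approx(spec)
            assert m["mcc"] == pytest.approx(mcc)

    def test_coin_flip_mcc_near_zero(self):
        rng = np.random.default_rng(4)
        mccs = []
        for _ in range(300):
            y = rng.integers(0, 2, size=200)
            p = rng.integers(0, 2, size=200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mccs.append(E.metrics(E.confusion(y, p))["mcc"])
        assert abs(np.mean(mccs)) < 0.02  # Monte-Carlo error band

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            m = E.metrics(E.ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m["sensitivity"] == 0.0 and m["mcc"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            E.metrics(E.ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = E.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_constant_scores(self):
        _, auc = E.roc_auc([0, 1, 0, 1], [0.5] * 4)
        assert auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            E.roc_auc([1, 1, 1], [0.2, 0.5, 0.9])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        p = rng.random(60)
        points, _ = E.roc_auc(y, p)
        fpr = [a for a, _ in points]
        tpr = [b for _, b in points]
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        assert all(x2 >= x1 for x1, x2 in zip(fpr, fpr[1:]))
        assert all(y2 >= y1 for y1, y2 in zip(tpr, tpr[1:]))

    def test_matches_mann_whitney(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            _, auc = E.roc_auc(y, scores)
            assert auc == pytest.approx(oracles.auc_mann_whitney(y, scores), abs=1e-9)


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 10))
    y = rng.integers(0, 2, size=60)
    X[y == 1] += 2.0  # clean mean shift: separable
    return X, y


class TestRunProtocol:
    spec = ModelSpec("lstm", widths=(6,), dense_units=6)
    cfg = TrainingConfig(epochs=8, seed=0)

    def test_sct_fits_separable_data(self, small_problem):
        X, y = small_problem
        rep = E.run_protocol(X, y, self.spec, TrainingConfig(epochs=60, seed=0), E.SplitPlan("SCT"))
        assert rep.accuracy >= 0.95

    def test_kfold_mean_is_bounded_by_folds(self, small_problem):
        X, y = small_problem
        rep = E.run_protocol(X, y, self.spec, self.cfg, E.SplitPlan("KFOLD", k=5, seed=0))
        accs = [f.accuracy for f in rep.folds]
        assert len(rep.folds) == 5
        assert min(accs) <= rep.accuracy <= max(accs)
        assert rep.accuracy == pytest.approx(np.mean(accs))

    def test_deterministic_report(self, small_problem):
        X, y = small_problem
        reps = [
            E.run_protocol(X, y, self.spec, self.cfg, E.SplitPlan("IST", seed=2))
            for _ in range(2)
        ]
        assert reps[0].accuracy == reps[1].accuracy
        assert reps[0].auc == reps[1].auc
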