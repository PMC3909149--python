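"""Folds, metrics, univariate thresholds, nested CV, report assembly."""

import numpy as np
import pandas as pd
import pytest

from breastmri.evaluation import (ModelSpec, build_report, confusion_metrics,
                                  cross_validate_subset, evaluate_feature_sets,
                                  make_folds, roc_auc, univariate_threshold_eval,
                                  youden_threshold)
from breastmri.phantom import sample_feature_table

from oracles import auc_brute


def _labels(n_mal, n_ben):
    return np.array(["malignant"] * n_mal + ["benign"] * n_ben)


class TestFolds:
    def test_study_scale_fold_sizes(self):
        y = _labels(149, 85)
        folds = make_folds(y, k=10, seed=0)
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [24, 24, 24, 24, 23, 23, 23, 23, 23, 23]
        # per-class size balance within one
        for label in ("malignant", "benign"):
            per = np.bincount(folds[y == label])
            assert per.max() - per.min() <= 1

    def test_small_balanced_cohort_perfectly_stratified(self):
        y = _labels(10, 10)
        folds = make_folds(y, k=10, seed=1)
        for f in range(10):
            assert (y[folds == f] == "malignant").sum() == 1

    def test_seeded_determinism(self):
        y = _labels(30, 20)
        np.testing.assert_array_equal(make_folds(y, 5, 42), make_folds(y, 5, 42))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="< k"):
            make_folds(_labels(5, 30), k=10)


class TestConfusionMetrics:
    def test_textbook_counts(self):
        truth = _labels(12, 10)
        pred = truth.copy()
        pred[10:12] = "benign"   # 2 FN
        pred[12:14] = "malignant"  # 2 FP
        m = confusion_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(10 / 12, abs=5e-5)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(18 / 22, abs=5e-5)

    def test_perfect_and_all_positive(self):
        truth = _labels(5, 5)
        m = confusion_metrics(truth, truth)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (1, 1, 1)
        m2 = confusion_metrics(np.full(10, "malignant"), truth)
        assert m2["sensitivity"] == 1.0 and m2["specificity"] == 0.0


class TestAUC:
    def test_separated_and_tied_scores(self):
        y = _labels(3, 3)
        assert roc_auc([5, 6, 7, 1, 2, 3], y) == 1.0
        assert roc_auc(np.ones(6), y) == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            n_mal = int(rng.integers(2, n - 2))
            y = _labels(n_mal, n - n_mal)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            assert roc_auc(scores, y) == pytest.approx(auc_brute(scores, y),
                                                       abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], np.array(["benign", "benign"]))


class TestUnivariateThreshold:
    def test_separable_feature_perfect_accuracy(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 4)
        y = np.array((["benign"] * 3 + ["malignant"] * 3) * 4)
        folds = make_folds(y, k=4, seed=0)
        res = univariate_threshold_eval(v, y, folds)
        assert res["averaged"]["accuracy"] == 1.0
        assert 3.0 < res["whole_data_threshold"] < 4.0
        assert res["direction"] == 1

    def test_direction_low_calls_malignant(self):
        # an ADC-like feature: malignant values lower
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(1.0, 0.2, 40), rng.normal(1.7, 0.2, 40)])
        y = _labels(40, 40)
        thr, direction = youden_threshold(v, y)
        assert direction == -1
        assert 1.0 < thr < 1.7

    def test_constant_feature_reports_chance(self):
        y = _labels(15, 10)
        folds = make_folds(y, k=5, seed=0)
        res = univariate_threshold_eval(np.ones(25), y, folds)
        assert res["averaged"]["accuracy"] == pytest.approx(0.6)
        assert res["constant_feature"]

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        accs = []
        for rep in range(30):
            y = _labels(60, 40)
            rng.shuffle(y)
            folds = make_folds(y, k=5, seed=rep)
            accs.append(univariate_threshold_eval(v, y, folds)["averaged"]["accuracy"])
        # a Youden-trained threshold balances the classes, so its null test
        # accuracy centres on 0.5; no spurious skill beyond the prevalence
        assert abs(np.mean(accs) - 0.5) < 0.05
        assert np.mean(accs) < 0.6


class TestCrossValidate:
    @staticmethod
    def _table(n=60, seed=0):
        X, y, _ = sample_feature_table(n_cases=n, n_informative=3, n_noise=2,
                                       effect_size=1.0, seed=seed)
        return X, y

    def test_label_leak_feature_gives_perfect_folds(self):
        X, y = self._table()
        X["oracle"] = (np.asarray(y) == "malignant").astype(float)
        for kind in ("svm_rbf", "naive_bayes_gaussian", "knn", "logistic_regression"):
            spec = next(m for m in
                        [ModelSpec("svm_rbf", grid={"clf__C": [1.0],
                                                    "clf__gamma": [0.1]}),
                         ModelSpec("naive_bayes_gaussian"), ModelSpec("knn"),
                         ModelSpec("logistic_regression")] if m.kind == kind)
            res = cross_validate_subset(X, ["oracle"], y, spec, k=5, inner_k=3, seed=0)
            assert all(f["accuracy"] == 1.0 for f in res["per_fold"])

    def test_deterministic_given_seed(self):
        X, y = self._table()
        spec = ModelSpec("logistic_regression")
        a = cross_validate_subset(X, list(X.columns), y, spec, k=5, inner_k=3, seed=3)
        b = cross_validate_subset(X, list(X.columns), y, spec, k=5, inner_k=3, seed=3)
        assert a == b

    def test_univariate_threshold_trained_without_test_fold(self):
        """Corrupting fold 0's feature values must not move the threshold
        trained *for* fold 0 (which sees only folds 1..k-1): trained cutoffs
        come from training data alone."""
        X, y = self._table(n=80, seed=5)
        v = X["signal_00"].to_numpy(float)
        folds = make_folds(y, k=5, seed=5)
        base = univariate_threshold_eval(v, y, folds)
        v_bad = v.copy()
        v_bad[folds == 0] = v_bad[folds == 0] * 100.0 + 17.0
        corrupted = univariate_threshold_eval(v_bad, y, folds)
        f0_base = next(f for f in base["per_fold"] if f["fold"] == 0)
        f0_bad = next(f for f in corrupted["per_fold"] if f["fold"] == 0)
        assert f0_bad["threshold"] == f0_base["threshold"]
        assert f0_bad["direction"] == f0_base["direction"]

    def test_empty_subset_rejected(self):
        X, y = self._table()
        with pytest.raises(ValueError):
            cross_validate_subset(X, [], y, ModelSpec("knn"), k=5)


class TestReport:
    @staticmethod
    def _table(n=100, seed=1):
        X, y, _ = sample_feature_table(n_cases=n, n_informative=3, n_noise=1,
                                       effect_size=1.0, seed=seed)
        return X, y

    def test_averaged_row_is_model_mean(self):
        X, y = self._table()
        sets = {"pair": ["signal_00", "signal_01"]}
        models = [ModelSpec("naive_bayes_gaussian"), ModelSpec("knn"),
                  ModelSpec("logistic_regression")]
        rep = evaluate_feature_sets(X, y, sets, models, k=5, inner_k=3, seed=2)
        rows = rep["sections"]["pair"]["rows"]
        model_rows = [r for r in rows if r["model"] != "Averaged"]
        avg = rows[-1]["averaged"]
        for key in ("sensitivity", "specificity", "accuracy", "auc"):
            assert avg[key] == pytest.approx(
                np.mean([r["averaged"][key] for r in model_rows]), abs=1e-12)

    def test_singleton_sets_use_univariate_threshold(self):
        X, y = self._table()
        rep = evaluate_feature_sets(X, y, {"solo": ["signal_00"]}, k=5, seed=2)
        rows = rep["sections"]["solo"]["rows"]
        assert rows[0]["model"] == "Univariate Threshold"
        assert "whole_data_threshold" in rep["sections"]["solo"]

    def test_report_regeneration_is_pure(self):
        X, y = self._table()
        sets = {"pair": ["signal_00", "signal_01"], "solo": ["signal_02"]}
        kwargs = dict(models=[ModelSpec("logistic_regression")], k=5,
                      inner_k=3, seed=4)
        a = build_report(X, y, ["signal_00"], sets, **kwargs)
        b = build_report(X, y, ["signal_00"], sets, **kwargs)
        assert a == b

    def test_roc_plot_written(self, tmp_path):
        from breastmri.evaluation import plot_roc
        X, y = self._table()
        out = tmp_path / "roc.png"
        plot_roc(X, y, {"solo": ["signal_00"],
                        "pair": ["signal_00", "signal_01"]}, out)
        assert out.exists() and out.stat().st_size > 0

    def test_univariate_section_contents(self):
        X, y = self._table()
        rep = build_report(X, y, ["signal_00", "noise_00"], {"solo": ["signal_00"]},
                           models=[ModelSpec("knn")], k=5, inner_k=3, seed=0)
        uni = rep["univariate"]["signal_00"]
        assert uni["welch_p"] < 0.01
        assert uni["mean_malignant"] > uni["mean_benign"]
        assert rep["univariate"]["noise_00"]["welch_p"] > 0.001
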