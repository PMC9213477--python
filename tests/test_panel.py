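import math

import numpy as np
import pandas as pd
import pytest

from accesspanel.intervals import Peak, PeakSet
from accesspanel.panel import (PanelConfig, blood_overlap_filter,
                               consensus_from_fold_outputs,
                               differential_accessibility,
                               evaluate_panel_classifier, filter_by_score,
                               select_consensus_features)
from accesspanel.scoring import CountMatrix, ScoreTrack


def track_from(scores):
    idx = pd.Index([f"r{i}" for i in range(len(scores))])
    s = pd.Series(scores, index=idx)
    return ScoreTrack(idx, s, s, s, 0.01)


def count_matrix(arr, label):
    arr = np.asarray(arr)
    idx = pd.Index([f"r{i}" for i in range(arr.shape[0])])
    cols = [f"{label}{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=idx, columns=cols),
                       pd.Series([label] * arr.shape[1], index=cols))


class TestScoreFilter:
    def test_accessible_keeps_boundary(self):
        mask = filter_by_score(track_from([2.0, 1.5, -2.0]),
                                 PanelConfig(direction="accessible"))
        assert mask.tolist() == [True, True, False]

    def test_inaccessible_strict(self):
        mask = filter_by_score(track_from([2.0, -1.5, -2.0]),
                                 PanelConfig(direction="inaccessible"))
        assert mask.tolist() == [False, False, True]

    def test_empty_survivors_ok(self):
        mask = filter_by_score(track_from([0.0, 0.5]),
                                 PanelConfig(direction="accessible"))
        assert mask.sum() == 0


class TestBloodOverlapFilter:
    def setup_method(self):
        self.regions = PeakSet.from_peaks([Peak("chr1", 0, 100, "a"),
                                           Peak("chr1", 200, 300, "b")])
        self.blood = PeakSet.from_peaks([Peak("chr1", 50, 150)])

    def test_accessible_removes_overlap(self):
        mask = blood_overlap_filter(self.regions, self.blood, "accessible")
        assert mask.tolist() == [False, True]

    def test_inaccessible_keeps_overlap(self):
        mask = blood_overlap_filter(self.regions, self.blood, "inaccessible")
        assert mask.tolist() == [True, False]

    def test_modes_partition_input(self, rng):
        from conftest import random_peakset
        regions = random_peakset(rng, 40)
        blood = random_peakset(rng, 20)
        acc = blood_overlap_filter(regions, blood, "accessible")
        inacc = blood_overlap_filter(regions, blood, "inaccessible")
        assert (acc ^ inacc).all()


class TestDifferentialAccessibility:
    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        mu = rng.uniform(5, 50, 2000)
        t = count_matrix(rng.poisson(mu[:, None], (2000, 10)), "t")
        b = count_matrix(rng.poisson(mu[:, None], (2000, 10)), "b")
        da = differential_accessibility(t, b, fdr_threshold=0.01)
        assert (da["qvalue"] < 0.01).mean() <= 0.02

    def test_planted_shift_detected_with_sign(self):
        rng = np.random.default_rng(1)
        n = 300
        mu = np.full(n, 20.0)
        mu_t = mu.copy()
        mu_t[:30] *= 8.0  # planted 8-fold gain in tumor
        alpha = 0.2
        draw = lambda m, k: rng.negative_binomial(
            1 / alpha, 1 / (1 + alpha * m[:, None]), (n, k))
        da = differential_accessibility(count_matrix(draw(mu_t, 10), "t"),
                                        count_matrix(draw(mu, 10), "b"))
        assert da["significant"][:30].mean() >= 0.9
        assert (da["log2fc"][:30] > 0).all()

    def test_constant_equal_counts_not_significant(self):
        t = count_matrix(np.full((20, 4), 10), "t")
        b = count_matrix(np.full((20, 4), 10), "b")
        da = differential_accessibility(t, b)
        assert not da["significant"].any()

    def test_needs_two_samples(self):
        t = count_matrix(np.ones((5, 1)), "t")
        b = count_matrix(np.ones((5, 3)), "b")
        with pytest.raises(ValueError):
            differential_accessibility(t, b)

    def test_ranksum_method(self):
        rng = np.random.default_rng(3)
        # small planted fraction keeps the cpm composition shift negligible
        mu = np.full(300, 20.0)
        mu_t = mu.copy()
        mu_t[:6] *= 8.0
        t = count_matrix(rng.poisson(mu_t[:, None], (300, 8)), "t")
        b = count_matrix(rng.poisson(mu[:, None], (300, 8)), "b")
        da = differential_accessibility(t, b, method="ranksum")
        assert da["significant"][:6].mean() > 0.9
        assert da["significant"][6:].mean() < 0.1


def make_classification(rng, n=20, p=30, informative=5, sep=3.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    X[y == 1, :informative] += sep
    cols = [f"f{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestConsensusSelection:
    def test_rule_reapplication_oracle(self, rng):
        # final set must equal an independent application of the
        # top-10% / non-zero / >=2-fold / >=2-of-3 rules to logged outputs
        for seed in range(5):
            X, y = make_classification(np.random.default_rng(seed), n=20, p=30)
            config = PanelConfig(seed=seed, n_estimators=50)
            res = select_consensus_features(X, y, config)
            p = X.shape[1]
            k = math.ceil(0.10 * p)
            rf_mean = res.fold_rf_importances.mean(axis=0)
            rf_exp = set(rf_mean.sort_values(ascending=False).index[:k])
            rf_exp = {f for f in rf_exp if rf_mean[f] > 0}
            svm_mean = res.fold_svm_coefs.mean(axis=0).abs()
            svm_exp = set(svm_mean.sort_values(ascending=False).index[:k])
            lasso_exp = set(X.columns[
                (res.fold_lasso_coefs != 0).sum(axis=0) >= 2])
            expected = {f for f in X.columns
                        if (f in rf_exp) + (f in svm_exp) + (f in lasso_exp) >= 2}
            assert set(res.selected) == expected
            assert res.rf_set == rf_exp and res.svm_set == svm_exp
            assert res.lasso_set == lasso_exp

    def test_three_set_member_selected_one_set_member_not(self):
        cols = list("abcde")
        rf = pd.DataFrame([[5, 0, 0, 1, 0.0]] * 5, columns=cols)
        svm = pd.DataFrame([[4, 0, 0, 0, 0.5]] * 5, columns=cols)
        lasso = pd.DataFrame([[1, 0, 1, 0, 0.0]] * 5, columns=cols)
        config = PanelConfig(top_fraction=0.2)  # k = 1
        selected, rf_s, svm_s, lasso_s = consensus_from_fold_outputs(
            rf, svm, lasso, config)
        assert selected == ["a"]          # in all three sets
        assert "c" in lasso_s and "c" not in selected  # lasso only

    def test_deterministic_under_seed(self, rng):
        X, y = make_classification(np.random.default_rng(0))
        config = PanelConfig(seed=9, n_estimators=50)
        a = select_consensus_features(X, y, config)
        b = select_consensus_features(X, y, config)
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.fold_rf_importances,
                                      b.fold_rf_importances)

    def test_single_class_rejected(self):
        X, _ = make_classification(np.random.default_rng(0))
        with pytest.raises(ValueError):
            select_consensus_features(X, np.zeros(len(X)), PanelConfig())

    def test_monotone_in_consensus_min_methods(self):
        X, y = make_classification(np.random.default_rng(2), n=30, p=40)
        loose = select_consensus_features(X, y, PanelConfig(seed=1, n_estimators=50,
                                                            consensus_min_methods=2))
        strict = select_consensus_features(X, y, PanelConfig(seed=1, n_estimators=50,
                                                             consensus_min_methods=3))
        assert set(strict.selected) <= set(loose.selected)


class TestEvaluatePanelClassifier:
    def test_separable_data_perfect(self):
        X, y = make_classification(np.random.default_rng(5), n=30, p=10,
                                   informative=5, sep=8.0)
        m = evaluate_panel_classifier(X, y, [f"f{j}" for j in range(5)],
                                      n_folds=5, seed=0, n_estimators=50)
        assert (m["sensitivity"] == 1.0).all()
        assert (m["specificity"] == 1.0).all()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(8)
        accs = []
        X, y = make_classification(rng, n=40, p=10, informative=5, sep=3.0)
        for _ in range(50):
            yp = rng.permutation(y)
            m = evaluate_panel_classifier(X, yp, list(X.columns), n_folds=5,
                                          seed=0, n_estimators=25)
            accs.append((m["sensitivity"].mean() + m["specificity"].mean()) / 2)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_empty_features_rejected(self):
        X, y = make_classification(np.random.default_rng(0))
        with pytest.raises(ValueError):
            evaluate_panel_classifier(X, y, [])
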