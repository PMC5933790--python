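"""Reliability-weighted fusion (precision weights, k-fold learning, metrics)."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adlsense.fusion import (CLASSES, ReliabilityFusion,
                             classification_report_frame, crossval_reliability,
                             fuse, group_precision, reliability_scores,
                             roc_auc)


class TestGroupPrecision:
    def test_perfect_predictor(self):
        truth = ["AIA", "normal", "AIA", "normal"]
        assert group_precision(truth, truth) == {"normal": 1.0, "AIA": 1.0}

    def test_always_predicting_aia(self):
        pred = ["AIA"] * 4
        truth = ["AIA", "AIA", "normal", "normal"]
        with pytest.warns(UserWarning, match="normal"):
            p = group_precision(pred, truth)
        assert p == {"AIA": 0.5, "normal": 0.0}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.choice(CLASSES, size=40)
        truth = rng.choice(CLASSES, size=40)
        base = group_precision(pred, truth)
        perm = rng.permutation(40)
        assert group_precision(pred[perm], truth[perm]) == base


class TestReliabilityScores:
    @pytest.mark.parametrize("p, want", [
        ((0.8, 0.2), (0.8, 0.2)),
        ((0.6, 0.6), (0.5, 0.5)),
        ((0.9, 0.3), (0.75, 0.25)),
    ])
    def test_normalisation_over_classes(self, p, want):
        rs = reliability_scores({"G2": {"normal": p[0], "AIA": p[1]}})
        assert rs.loc["normal", "G2"] == pytest.approx(want[0])
        assert rs.loc["AIA", "G2"] == pytest.approx(want[1])

    def test_columns_always_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            precisions = {g: {"normal": rng.random(), "AIA": rng.random()}
                          for g in ("G1", "G2", "G3")}
            rs = reliability_scores(precisions)
            np.testing.assert_allclose(rs.sum(axis=0), 1.0, atol=1e-9)

    def test_all_zero_precisions_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="all-zero"):
            rs = reliability_scores({"G1": {"normal": 0.0, "AIA": 0.0}})
        np.testing.assert_allclose(rs["G1"], 0.5)


class TestCrossvalReliability:
    @staticmethod
    def dataset(n=60, seed=0):
        rng = np.random.default_rng(seed)
        truth = np.where(rng.random(n) < 0.4, "AIA", "normal").astype(object)
        aia = truth == "AIA"
        scores = pd.DataFrame({
            "G2": np.where(aia, 0.9, 0.1),             # always right
            "G3": np.where(aia, 0.1, 0.9),             # always wrong
        })
        return scores, truth

    def test_degenerate_groups_get_extreme_weights(self):
        scores, truth = self.dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = crossval_reliability(scores, truth, k=5, seed=0)
        # G2 is perfectly precise on both classes -> balanced weights;
        # G3 never gets a prediction right -> zero precision everywhere
        np.testing.assert_allclose(rs["G2"], 0.5)
        np.testing.assert_allclose(rs["G3"], 0.5)  # uniform fallback

    def test_same_seed_reproduces_folds_and_weights(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"G2": rng.random(40), "G3": rng.random(40)})
        truth = np.where(rng.random(40) < 0.5, "AIA", "normal").astype(object)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = crossval_reliability(scores, truth, k=5, seed=7)
            b = crossval_reliability(scores, truth, k=5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_k_reduced_when_a_class_is_rare(self):
        scores, truth = self.dataset(n=30)
        truth[:] = "normal"
        truth[:3] = "AIA"
        with pytest.warns(UserWarning, match="folds"):
            crossval_reliability(scores, truth, k=10, seed=0)

    def test_single_class_rejected(self):
        scores, truth = self.dataset()
        truth[:] = "normal"
        with pytest.raises(ValueError):
            crossval_reliability(scores, truth, k=5, seed=0)


class TestFuse:
    @staticmethod
    def uniform_rs():
        return pd.DataFrame(0.5, index=list(CLASSES),
                            columns=["G1", "G2", "G3"])

    def test_unanimous_vote(self):
        rs = self.uniform_rs()
        result = fuse({g: (1.0, 0.0) for g in rs.columns}, rs)
        assert result.label == "AIA"
        assert result.class_scores["AIA"] == pytest.approx(
            rs.loc["AIA"].sum())

    def test_weighted_sum_worked_example(self):
        # mean AIA score 0.467 vs normal 0.533 -> normal wins
        rs = self.uniform_rs()
        scores = {"G1": (0.6, 0.4), "G2": (0.4, 0.6), "G3": (0.4, 0.6)}
        result = fuse(scores, rs)
        assert result.label == "normal"
        assert result.class_scores["AIA"] == pytest.approx(0.5 * 1.4)
        assert result.class_scores["normal"] == pytest.approx(0.5 * 1.6)

    def test_matches_brute_force_weighted_vote(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            rs_raw = rng.random((2, 3))
            rs = pd.DataFrame(rs_raw / rs_raw.sum(axis=0),
                              index=list(CLASSES), columns=["G1", "G2", "G3"])
            p = rng.random(3)
            scores = {g: (p[j], 1 - p[j])
                      for j, g in enumerate(["G1", "G2", "G3"])}
            want_aia = float(np.dot(rs.loc["AIA"], p))
            want_norm = float(np.dot(rs.loc["normal"], 1 - p))
            result = fuse(scores, rs)
            assert result.class_scores["AIA"] == pytest.approx(want_aia)
            assert result.class_scores["normal"] == pytest.approx(want_norm)
            want_label = "AIA" if want_aia > want_norm else "normal"
            assert result.label == want_label

    def test_missing_group_term_is_omitted(self):
        rs = self.uniform_rs()
        with pytest.warns(UserWarning, match="G1"):
            result = fuse({"G2": (0.9, 0.1), "G3": (0.8, 0.2)}, rs)
        assert result.label == "AIA"
        assert result.class_scores["AIA"] == pytest.approx(0.5 * 1.7)

    def test_no_groups_rejected(self):
        with pytest.raises(ValueError):
            fuse({}, self.uniform_rs())


class TestReliabilityFusionEstimator:
    def test_sklearn_params_roundtrip(self):
        est = ReliabilityFusion(k=5, random_state=1)
        assert est.get_params()["k"] == 5
        est.set_params(k=3)
        assert est.k == 3

    def test_fit_predict_shapes_and_classes(self):
        rng = np.random.default_rng(4)
        truth = np.where(rng.random(60) < 0.4, "AIA", "normal").astype(object)
        X = np.column_stack([
            np.where(truth == "AIA", 0.9, 0.1) + rng.normal(0, 0.02, 60),
            np.where(truth == "AIA", 0.8, 0.2) + rng.normal(0, 0.05, 60),
            rng.random(60)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ReliabilityFusion(k=5, random_state=0).fit(X, truth)
        proba = est.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= set(CLASSES)

    def test_equal_precisions_reduce_to_unweighted_average(self):
        rs = pd.DataFrame(0.5, index=list(CLASSES), columns=["G1", "G2", "G3"])
        est = ReliabilityFusion()
        est.reliability_ = rs
        est.classes_ = np.asarray(CLASSES, dtype=object)
        X = np.array([[0.2, 0.4, 0.9]])
        scores = est.decision_scores(X)
        assert scores.loc[0, "AIA"] == pytest.approx(0.5 * X.sum())


class TestEvaluation:
    def test_perfect_separation_gives_auc_one(self):
        truth = ["AIA"] * 5 + ["normal"] * 5
        scores = [0.9] * 5 + [0.1] * 5
        auc, fpr, tpr = roc_auc(scores, truth)
        assert auc == 1.0

    def test_random_scores_hover_at_half(self):
        rng = np.random.default_rng(5)
        aucs = []
        for _ in range(200):
            truth = np.where(rng.random(40) < 0.5, "AIA", "normal")
            aucs.append(roc_auc(rng.random(40), truth)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(6)
        truth = np.where(rng.random(50) < 0.4, "AIA", "normal")
        scores = rng.random(50)
        pos = scores[truth == "AIA"]
        neg = scores[truth == "normal"]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, truth)[0] == pytest.approx(
            u / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], ["AIA", "AIA"])

    def test_perfect_predictions_score_one_everywhere(self):
        truth = ["AIA", "normal", "AIA"]
        report = classification_report_frame(truth, truth)
        assert report["weighted"] == {"precision": 1.0, "recall": 1.0,
                                      "f1": 1.0}

    def test_confusion_counts_worked_example(self):
        # class AIA: TP=7, FP=3, FN=7 -> precision 0.7, recall 0.5
        truth = ["AIA"] * 7 + ["normal"] * 3 + ["AIA"] * 7 + ["normal"] * 3
        pred = ["AIA"] * 10 + ["normal"] * 10
        report = classification_report_frame(pred, truth)["per_class"]["AIA"]
        assert report["precision"] == pytest.approx(0.7)
        assert report["recall"] == pytest.approx(0.5)
        assert report["f1"] == pytest.approx(2 * 0.7 * 0.5 / 1.2)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(7)
        truth = rng.choice(CLASSES, size=60)
        pred = rng.choice(CLASSES, size=60)
        for stats in classification_report_frame(pred, truth)["per_class"].values():
            p, r, f = stats["precision"], stats["recall"], stats["f1"]
            if p > 0 and r > 0:
                assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
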