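"""Task labels, cross-validation, metrics, ROC/AUC, DeLong, misclassification."""

import numpy as np
import pandas as pd
import pytest

import glioedit as g
from glioedit.quant import GlioeditError


def table1_like_cohort():
    """A cohort with the 225/163/250 subtype composition."""
    rows = []
    for subtype, n in zip(g.SUBTYPES, (225, 163, 250)):
        for i in range(n):
            rows.append({
                "sample_id": f"{subtype}-{i}",
                "subtype": subtype,
                "idh_status": "wildtype" if subtype == "wt" else "mutant",
                "codel_status": "codel" if subtype == "mut-codel" else "non-codel",
                "grade": "G2",
            })
    return pd.DataFrame(rows).set_index("sample_id")


class TestTaskLabels:
    def test_idh_task_positives_over_whole_cohort(self):
        labels = g.make_task_labels(table1_like_cohort(), g.TaskSpec(task="idh"))
        assert len(labels) == 638
        assert labels.sum() == 413

    def test_codel_task_restricted_to_idh_mutants(self):
        labels = g.make_task_labels(
            table1_like_cohort(),
            g.TaskSpec(task="codel", cohort_restriction="idh_mutant_only"))
        assert len(labels) == 413
        assert labels.sum() == 163

    def test_codel_task_full_cohort_mode(self):
        labels = g.make_task_labels(
            table1_like_cohort(), g.TaskSpec(task="codel", cohort_restriction="all"))
        assert len(labels) == 638
        assert labels.sum() == 163

    def test_three_class_one_vs_rest(self):
        out = g.make_task_labels(table1_like_cohort(), g.TaskSpec(task="three_class"))
        assert list(out.columns) == ["wt", "mut-codel", "mut-non-codel"]
        assert (out.sum(axis=1) == 1).all()

    def test_empty_class_rejected_by_name(self):
        cohort = table1_like_cohort()
        cohort = cohort[cohort["idh_status"] == "mutant"]
        with pytest.raises(GlioeditError, match="negative"):
            g.make_task_labels(cohort, g.TaskSpec(task="idh"))


class TestFeatureMatrix:
    def _levels(self):
        return pd.DataFrame(
            [[0.1, np.nan, 0.3], [0.0, 0.5, 1.0]],
            index=["a", "b"], columns=["s1", "s2", "s3"])

    def test_no_missing_is_identity_restriction(self):
        lv = self._levels().fillna(0.2)
        out = g.build_feature_matrix(lv, ["a", "b"])
        pd.testing.assert_frame_equal(out, lv.T)

    def test_zero_and_mean_imputation(self):
        lv = self._levels()
        assert g.build_feature_matrix(lv, ["a"]).loc["s2", "a"] == 0.0
        assert g.build_feature_matrix(lv, ["a"], impute="mean").loc["s2", "a"] == \
            pytest.approx(0.2)

    def test_all_missing_site_becomes_zero_column(self):
        lv = pd.DataFrame([[np.nan, np.nan]], index=["a"], columns=["s1", "s2"])
        assert (g.build_feature_matrix(lv, ["a"])["a"] == 0).all()

    def test_absent_site_rejected(self):
        with pytest.raises(GlioeditError, match="absent"):
            g.build_feature_matrix(self._levels(), ["zzz"])


class TestMetrics:
    def test_all_correct(self):
        acc, sen, spe, conf = g.compute_metrics([1, 0, 1], [1, 0, 1])
        assert (acc, sen, spe) == (1.0, 1.0, 1.0)

    def test_complement_predictions_zero_accuracy(self):
        acc, *_ = g.compute_metrics([0, 1, 0], [1, 0, 1])
        assert acc == 0.0

    def test_toy_confusion_counts(self):
        # TP=2, FN=1, TN=3, FP=0
        acc, sen, spe, conf = g.compute_metrics(
            [1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0])
        assert acc == pytest.approx(5 / 6)
        assert sen == pytest.approx(2 / 3)
        assert spe == 1.0
        assert conf == {"TP": 2, "FP": 0, "TN": 3, "FN": 1}

    def test_undefined_sensitivity_without_positives(self):
        _, sen, spe, _ = g.compute_metrics([0, 0], [0, 0])
        assert np.isnan(sen) and spe == 1.0


def mann_whitney_auc(scores, labels):
    """Pair-counting oracle: concordant pairs + half ties over all pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        roc, auc = g.compute_roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert tuple(roc[0]) == (0, 0) and tuple(roc[-1]) == (1, 1)

    def test_constant_scores_give_half(self):
        _, auc = g.compute_roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_hand_example_three_of_four_pairs_concordant(self):
        _, auc = g.compute_roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_mann_whitney_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 30)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        roc, auc = g.compute_roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(GlioeditError):
            g.compute_roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        res = g.delong_test(scores, scores, labels)
        assert res.p_value == 1.0 and res.z == 0.0

    def test_swap_flips_z_keeps_p(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 25)
        a = rng.normal(size=50) + labels
        b = rng.normal(size=50) + 0.3 * labels
        r1 = g.delong_test(a, b, labels)
        r2 = g.delong_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert (r1.auc_a, r1.auc_b) == (r2.auc_b, r2.auc_a)

    def test_large_effect_detected(self):
        # AUC 1 vs ~0.5 on n=100 must be decisively significant
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 50)
        perfect = labels.astype(float)
        noise = rng.normal(size=100)
        res = g.delong_test(perfect, noise, labels)
        assert res.auc_a == 1.0
        assert res.p_value < 1e-3

    def test_null_calibration_rejection_rate(self):
        # two independent uninformative classifiers: ~5% rejections at 0.05
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 500
        labels = np.repeat([0, 1], 30)
        for _ in range(n_rep):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            rejections += g.delong_test(a, b, labels).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(GlioeditError, match="paired"):
            g.delong_test([0.1, 0.2], [0.1], [1, 0])


def _planted_features(n=80, n_sites=30, n_informative=6, effect=1.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = pd.Series(np.repeat([0, 1], n // 2),
                       index=[f"s{i}" for i in range(n)])
    X = rng.normal(size=(n, n_sites)) * 0.3
    X[:, :n_informative] += effect * labels.to_numpy()[:, None]
    feats = pd.DataFrame(X, index=labels.index,
                         columns=[f"site{j}" for j in range(n_sites)])
    return feats, labels


class TestRunCV:
    def test_separable_data_reaches_auc_one(self):
        feats, labels = _planted_features(effect=5.0)
        for learner in g.classify.LEARNERS:
            _, summary = g.run_cv(feats, labels,
                                  g.CVConfig(n_folds=5, seed=0, learner=learner))
            assert summary.auc == 1.0

    def test_same_seed_reproduces_folds_and_summary(self):
        feats, labels = _planted_features(seed=4)
        cfg = g.CVConfig(n_folds=5, seed=7, learner="random_forest",
                         feature_selection="in_fold")
        folds1, s1 = g.run_cv(feats, labels, cfg)
        folds2, s2 = g.run_cv(feats, labels, cfg)
        assert [f.test_ids for f in folds1] == [f.test_ids for f in folds2]
        assert [f.selected_site_ids for f in folds1] == \
            [f.selected_site_ids for f in folds2]
        assert s1.auc == s2.auc and s1.acc == s2.acc

    def test_every_sample_tested_exactly_once(self):
        feats, labels = _planted_features(seed=5)
        folds, summary = g.run_cv(feats, labels, g.CVConfig(n_folds=8, seed=1))
        tested = [s for f in folds for s in f.test_ids]
        assert sorted(tested) == sorted(labels.index)
        assert sum(summary.confusion.values()) == len(labels)

    def test_permuted_labels_give_chance_auc(self):
        feats, labels = _planted_features(n=200, effect=2.0, seed=6)
        rng = np.random.default_rng(8)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        _, summary = g.run_cv(feats, permuted, g.CVConfig(n_folds=5, seed=2))
        assert 0.35 <= summary.auc <= 0.65

    def test_in_fold_selection_uses_training_data_only(self, monkeypatch):
        # instrument the selector: it must never see test-sample rows
        feats, labels = _planted_features(seed=9)
        cfg = g.CVConfig(n_folds=4, seed=3, learner="svm",
                         feature_selection="in_fold")
        seen = []
        import glioedit.classify as mod
        original = mod.select_features_fold
        monkeypatch.setattr(
            mod, "select_features_fold",
            lambda learner, X, y, **kw: seen.append(set(X.index)) or
            original(learner, X, y, **kw))
        folds, _ = g.run_cv(feats, labels, cfg)
        for fold, train_rows in zip(folds, seen):
            assert train_rows == set(fold.train_ids)
            assert not train_rows & set(fold.test_ids)

    def test_training_fold_without_a_class_raises(self):
        feats, labels = _planted_features(n=20, seed=10)
        labels[:] = 0
        labels.iloc[0] = 1  # single positive cannot stratify into 5 folds
        with pytest.raises((GlioeditError, ValueError)):
            g.run_cv(feats, labels,
                     g.CVConfig(n_folds=5, seed=0, stratified=False))


class TestFeatureSelection:
    def test_adaboost_bounded_by_stump_count(self):
        feats, labels = _planted_features(n=60, n_sites=120, n_informative=60,
                                          effect=0.8, seed=11)
        sel = g.select_features_fold("adaboost", feats, labels)
        assert len(sel) <= 50  # one feature per stump, 50 stumps by default

    def test_top_k_returns_exactly_k(self):
        feats, labels = _planted_features(seed=12)
        sel = g.select_features_fold("svm", feats, labels, top_k=10)
        assert len(sel) == 10

    def test_informative_sites_rank_first(self):
        feats, labels = _planted_features(effect=3.0, seed=13)
        sel = g.select_features_fold("svm", feats, labels, top_k=6)
        assert set(sel) == {f"site{j}" for j in range(6)}

    def test_duplicated_informative_column_still_selected(self):
        feats, labels = _planted_features(effect=3.0, seed=14)
        feats = feats.copy()
        feats["site0_dup"] = feats["site0"]
        sel = g.select_features_fold("random_forest", feats, labels)
        # importance splits across the duplicates, but the union survives
        assert {"site0", "site0_dup"} & set(sel)


class TestRunAggregation:
    def _fold(self, idx, test_ids, predicted, true, selected=()):
        s = pd.Series(predicted, index=test_ids, dtype=int)
        return g.FoldResult(fold_index=idx, train_ids=[], test_ids=list(test_ids),
                            selected_site_ids=list(selected),
                            scores=s.astype(float), predicted=s)

    def test_misclassified_intersection_across_runs(self):
        labels = pd.Series([1, 0, 1, 0], index=list("abcd"))
        run1 = [self._fold(0, list("abcd"), [0, 0, 1, 1], labels)]
        run2 = [self._fold(0, list("abcd"), [0, 1, 1, 0], labels)]
        run3 = [self._fold(0, list("abcd"), [0, 0, 0, 0], labels)]
        # 'a' is wrong in every run; 'd' only in run1; 'b' in run2; 'c' in run3
        assert g.identify_misclassified([run1, run2, run3], labels) == {"a"}
        assert g.identify_misclassified([run1], labels) == {"a", "d"}
        with pytest.raises(GlioeditError):
            g.identify_misclassified([], labels)

    def test_disjoint_misclassified_sets_intersect_empty(self):
        labels = pd.Series([1, 0], index=list("ab"))
        run1 = [self._fold(0, list("ab"), [0, 0], labels)]  # a wrong
        run2 = [self._fold(0, list("ab"), [1, 1], labels)]  # b wrong
        assert g.identify_misclassified([run1, run2], labels) == set()

    def test_repeated_sites_counting(self):
        per_fold = [("x", "y"), ("x",), ("x", "z"), ("x", "y"), ("x", "y")]
        folds = [self._fold(i, [f"s{i}"], [0], None, selected=sel)
                 for i, sel in enumerate(per_fold)]
        assert g.repeated_selected_sites(folds, min_count=5) == {"x"}
        assert g.repeated_selected_sites(folds, min_count=3) == {"x", "y"}
        assert g.repeated_selected_sites(folds, min_count=1) == {"x", "y", "z"}
        with pytest.warns(UserWarning):
            assert g.repeated_selected_sites(folds, min_count=6) == set()
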