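"""ROC/AUC machinery, cross-validation, importance and transfer."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ampliclass import (ClassifierSpec, choose_operating_point, confusion_at,
                        cross_validate, feature_importance, normalize,
                        roc_and_auc, simulate_cohort, transfer_classify)
from ampliclass.synthetic import CohortSpec, default_planted


def brute_force_auc(scores, labels, positive) -> float:
    """Oracle: pair counting with the half-credit tie convention."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == positive], s[y != positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else 0.5 if a == b else 0.0
    return wins / (len(pos) * len(neg))


SMALL_RF = ClassifierSpec(n_trees=100, seed=0)


@pytest.fixture(scope="module")
def small_signal_table():
    spec = CohortSpec(n_per_class={"control": 30, "IBD": 30}, n_taxa=80,
                      planted_taxa=default_planted(6, 2.0), seed=21)
    table, labels, truth = simulate_cohort(spec)
    return normalize(table), labels, truth


class TestRocAuc:
    def test_perfect_separation(self):
        roc, auc = roc_and_auc([0.9, 0.8, 0.2, 0.1], ["+", "+", "-", "-"], "+")
        assert auc == 1.0

    def test_all_scores_equal_gives_half(self):
        _, auc = roc_and_auc([0.5] * 6, ["+", "-", "+", "-", "+", "-"], "+")
        assert auc == 0.5

    def test_three_score_pair_counting_example(self):
        # pairs: (0.9 vs 0.8) won, (0.4 vs 0.8) lost -> AUC = 1/2
        _, auc = roc_and_auc([0.9, 0.8, 0.4], ["+", "-", "+"], "+")
        assert auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_auc([0.1, 0.2], ["+", "+"], "+")

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # ties guaranteed
        labels = rng.choice(["+", "-"], size=n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "+", "-"
        _, auc = roc_and_auc(scores, labels, "+")
        assert auc == pytest.approx(brute_force_auc(scores, labels, "+"), abs=1e-12)
        # sklearn agrees on the tie convention
        assert auc == pytest.approx(
            roc_auc_score(labels == np.array("+"), scores), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_roc_monotone_with_correct_endpoints(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(size=40)
        labels = rng.choice(["+", "-"], size=40)
        labels[:2] = ["+", "-"]
        roc, _ = roc_and_auc(scores, labels, "+")
        assert roc.iloc[0]["fpr"] == 0.0 and roc.iloc[0]["tpr"] == 0.0
        assert roc.iloc[-1]["fpr"] == 1.0 and roc.iloc[-1]["tpr"] == 1.0
        assert (np.diff(roc["fpr"]) >= 0).all() and (np.diff(roc["tpr"]) >= 0).all()


class TestOperatingPoint:
    def _roc(self):
        return pd.DataFrame({
            "threshold": [np.inf, 0.9, 0.7, 0.5, 0.3, 0.1],
            "fpr": [0.0, 0.0, 0.2, 0.4, 0.7, 1.0],
            "tpr": [0.0, 0.4, 0.6, 0.8, 0.9, 1.0],
        })

    def test_target_between_points(self):
        thr, sens, spec = choose_operating_point(self._roc(), 0.8)
        assert (thr, sens, spec) == (0.5, 0.8, 0.6)

    def test_target_zero_returns_most_specific_point(self):
        thr, sens, spec = choose_operating_point(self._roc(), 0.0)
        assert sens == 0.0 and spec == 1.0

    def test_target_one_returns_endpoint(self):
        thr, sens, spec = choose_operating_point(self._roc(), 1.0)
        assert sens == 1.0 and spec == 0.0

    def test_unachievable_target_warns(self):
        roc = self._roc().iloc[:4]
        with pytest.warns(UserWarning, match="unachievable"):
            thr, sens, spec = choose_operating_point(roc, 0.99)
        assert sens == 0.8


class TestConfusion:
    def test_threshold_below_all_scores(self):
        c = confusion_at([0.6, 0.7], ["+", "-"], 0.0, "+")
        assert c["sensitivity"] == 1.0 and c["specificity"] == 0.0

    def test_threshold_above_all_scores(self):
        c = confusion_at([0.6, 0.7], ["+", "-"], 2.0, "+")
        assert c["TP"] == 0 and c["TN"] == 1 and c["FN"] == 1

    def test_hand_tallied_eight_scores(self):
        scores = [0.9, 0.8, 0.6, 0.55, 0.45, 0.4, 0.2, 0.1]
        labels = ["+", "+", "-", "+", "-", "+", "-", "-"]
        c = confusion_at(scores, labels, 0.5, "+")
        assert (c["TP"], c["FP"], c["FN"], c["TN"]) == (3, 1, 1, 3)
        assert c["sensitivity"] == 0.75 and c["specificity"] == 0.75


class TestCrossValidate:
    def test_each_sample_in_exactly_one_test_fold_per_repeat(self, small_signal_table):
        table, _, _ = small_signal_table
        ev = cross_validate(table, "label", SMALL_RF, k=5, repeats=2, seed=0)
        assert ev.scores.notna().all().all()      # scored once per repeat
        assert ev.folds.notna().all().all()
        for col in ev.folds:
            assert set(ev.folds[col].unique()) == set(range(5))

    def test_deterministic_given_seed(self, small_signal_table):
        table, _, _ = small_signal_table
        e1 = cross_validate(table, "label", SMALL_RF, k=5, repeats=2, seed=3)
        e2 = cross_validate(table, "label", SMALL_RF, k=5, repeats=2, seed=3)
        pd.testing.assert_frame_equal(e1.scores, e2.scores)
        pd.testing.assert_frame_equal(e1.folds, e2.folds)
        assert e1.aucs == e2.aucs

    def test_signal_cohort_high_auc(self, small_signal_table):
        table, _, _ = small_signal_table
        ev = cross_validate(table, "label", SMALL_RF, k=5, repeats=2, seed=0)
        assert ev.auc_median >= 0.9

    def test_stratification_error_when_class_too_small(self, small_signal_table):
        table, _, _ = small_signal_table
        with pytest.raises(ValueError, match="stratified"):
            cross_validate(table, "label", SMALL_RF, k=40)

    def test_auc_in_unit_interval_and_median_order_free(self, small_signal_table):
        table, _, _ = small_signal_table
        ev = cross_validate(table, "label", SMALL_RF, k=5, repeats=3, seed=1)
        assert all(0.0 <= a <= 1.0 for a in ev.aucs)
        assert np.median(ev.aucs[::-1]) == ev.auc_median


class TestFeatureImportance:
    def test_planted_taxa_rank_highly(self, small_signal_table):
        table, _, truth = small_signal_table
        imp = feature_importance(table, "label", SMALL_RF, seed=0)
        planted_ranks = imp.loc[truth.planted["taxon"], "rank"]
        assert planted_ranks.median() <= 2 * len(truth.planted)

    def test_duplicated_feature_importance_dilutes(self, small_signal_table):
        table, _, truth = small_signal_table
        imp = feature_importance(table, "label", SMALL_RF, seed=0)
        top = imp.index[0]
        dup = table.frequencies.copy()
        dup.loc[top + "_copy"] = dup.loc[top]
        counts = table.counts.copy()
        counts.loc[top + "_copy"] = counts.loc[top]
        table2 = dataclasses.replace(table, counts=counts, frequencies=dup,
                                     ranks=None)
        imp2 = feature_importance(table2, "label", SMALL_RF, seed=0)
        solo = imp.loc[top, "importance"]
        assert imp2.loc[top, "importance"] <= solo + 0.05
        assert imp2.loc[top + "_copy", "importance"] <= solo + 0.05


class TestTransfer:
    def test_resubstitution_auc_at_least_cv_auc(self, small_signal_table):
        table, _, _ = small_signal_table
        ev = cross_validate(table, "label", SMALL_RF, k=5, repeats=2, seed=0)
        res = transfer_classify(table, "label", table, spec=SMALL_RF)
        assert res.auc >= ev.auc_median

    def test_transfer_between_cohorts_with_shared_signal(self):
        planted = default_planted(6, 1.5)
        spec_a = CohortSpec(n_per_class={"control": 40, "IBD": 40}, n_taxa=80,
                            planted_taxa=planted, seed=30)
        from ampliclass.synthetic import default_concentration
        spec_b = CohortSpec(n_per_class={"control": 40, "IBD": 40}, n_taxa=80,
                            planted_taxa=planted,
                            baseline_concentration=default_concentration(80, total=450),
                            seed=31)
        ta, _, _ = simulate_cohort(spec_a)
        tb, _, _ = simulate_cohort(spec_b)
        res = transfer_classify(normalize(ta), "label", normalize(tb), spec=SMALL_RF)
        assert res.auc >= 0.8

    def test_missing_test_features_zero_filled_with_warning(self, small_signal_table):
        table, _, _ = small_signal_table
        reduced = dataclasses.replace(
            table,
            counts=table.counts.iloc[:40],
            frequencies=table.frequencies.iloc[:40],
            ranks=None)
        with pytest.warns(UserWarning, match="zero"):
            res = transfer_classify(table, "label", reduced, spec=SMALL_RF)
        assert len(res.train_only) == len(table.features) - 40

    def test_disjoint_features_error_lists_names(self, small_signal_table):
        table, _, _ = small_signal_table
        renamed = dataclasses.replace(
            table,
            counts=table.counts.rename(index=lambda f: "other_" + f),
            frequencies=table.frequencies.rename(index=lambda f: "other_" + f),
            ranks=None)
        with pytest.raises(ValueError, match="no shared features"):
            transfer_classify(table, "label", renamed, spec=SMALL_RF)


class TestModelPersistence:
    def test_save_load_round_trip_scores_identically(self, small_signal_table, tmp_path):
        from ampliclass.classify import (_features_matrix, load_model,
                                         positive_vote_fraction, save_model)

        table, _, _ = small_signal_table
        X, names = _features_matrix(table)
        y = table.metadata["label"].to_numpy()
        model = SMALL_RF.build()
        model.fit(X, y)
        save_model(model, names, tmp_path / "rf.joblib", positive_class="IBD")
        back, manifest = load_model(tmp_path / "rf.joblib")
        assert manifest["features"] == names
        assert manifest["positive_class"] == "IBD"
        np.testing.assert_array_equal(
            positive_vote_fraction(model, X, "IBD"),
            positive_vote_fraction(back, X, "IBD"))


class TestNullBehavior:
    def test_label_permutation_auc_near_half(self, small_signal_table):
        table, _, _ = small_signal_table
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(3):
            meta = table.metadata.copy()
            meta["label"] = rng.permutation(meta["label"].to_numpy())
            permuted = dataclasses.replace(table, metadata=meta)
            ev = cross_validate(permuted, "label", SMALL_RF, k=5, repeats=1, seed=2)
            aucs.append(ev.auc_median)
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_auc_increases_with_effect_size(self):
        medians = []
        for lfc in (0.5, 1.5):
            spec = CohortSpec(n_per_class={"control": 30, "IBD": 30}, n_taxa=80,
                              planted_taxa=default_planted(6, lfc), seed=33)
            table, _, _ = simulate_cohort(spec)
            ev = cross_validate(normalize(table), "label", SMALL_RF,
                                k=5, repeats=1, seed=0)
            medians.append(ev.auc_median)
        assert medians[1] >= medians[0]
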