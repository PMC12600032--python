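"""Segment labeling, feature selection, random-forest CV and interrogation."""

import numpy as np
import pandas as pd
import pytest

from foreco import ecosystem, synthetic
from foreco.errors import DataError


def separable_training_table(seed=0, n_per_class=30, n_noise=3) -> pd.DataFrame:
    """Two perfectly separable classes: one informative feature + pure noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for c, center in ((1, 0.0), (2, 10.0)):
        for i in range(n_per_class):
            row = {"segment_id": f"S{c}_{i}", "cluster": c,
                   "sep_q50": center + rng.normal(0, 0.5)}
            for k in range(n_noise):
                row[f"noise{k}_q50"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestSegmentQuantiles:
    def test_constant_pixels_collapse(self):
        px = pd.DataFrame({"segment_id": ["s"] * 4, "variable": ["v"] * 4,
                           "value": [2.0] * 4})
        out = ecosystem.compute_segment_quantiles(px).set_index("segment_id")
        assert out.loc["s", ["v_q25", "v_q50", "v_q75"]].tolist() == [2.0, 2.0, 2.0]

    def test_odd_length_median(self):
        px = pd.DataFrame({"segment_id": ["s"] * 5, "variable": ["v"] * 5,
                           "value": [1.0, 2, 3, 4, 5]})
        out = ecosystem.compute_segment_quantiles(px)
        assert out.loc[0, "v_q50"] == 3.0

    def test_linear_interpolation_convention(self):
        px = pd.DataFrame({"segment_id": ["s"] * 4, "variable": ["v"] * 4,
                           "value": [1.0, 2, 3, 4]})
        out = ecosystem.compute_segment_quantiles(px)
        assert out.loc[0, "v_q25"] == pytest.approx(1.75)

    def test_empty_table_errors(self):
        with pytest.raises(DataError):
            ecosystem.compute_segment_quantiles(
                pd.DataFrame(columns=["segment_id", "variable", "value"]))


class TestLabelSegments:
    @staticmethod
    def segments_and_labels():
        seg = pd.DataFrame({
            "segment_id": [f"S{i}" for i in range(8)],
            "plot_id": ["p1", "p2", "p3", "p4", "p5", None, None, None],
            "v_q50": np.arange(8.0),
        })
        labels = pd.Series([1, 1, 1, 2, 2], index=[f"p{i}" for i in range(1, 6)])
        return seg, labels

    def test_small_clusters_are_excluded_entirely(self):
        seg, labels = self.segments_and_labels()
        train, predict = ecosystem.label_segments(seg, labels, min_cluster_size=3)
        assert set(train["cluster"]) == {1}
        assert len(train) == 3 and len(predict) == 5

    def test_unlabeled_segments_form_prediction_set(self):
        seg, labels = self.segments_and_labels()
        train, predict = ecosystem.label_segments(seg, labels, min_cluster_size=1)
        assert len(train) == 5
        assert set(predict["segment_id"]) == {"S5", "S6", "S7"}

    def test_threshold_rule_keeps_all_large_clusters(self):
        seg, labels = self.segments_and_labels()
        train, _ = ecosystem.label_segments(seg, labels, min_cluster_size=2)
        assert set(train["cluster"]) == {1, 2}


class TestSelectFeaturesRfe:
    def test_informative_feature_ranked_first_across_seeds(self):
        """With 1 separating + noise features, the signal tops the ranking."""
        for seed in range(5):
            train = separable_training_table(seed=seed)
            sel = ecosystem.select_features_rfe(
                train, subset_sizes=[1, 2, 4], folds=3, seed=seed, n_estimators=50)
            assert sel.ranking[0] == "sep_q50"
            assert "sep_q50" in sel.selected

    def test_label_leak_is_selected_with_perfect_score(self):
        train = separable_training_table(seed=1)
        train["leak_q50"] = train["cluster"].astype(float)
        sel = ecosystem.select_features_rfe(
            train, subset_sizes=[1], folds=3, seed=0, n_estimators=50)
        assert sel.selected in (["leak_q50"], ["sep_q50"])
        assert sel.cv_scores.max() == pytest.approx(1.0)

    def test_full_size_is_identity_selection(self):
        train = separable_training_table(seed=2)
        feats = ecosystem.feature_columns(train)
        sel = ecosystem.select_features_rfe(
            train, subset_sizes=[len(feats)], folds=3, seed=0, n_estimators=30)
        assert sorted(sel.selected) == sorted(feats)

    def test_oversized_subsets_are_clipped(self):
        train = separable_training_table(seed=3)
        sel = ecosystem.select_features_rfe(
            train, subset_sizes=[2, 99], folds=3, seed=0, n_estimators=30)
        assert max(sel.cv_scores.index) == len(ecosystem.feature_columns(train))


class TestPruneCollinear:
    def test_exact_duplicates_keep_one(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.normal(size=100)})
        t["b"] = t["a"]
        kept, dropped = ecosystem.prune_collinear(t, ["a", "b"])
        assert kept == ["a"]
        assert dropped[0][:2] == ("b", "a")

    def test_independent_features_all_kept(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        kept, dropped = ecosystem.prune_collinear(t, list("abcd"))
        assert kept == list("abcd") and not dropped

    def test_greedy_rule_keeps_rank_leader_and_uncorrelated_tail(self):
        """Correlation chain: v2 collinear with v1, v3 collinear with v2 but
        not v1 -> greedy scan keeps {v1, v3}."""
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.8], [0.5, 0.8, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        t = pd.DataFrame(X, columns=["v1", "v2", "v3"])
        kept, dropped = ecosystem.prune_collinear(t, ["v1", "v2", "v3"], r_threshold=0.7)
        assert kept == ["v1", "v3"]
        assert dropped[0][0] == "v2"


class TestFitEvaluate:
    def test_toy_confusion_f1_arithmetic(self):
        """Counts [[2,0],[1,1]] -> per-class F1 (0.8, 2/3), macro 0.7333."""
        fit = ecosystem.scores_from_predictions([1, 1, 2, 2], [1, 1, 1, 2])
        assert fit.per_class_f1.to_numpy() == pytest.approx([0.8, 2 / 3])
        assert fit.macro_f1 == pytest.approx(0.73333, abs=1e-4)
        assert fit.confusion.loc[2].to_numpy() == pytest.approx([50.0, 50.0])

    def test_confusion_rows_sum_to_100_and_macro_is_mean(self):
        train = separable_training_table(seed=4)
        fit, _ = ecosystem.fit_evaluate(train, ["sep_q50", "noise0_q50"],
                                        folds=5, seed=0, n_estimators=50)
        assert fit.confusion.sum(axis=1).to_numpy() == pytest.approx([100.0, 100.0])
        assert fit.macro_f1 == pytest.approx(fit.per_class_f1.mean())

    def test_separable_classes_reach_perfect_macro_f1(self):
        train = separable_training_table(seed=5)
        fit, _ = ecosystem.fit_evaluate(train, ["sep_q50"], folds=5, seed=0,
                                        n_estimators=50)
        assert fit.macro_f1 == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(6)
        train = separable_training_table(seed=6, n_per_class=50)
        train["cluster"] = rng.permutation(train["cluster"].to_numpy())
        fit, _ = ecosystem.fit_evaluate(train, ["sep_q50", "noise0_q50"],
                                        folds=5, seed=0, n_estimators=50)
        assert fit.macro_f1 < 0.70  # chance level is 0.5 on 2 balanced classes

    def test_single_class_errors(self):
        train = separable_training_table(seed=7)
        train["cluster"] = 1
        with pytest.raises(DataError):
            ecosystem.fit_evaluate(train, ["sep_q50"], folds=5, seed=0)

    def test_folds_reduced_when_class_too_small(self):
        train = separable_training_table(seed=8, n_per_class=6)
        fit, _ = ecosystem.fit_evaluate(train, ["sep_q50"], folds=10, seed=0,
                                        n_estimators=20)
        assert fit.folds == 6


class TestPermutationImportance:
    @staticmethod
    def fitted(seed=0, with_constant=False):
        train = separable_training_table(seed=seed)
        feats = ["sep_q50", "noise0_q50"]
        if with_constant:
            train["const_q50"] = 1.0
            feats.append("const_q50")
        _, model = ecosystem.fit_evaluate(train, feats, folds=3, seed=0,
                                          n_estimators=50)
        return train, feats, model

    def test_sole_separating_variable_has_minimal_p(self):
        train, feats, model = self.fitted()
        imp = ecosystem.permutation_importance_scores(
            model, train, feats, n_permutations=30, seed=0)
        assert imp.overall.loc["sep_q50", "importance"] > 0.3
        assert imp.overall.loc["sep_q50", "p_value"] == pytest.approx(1 / 31)

    def test_noise_variable_is_unimportant(self):
        train, feats, model = self.fitted(seed=1)
        imp = ecosystem.permutation_importance_scores(
            model, train, feats, n_permutations=30, seed=0)
        assert abs(imp.overall.loc["noise0_q50", "importance"]) < 0.05
        assert imp.overall.loc["noise0_q50", "p_value"] > 0.05

    def test_constant_column_changes_nothing(self):
        train, feats, model = self.fitted(seed=2, with_constant=True)
        imp = ecosystem.permutation_importance_scores(
            model, train, feats, n_permutations=10, seed=0)
        assert imp.overall.loc["const_q50", "importance"] == 0.0
        assert imp.overall.loc["const_q50", "p_value"] == 1.0

    def test_per_class_table_and_pvalue_ranges(self):
        train, feats, model = self.fitted(seed=3)
        imp = ecosystem.permutation_importance_scores(
            model, train, feats, n_permutations=10, seed=0)
        assert set(imp.per_class.index.get_level_values("cluster")) == {1, 2}
        assert ((imp.overall["p_value"] > 0) & (imp.overall["p_value"] <= 1)).all()

    def test_gini_null_refits_give_pvalues(self):
        train, feats, model = self.fitted(seed=4)
        imp = ecosystem.permutation_importance_scores(
            model, train, feats, n_permutations=10, seed=0, gini_refits=True)
        assert imp.gini_p_values.loc["sep_q50"] == pytest.approx(1 / 11)


class TestPartialDependence:
    def test_ignored_variable_gives_flat_curve(self):
        train, feats, model = TestPermutationImportance.fitted(seed=5, with_constant=True)
        pdp = ecosystem.partial_dependence(model, train, "const_q50", feats, grid_size=5)
        assert np.allclose(pdp.log_odds.std(axis=0), 0.0, atol=1e-12)

    def test_monotone_relation_yields_monotone_curve(self):
        train, feats, model = TestPermutationImportance.fitted(seed=6)
        pdp = ecosystem.partial_dependence(model, train, "sep_q50", feats, grid_size=10)
        curve = pdp.log_odds[2].to_numpy()  # class 2 sits at high sep values
        assert (np.diff(curve) >= -1e-9).all() and curve[-1] > curve[0]

    def test_grid_clamped_to_observed_range(self):
        train, feats, model = TestPermutationImportance.fitted(seed=7)
        pdp = ecosystem.partial_dependence(model, train, "sep_q50", feats, grid_size=7)
        assert pdp.grid.min() == train["sep_q50"].min()
        assert pdp.grid.max() == train["sep_q50"].max()

    def test_unknown_variable_errors(self):
        train, feats, model = TestPermutationImportance.fitted(seed=8)
        with pytest.raises(DataError):
            ecosystem.partial_dependence(model, train, "missing", feats)


class TestPredictSegments:
    def test_probabilities_sum_to_one_and_labels_match(self):
        train, feats, model = TestPermutationImportance.fitted(seed=9)
        out = ecosystem.predict_segments(model, train, feats)
        proba = out[[c for c in out.columns if c.startswith("p_")]].to_numpy()
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (out["ecosystem"] == train["cluster"].to_numpy()).mean() == 1.0

    def test_missing_feature_column_errors(self):
        train, feats, model = TestPermutationImportance.fitted(seed=10)
        with pytest.raises(DataError):
            ecosystem.predict_segments(model, train.drop(columns=["sep_q50"]), feats)

    def test_zero_noise_landscape_recovered(self, zero_noise_data):
        """Model trained on plot segments maps the unlabeled segments exactly."""
        from foreco import dominance, clustering
        cfg, trees, _, truth = zero_noise_data
        segs = synthetic.generate_segments(cfg, truth)
        matrix = dominance.select_dominant(dominance.compute_ivi(trees), 5.0)
        labels = clustering.cluster_sites(matrix, n_randomizations=10, seed=0,
                                          k=cfg.n_clusters).labels
        train, predict = ecosystem.label_segments(segs, labels, min_cluster_size=3)
        feats = ecosystem.feature_columns(train)
        _, model = ecosystem.fit_evaluate(train, feats, folds=3, seed=0,
                                          n_estimators=100)
        out = ecosystem.predict_segments(model, predict, feats)
        predicted = out.set_index("segment_id")["ecosystem"]
        truth_labels = predicted.index.map(truth.segment_cluster)
        from foreco import adjusted_rand_index
        assert adjusted_rand_index(predicted.to_numpy(), truth_labels.to_numpy()) == 1.0
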