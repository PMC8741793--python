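"""Chi-square scorer, RFE/forest rankers, k-schedule, selection plans,
integration strategies."""

import numpy as np
import pytest
from scipy import stats

from adomics import (
    ClassifierSpec,
    OmicsTable,
    chi2_scores,
    generate_cohort,
    integrate,
    k_schedule,
    min_max_normalize,
    rfc_importance_rank,
    rfe_rank,
    select_plan_a,
    select_plan_b,
    threshold_select,
)
from adomics.select import FeatureRanking, SelectionConfig, rank_features
from adomics.simulate import SyntheticConfig


class TestChi2Scores:
    def test_even_split_scores_zero(self):
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        assert chi2_scores(X, np.array([1, 1, 0, 0]))[0] == pytest.approx(0.0)

    def test_hand_evaluated_aligned_column(self):
        # f_obs = (2, 0), f_exp = (1, 1) -> chi2 = 1 + 1 = 2
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        assert chi2_scores(X, np.array([1, 1, 0, 0]))[0] == pytest.approx(2.0)

    def test_matches_goodness_of_fit_oracle_on_random_matrices(self):
        # per feature, the score is the chi-square GoF statistic of the
        # class-wise feature mass against class-probability expectations
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, p = rng.integers(4, 30), rng.integers(1, 10)
            X = rng.random((n, p))
            y = rng.integers(0, 2, n)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 2, n)
            ours = chi2_scores(X, y)
            Y = np.column_stack([1 - y, y]).astype(float)
            for j in range(p):
                f_obs = Y.T @ X[:, j]
                f_exp = Y.mean(axis=0) * X[:, j].sum()
                expected = stats.chisquare(f_obs, f_exp).statistic
                assert ours[j] == pytest.approx(expected, abs=1e-10)

    def test_matches_sklearn_chi2(self):
        from sklearn.feature_selection import chi2 as sk_chi2

        rng = np.random.default_rng(1)
        X = rng.random((40, 15))
        y = rng.integers(0, 2, 40)
        np.testing.assert_allclose(chi2_scores(X, y), sk_chi2(X, y)[0], atol=1e-10)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.random((25, 6))
        y = rng.integers(0, 2, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(
            chi2_scores(X, y), chi2_scores(X[perm], y[perm]), atol=1e-12
        )

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((25, 6))
        y = rng.integers(0, 2, 25)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            chi2_scores(X, y)[perm], chi2_scores(X[:, perm], y), atol=1e-12
        )

    def test_column_scaling_absorbed_by_minmax(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 4))
        y = rng.integers(0, 2, 30)
        scaled = X.copy()
        scaled[:, 2] *= 37.5
        s1 = chi2_scores(min_max_normalize(X), y)
        s2 = chi2_scores(min_max_normalize(scaled), y)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_zero_mass_feature_scores_zero(self):
        X = np.array([[0.0, 1.0], [0.0, 0.0], [0.0, 2.0], [0.0, 1.0]])
        assert chi2_scores(X, np.array([1, 0, 1, 0]))[0] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            chi2_scores(np.array([[-1.0], [1.0]]), np.array([0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            chi2_scores(np.ones((4, 2)), np.array([1, 1, 1, 1]))


class TestRFE:
    def test_separating_feature_eliminated_last(self):
        # 6-sample set where only feature 'sep' separates the classes
        y = np.array([1, 1, 1, 0, 0, 0])
        rng = np.random.default_rng(5)
        X = np.column_stack([y * 2.0 - 1.0, rng.normal(0, 0.05, 6),
                             rng.normal(0, 0.05, 6)])
        ranking = rfe_rank(X, y, ["sep", "noise1", "noise2"],
                           ClassifierSpec("logistic_regression", {}, seed=0),
                           step_fraction=0.3)
        assert ranking.feature_ids[0] == "sep"

    def test_step_one_ranking_is_permutation(self):
        rng = np.random.default_rng(6)
        X = rng.random((12, 4))
        y = np.array([0, 1] * 6)
        ranking = rfe_rank(X, y, ["a", "b", "c", "d"],
                           ClassifierSpec("svm_linear", {}, seed=0),
                           step_fraction=0.2)
        assert sorted(ranking.feature_ids) == ["a", "b", "c", "d"]

    def test_identical_columns_adjacent_lexicographic(self):
        rng = np.random.default_rng(7)
        col = rng.random(10)
        X = np.column_stack([col, col, rng.random(10)])
        y = np.array([0, 1] * 5)
        ranking = rfe_rank(X, y, ["dup_b", "dup_a", "other"],
                           ClassifierSpec("logistic_regression", {}, seed=0),
                           step_fraction=0.3)
        ia, ib = ranking.feature_ids.index("dup_a"), ranking.feature_ids.index("dup_b")
        assert abs(ia - ib) == 1
        assert ia < ib  # lexicographically smaller ranks better on a tie

    def test_rbf_base_model_rejected_with_guidance(self):
        X = np.random.default_rng(8).random((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="linear"):
            rfe_rank(X, y, ["a", "b", "c"], ClassifierSpec("svm_rbf", {}, seed=0))


class TestForestImportance:
    def test_signal_ranked_above_null(self):
        cfg = SyntheticConfig(n_cases=50, n_controls=50, n_probes=40, n_taxa=2,
                              n_signal_probes=5, n_signal_taxa=0, probe_effect=2.0,
                              missing_transcriptome=0, missing_microbiota=0, seed=0)
        gaps = []
        for seed in range(10):
            cfg.seed = seed
            t, _m, y, g = generate_cohort(cfg)
            X = min_max_normalize(t.values)
            ranking = rfc_importance_rank(X, y.subset(t.sample_ids).labels,
                                          t.feature_ids, n_trees=60, seed=seed)
            pos = {f: i for i, f in enumerate(ranking.feature_ids)}
            sig = np.mean([pos[f] for f in g["signal_probes"]])
            null = np.mean([pos[f] for f in t.feature_ids
                            if f not in g["signal_probes"]])
            gaps.append(null - sig)
        assert np.mean(gaps) > 0
        assert sum(g > 0 for g in gaps) >= 9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        X = rng.random((30, 8))
        y = rng.integers(0, 2, 30)
        ids = [f"f{i}" for i in range(8)]
        r1 = rfc_importance_rank(X, y, ids, seed=4)
        r2 = rfc_importance_rank(X, y, ids, seed=4)
        assert r1.feature_ids == r2.feature_ids
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_pure_noise_no_spurious_dominance(self):
        rng = np.random.default_rng(10)
        maxima = []
        for seed in range(20):
            X = rng.random((60, 10))
            y = rng.integers(0, 2, 60)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 2, 60)
            r = rfc_importance_rank(X, y, [f"f{i}" for i in range(10)],
                                    n_trees=50, seed=seed)
            maxima.append(r.scores.max() / r.scores.mean())
        assert max(maxima) < 3.0

    def test_zero_trees_rejected(self):
        with pytest.raises(ValueError, match="n_trees"):
            rfc_importance_rank(np.ones((4, 2)), np.array([0, 1, 0, 1]),
                                ["a", "b"], n_trees=0)


class TestKSchedule:
    def test_study_start_and_floor_rule(self):
        ks = k_schedule(44608)
        assert ks[:3] == [44608, 40147, 36132]
        assert ks[-1] == 1
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_singleton(self):
        assert k_schedule(1) == [1]

    def test_ten(self):
        assert k_schedule(10) == [10, 9, 8, 7, 6, 5, 4, 3, 2, 1]


def _planted(n=160, p=150, n_signal=20, effect=1.5, seed=0):
    cfg = SyntheticConfig(n_cases=88, n_controls=72, n_probes=p, n_taxa=2,
                          n_signal_probes=n_signal, n_signal_taxa=0,
                          probe_effect=effect, missing_transcriptome=0,
                          missing_microbiota=0, seed=seed)
    t, _m, y, g = generate_cohort(cfg)
    return min_max_normalize(t.values), y.subset(t.sample_ids).labels, \
        t.feature_ids, set(g["signal_probes"])


class TestPlanB:
    def test_recovery_of_planted_signal(self):
        hits, ks = [], []
        for seed in range(5):
            X, y, ids, truth = _planted(seed=seed)
            res = select_plan_b(X, y, ids, ranker="chi2", n_folds=5,
                                model_spec=ClassifierSpec("svm_rbf", {}, seed=0),
                                seed=seed)
            ks.append(res.chosen_k)
            hits.append(len(res.selected_ids & truth) / len(truth))
        assert np.mean(hits) >= 0.9
        assert all(20 / 3 <= k <= 60 for k in ks)  # within a factor of 3 of 20

    def test_degenerate_schedule_selects_everything(self):
        X, y, ids, _ = _planted(p=30, n_signal=5)
        res = select_plan_b(X, y, ids, schedule=[30], seed=0)
        assert res.selected_ids == set(ids)
        assert res.chosen_k == 30

    def test_trace_bookkeeping_and_top_k_exactness(self):
        X, y, ids, _ = _planted(p=40, n_signal=5)
        schedule = [40, 20, 10, 5]
        res = select_plan_b(X, y, ids, schedule=schedule, seed=1)
        assert len(res.cv_trace) == len(schedule)
        ranking = rank_features(X, y, ids, "chi2")
        assert res.selected_order == ranking.top(res.chosen_k)


class TestPlanA:
    def test_intersection_subset_of_each_fold(self):
        X, y, ids, _ = _planted(p=50, n_signal=8)
        res = select_plan_a(X, y, ids, schedule=[50, 25, 12, 6], seed=2)
        for s in res.per_fold_sets:
            assert res.selected_ids <= s or res.fallback_used
        assert len(res.selected_ids) <= min(len(s) for s in res.per_fold_sets)

    def test_strong_signal_survives_intersection(self):
        X, y, ids, truth = _planted(p=60, n_signal=8, effect=2.5, seed=3)
        res = select_plan_a(X, y, ids, schedule=[60, 30, 16, 8], seed=3)
        assert truth <= res.selected_ids

    def test_duplicate_data_degenerates_to_single_fold_set(self):
        # k pinned to the number of strongly planted features: every outer
        # fold of the tripled data recovers the same set, so the
        # intersection equals any single fold's set
        X, y, ids, truth = _planted(n=160, p=30, n_signal=10, effect=3.0, seed=4)
        Xd = np.vstack([X] * 3)
        yd = np.concatenate([y] * 3)
        res = select_plan_a(Xd, yd, ids, schedule=[10], seed=4)
        for s in res.per_fold_sets:
            assert res.selected_ids == s
        assert res.selected_ids == truth


class TestThresholdSelect:
    def test_rescaled_floor(self):
        r = FeatureRanking(["a", "b", "c"], np.array([10.0, 9.5, 1.0]), "chi2")
        assert threshold_select(r, 0.95) == {"a", "b"}

    def test_floor_zero_keeps_all(self):
        r = FeatureRanking(["a", "b"], np.array([5.0, 0.1]), "chi2")
        assert threshold_select(r, 0.0) == {"a", "b"}

    def test_floor_one_unique_maximum(self):
        r = FeatureRanking(["a", "b"], np.array([5.0, 4.9]), "chi2")
        assert threshold_select(r, 1.0) == {"a"}

    def test_all_zero_scores_warn_empty(self):
        r = FeatureRanking(["a"], np.array([0.0]), "chi2")
        with pytest.warns(UserWarning, match="zero"):
            assert threshold_select(r, 0.5) == set()


def _two_modality_training_set(seed=0):
    cfg = SyntheticConfig(n_cases=60, n_controls=50, n_probes=80, n_taxa=60,
                          n_signal_probes=8, n_signal_taxa=6, probe_effect=1.5,
                          taxa_effect=4.0, missing_transcriptome=0,
                          missing_microbiota=0, seed=seed)
    t, m, y, g = generate_cohort(cfg)
    tn = OmicsTable(t.sample_ids, t.feature_ids, min_max_normalize(t.values),
                    "transcriptome")
    mn = OmicsTable(m.sample_ids, m.feature_ids, min_max_normalize(m.values),
                    "microbiota")
    return tn, mn, y.subset(t.sample_ids).labels, g


class TestIntegrate:
    def test_select_then_combine_width_85(self):
        t, m, y, _ = _two_modality_training_set()
        out = integrate(t, m, y, "select_then_combine",
                        transcriptome_config=SelectionConfig(n_features=35),
                        microbiota_config=SelectionConfig(n_features=35 + 15))
        assert out.X.shape[1] == 85
        assert len(out.feature_ids) == 85
        mods = [out.provenance[f] for f in out.feature_ids]
        assert mods.count("transcriptome") == 35
        assert mods.count("microbiota") == 50

    def test_transcriptome_only_reduces_to_single_modality(self):
        t, m, y, _ = _two_modality_training_set()
        cfg = SelectionConfig(n_features=10)
        out = integrate(t, m, y, "transcriptome_only", transcriptome_config=cfg)
        sel = out.selections["transcriptome"]
        assert set(out.feature_ids) == sel.selected_ids
        assert all(f in t.feature_ids for f in out.feature_ids)

    def test_combine_then_select_finds_both_modalities(self):
        t, m, y, g = _two_modality_training_set(seed=1)
        out = integrate(t, m, y, "combine_then_select",
                        combined_config=SelectionConfig(n_features=14))
        mods = set(out.provenance[f] for f in out.feature_ids)
        assert mods == {"transcriptome", "microbiota"}

    def test_no_config_keeps_all_features(self):
        t, m, y, _ = _two_modality_training_set()
        out = integrate(t, m, y, "microbiota_only")
        assert out.feature_ids == list(m.feature_ids)

    def test_unknown_strategy_rejected(self):
        t, m, y, _ = _two_modality_training_set()
        with pytest.raises(ValueError, match="unknown strategy"):
            integrate(t, m, y, "late_fusion")


class TestNoLeakage:
    def test_selection_ignores_rows_outside_training_partition(self):
        X, y, ids, _ = _planted(p=40, n_signal=5, seed=6)
        train = slice(0, 120)
        res1 = select_plan_b(X[train], y[train], ids, schedule=[40, 20, 10], seed=7)
        X_mut = X.copy()
        X_mut[120:] = 999.0  # mutate held-out rows only
        res2 = select_plan_b(X_mut[train], y[train], ids, schedule=[40, 20, 10], seed=7)
        assert res1.selected_order == res2.selected_order
        assert res1.cv_trace == res2.cv_trace
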