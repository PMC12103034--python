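"""Eigengene classifier: t-test calls, combinations, trees, exact CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexsig.classify import (
    EigengeneClassifier,
    ModuleProfile,
    classify_combination,
    classify_sample_single,
    clopper_pearson,
    compare_classifiers,
    fit_decision_tree,
    fit_disease_profile,
    percent,
    performance,
    project_sample_me,
    search_combinations,
)
from coexsig.modules import compute_eigengenes

from conftest import me_cohort


class TestClopperPearson:
    # every confidence bracket the study reports, as integer percents
    BRACKETS = [
        (8, 11, 39, 94), (34, 35, 85, 100), (11, 11, 72, 100), (9, 11, 48, 98),
        (28, 35, 63, 92), (32, 35, 77, 98), (9, 21, 22, 66), (12, 21, 34, 78),
        (8, 13, 32, 86), (23, 32, 53, 86), (17, 32, 35, 71), (16, 20, 56, 94),
        (14, 20, 46, 88),
    ]

    @pytest.mark.parametrize("k,n,lo,hi", BRACKETS)
    def test_reported_brackets(self, k, n, lo, hi):
        lower, upper = clopper_pearson(k, n)
        assert percent(lower) == lo
        assert percent(upper) == hi

    def test_all_successes_closed_form(self):
        lower, upper = clopper_pearson(11, 11)
        assert upper == 1.0
        assert lower == pytest.approx(0.025 ** (1 / 11), rel=1e-9)

    def test_zero_successes(self):
        lower, upper = clopper_pearson(0, 20)
        assert lower == 0.0
        assert upper < 0.2

    def test_ordering_invariant(self):
        for k, n, _, _ in self.BRACKETS:
            lo, hi = clopper_pearson(k, n)
            assert 0 <= lo <= k / n <= hi <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)


class TestCompareClassifiers:
    def test_reported_fisher_pvalues(self):
        assert compare_classifiers(23, 32, 17, 32) == pytest.approx(0.196, abs=5e-4)
        assert compare_classifiers(16, 20, 14, 20) == pytest.approx(0.716, abs=5e-4)

    def test_exhaustive_small_table(self):
        # [[1,0],[0,1]]: both tables in the support are equally likely
        assert compare_classifiers(1, 1, 0, 1) == pytest.approx(1.0)


class TestSingleModuleCall:
    def profile(self, n=35):
        return ModuleProfile(control_mean=0.0, control_sd=1.0, control_n=n,
                             patient_mean=2.0)

    def test_sample_at_control_mean_is_negative(self):
        p, call = classify_sample_single(self.profile(), 0.0)
        assert p == pytest.approx(1.0)
        assert call is False

    def test_far_sample_positive_with_tiny_p(self):
        p, call = classify_sample_single(self.profile(), 10.0)
        # closed form: t = -10*sqrt(35), df 34
        t = -10 * np.sqrt(35)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 34), rel=1e-9)
        assert p < 1e-10 and call is True

    def test_direction_gate_blocks_wrong_side(self):
        p, call = classify_sample_single(self.profile(), -10.0)
        assert p < 1e-10 and call is False

    def test_degenerate_sd_rejected(self):
        prof = ModuleProfile(0.0, 0.0, 35, 1.0)
        with pytest.raises(ValueError):
            classify_sample_single(prof, 1.0)


class TestFitDiseaseProfile:
    def test_summaries_match_direct_computation(self):
        me, status = me_cohort(delta=1.5, seed=1)
        prof = fit_disease_profile(me, status, [1, 2])
        ctrl = me.loc[status == "control", 1]
        case = me.loc[status == "case", 1]
        assert prof[1].control_mean == pytest.approx(ctrl.mean())
        assert prof[1].control_sd == pytest.approx(ctrl.std(ddof=1))
        assert prof[1].control_n == 35
        assert prof[1].patient_mean == pytest.approx(case.mean())

    def test_degenerate_controls_rejected(self):
        me = pd.DataFrame({1: [1.0, 1.0] + [0.0] * 4},
                          index=[f"s{i}" for i in range(6)])
        status = pd.Series(["case"] * 2 + ["control"] * 4, index=me.index)
        with pytest.raises(ValueError, match="degenerate"):
            fit_disease_profile(me, status, [1])

    def test_alpha_recorded_in_model(self):
        me, status = me_cohort(seed=2)
        model = EigengeneClassifier(me, status, [1], alpha=0.01)
        assert model.fit().model.alpha == 0.01

    def test_missing_module_rejected(self):
        me, status = me_cohort(seed=3)
        with pytest.raises(ValueError, match="absent"):
            fit_disease_profile(me, status, [99])


class TestCombination:
    def test_or_rule_truth_table(self):
        me, status = me_cohort(delta=3.0, seed=4)
        prof = fit_disease_profile(me, status, [1, 2])
        strong_case = {1: 5.0, 2: 0.0}
        assert classify_combination(prof, strong_case, [1, 2]) is True
        assert classify_combination(prof, {1: 0.0, 2: 0.0}, [1, 2]) is False
        with pytest.raises(ValueError):
            classify_combination(prof, strong_case, [])

    def test_or_monotonicity_exhaustive(self):
        """Adding a module never lowers sensitivity nor raises specificity."""
        me, status = me_cohort(delta=1.5, n_noise=2, seed=5)
        prof = fit_disease_profile(me, status, [1, 2, 3])
        truth = (status == "case").to_numpy()
        calls = {
            m: np.array([classify_sample_single(prof[m], v)[1] for v in me[m]])
            for m in (1, 2, 3)
        }
        for r in (1, 2):
            for base in itertools.combinations((1, 2, 3), r):
                joined = np.logical_or.reduce([calls[m] for m in base])
                for extra in (1, 2, 3):
                    wider = joined | calls[extra]
                    assert wider[truth].mean() >= joined[truth].mean()
                    assert (~wider[~truth]).mean() <= (~joined[~truth]).mean()


class TestDecisionTree:
    def test_separable_data_gives_root_only_perfect_tree(self):
        me = pd.DataFrame({1: np.r_[np.ones(8) * 3, np.zeros(12)],
                           2: np.random.default_rng(6).normal(size=20)})
        status = pd.Series(["case"] * 8 + ["control"] * 12)
        tree = fit_decision_tree(me, status)
        assert tree.module == 1
        preds = [tree.predict(me.iloc[i]) for i in range(20)]
        assert preds == [True] * 8 + [False] * 12

    def test_two_module_structure_beats_any_single_threshold(self):
        # positive only when BOTH MEs are high: needs both modules
        rng = np.random.default_rng(7)
        a = np.r_[rng.uniform(1, 2, 10), rng.uniform(-2, -1, 5), rng.uniform(1, 2, 5)]
        b = np.r_[rng.uniform(1, 2, 10), rng.uniform(1, 2, 5), rng.uniform(-2, -1, 5)]
        me = pd.DataFrame({1: a, 2: b})
        status = pd.Series(["case"] * 10 + ["control"] * 10)
        tree = fit_decision_tree(me, status)
        y = np.array([True] * 10 + [False] * 10)
        acc = np.mean([tree.predict(me.iloc[i]) == y[i] for i in range(20)])
        # exhaustive depth-1 oracle over every midpoint of either module
        best1 = 0.0
        for m in (1, 2):
            xs = np.sort(me[m].unique())
            for thr in (xs[:-1] + xs[1:]) / 2:
                for side in (True, False):
                    pred = (me[m] > thr) == side
                    best1 = max(best1, np.mean(pred.to_numpy() == y))
        assert acc > best1

    def test_refit_is_deterministic(self):
        me, status = me_cohort(delta=2.0, seed=8)
        t1 = fit_decision_tree(me[[1, 2]], status)
        t2 = fit_decision_tree(me[[1, 2]], status)
        assert t1.nodes() == t2.nodes()

    def test_single_class_rejected(self):
        me = pd.DataFrame({1: np.arange(5.0), 2: np.arange(5.0)})
        with pytest.raises(ValueError):
            fit_decision_tree(me, pd.Series(["control"] * 5))


class TestSearchCombinations:
    def test_strong_module_ranks_first(self):
        me, status = me_cohort(delta=3.0, n_noise=3, seed=9)
        table = search_combinations(me, status, [1, 2, 3, 4], max_k=2)
        assert table.iloc[0]["modules"] == (1,)

    def test_max_k_one_row_count(self):
        me, status = me_cohort(seed=10)
        table = search_combinations(me, status, [1, 2, 3], max_k=1)
        assert len(table) == 3

    def test_adding_noise_module_never_raises_specificity(self):
        me, status = me_cohort(delta=2.0, n_noise=2, seed=11)
        table = search_combinations(me, status, [1, 2, 3], max_k=3)
        spec = {row["modules"]: row["specificity"] for _, row in table.iterrows()}
        assert spec[(1, 2)] <= spec[(1,)]
        assert spec[(1, 2, 3)] <= spec[(1, 2)]


class TestPerformance:
    def test_reported_training_sensitivity(self):
        calls = pd.Series([True] * 8 + [False] * 3)
        truth = pd.Series([True] * 11)
        rep = performance(calls, truth, sides=("sensitivity",))
        assert percent(rep.sensitivity) == 73
        lo, hi = rep.sensitivity_ci
        assert (percent(lo), percent(hi)) == (39, 94)

    def test_reported_training_specificity(self):
        calls = pd.Series([True] + [False] * 34)
        truth = pd.Series([False] * 35)
        rep = performance(calls, truth, sides=("specificity",))
        assert percent(rep.specificity) == 97
        lo, hi = rep.specificity_ci
        assert (percent(lo), percent(hi)) == (85, 100)

    def test_family_rollup_or_semantics(self):
        idx = list("abcdef")
        calls = pd.Series([True, False, False, False, True, False], index=idx)
        truth = pd.Series([True, True, True, True, False, False], index=idx)
        fam = pd.Series(["f1", "f1", "f2", "f2", "f3", "f3"], index=idx)
        rep = performance(calls, truth, level="family", family_id=fam)
        # f1 positive (one affected member called), f2 negative; f3 is control-only
        assert (rep.k_sens, rep.n_sens) == (1, 2)
        assert (rep.k_spec, rep.n_spec) == (0, 1)

    def test_family_sensitivity_dominates_individual(self):
        me, status = me_cohort(delta=1.2, seed=12)
        fam = pd.Series(
            [f"f{i % 4}" for i in range(11)] + [f"cf{i}" for i in range(35)],
            index=me.index,
        )
        model = EigengeneClassifier(me, status, [1], family_id=fam)
        res = model.fit()
        ind = res.performance("individual")
        fam_rep = res.performance("family", sides=("sensitivity",))
        assert fam_rep.sensitivity >= ind.sensitivity

    def test_zero_denominator_rejected(self):
        calls = pd.Series([True, False])
        truth = pd.Series([True, True])
        with pytest.raises(ValueError):
            performance(calls, truth)


class TestProjection:
    def test_projecting_training_samples_reproduces_joint_me(self, detrended, scenario):
        _, _, truth = scenario
        labels = truth.gene_modules.loc[detrended.values.index].to_numpy()
        eig = compute_eigengenes(detrended.values, labels)
        projected = project_sample_me(eig, detrended.values)
        for k in eig.modules:
            diff = np.abs(projected[k].to_numpy() - eig.values[k].to_numpy())
            assert diff.max() < 0.05

    def test_control_mean_profile_maps_near_zero(self, detrended, scenario):
        _, _, truth = scenario
        labels = truth.gene_modules.loc[detrended.values.index].to_numpy()
        eig = compute_eigengenes(detrended.values, labels)
        mean_profile = detrended.values.mean(axis=1).to_frame("avg")
        projected = project_sample_me(eig, mean_profile)
        for k in eig.modules:
            assert abs(projected.loc["avg", k]) < 0.3

    def test_missing_genes_rejected(self, detrended, scenario):
        _, _, truth = scenario
        labels = truth.gene_modules.loc[detrended.values.index].to_numpy()
        eig = compute_eigengenes(detrended.values, labels)
        stub = detrended.values.iloc[:10]
        with pytest.raises(ValueError, match="missing"):
            project_sample_me(eig, stub)


class TestModelResultsApi:
    def test_fit_classify_summary_roundtrip(self):
        me, status = me_cohort(delta=2.0, seed=13)
        fam = pd.Series(["f0"] * 4 + ["f1"] * 7 + [f"c{i}" for i in range(35)],
                        index=me.index)
        model = EigengeneClassifier(me, status, [1, 2], family_id=fam)
        res = model.fit(rule="or_combination")
        cls = res.classify()
        assert set(cls.sample_table["call"].index) == set(me.index)
        assert set(cls.family_calls.index) <= set(fam)
        text = res.summary()
        assert "sensitivity" in text and "module" in text

    def test_tree_rule_needs_two_modules(self):
        me, status = me_cohort(seed=14)
        model = EigengeneClassifier(me, status, [1, 2, 3])
        with pytest.raises(ValueError):
            model.fit(rule="tree", modules=[1, 2, 3])
        res = model.fit(rule="tree", modules=[1, 2])
        assert res.tree is not None
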