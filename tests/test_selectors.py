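import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from ptsdpanel.core import FeatureMatrix, ValidationError
from ptsdpanel.selectors import (
    SelectorResult,
    fixed_list_select,
    fold_change_filter,
    pvalue_filter,
    qvalue_filter,
    rf_rank_select,
    svm_rfe_select,
    union_panels,
)


def make_matrix(seed=0, n=60, n_null=20, planted=None, types="protein"):
    """Gaussian matrix with optional planted standardized shifts.

    ``planted`` maps feature name -> d; half the rows are cases.
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    cols = list(planted) + [f"null_{i}" for i in range(n_null)]
    X = rng.normal(size=(n, len(cols)))
    y = pd.Series([1] * (n // 2) + [0] * (n - n // 2),
                  index=[f"s{i}" for i in range(n)])
    for j, (f, d) in enumerate(planted.items()):
        X[: n // 2, j] += d
    values = pd.DataFrame(X, index=y.index, columns=cols)
    fm = FeatureMatrix(values, {c: types for c in cols}, normalized=True)
    return fm, y


class TestPvalueFilter:
    def test_identical_groups_never_selected(self):
        values = pd.DataFrame(
            {"same": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=[f"s{i}" for i in range(6)],
        )
        fm = FeatureMatrix(values, {"same": "protein"})
        y = pd.Series([1, 1, 1, 0, 0, 0], index=values.index)
        res = pvalue_filter(fm, y, alpha=0.05)
        assert res.selected == []
        assert res.scores["same"] == pytest.approx(1.0)

    def test_large_effect_detected(self):
        # power of the two-sample t-test at d=2, n=30/30 is essentially 1
        fm, y = make_matrix(seed=1, planted={"big": 2.0})
        res = pvalue_filter(fm, y, alpha=0.05)
        assert "big" in res.selected

    def test_null_calibration_under_permutation(self):
        fm, y = make_matrix(seed=2, n=100, n_null=400)
        rng = np.random.default_rng(3)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = pvalue_filter(fm, y_perm, alpha=0.05)
        prop = len(res.selected) / fm.n_features
        se = np.sqrt(0.05 * 0.95 / fm.n_features)
        assert abs(prop - 0.05) < 3 * se

    def test_single_class_rejected(self):
        fm, y = make_matrix(seed=4)
        with pytest.raises(ValidationError):
            pvalue_filter(fm, pd.Series(1, index=y.index), alpha=0.05)


class TestQvalueFilter:
    def test_threshold_monotonicity(self):
        fm, y = make_matrix(seed=5, planted={"a": 1.5, "b": 1.0}, n_null=50)
        strict = set(qvalue_filter(fm, y, 0.01).selected)
        loose = set(qvalue_filter(fm, y, 0.10).selected)
        assert strict <= loose

    def test_single_feature_q_equals_p(self):
        fm, y = make_matrix(seed=6, planted={"only": 1.0}, n_null=0)
        q = qvalue_filter(fm, y, 0.5).scores["only"]
        p = pvalue_filter(fm, y, 0.5).scores["only"]
        assert q == pytest.approx(p)

    def test_false_discovery_proportion_bounded(self):
        # all-null matrix: BH controls the expected FDP at the threshold
        fdps = []
        for seed in range(20):
            fm, y = make_matrix(seed=seed, n=80, n_null=500)
            sel = qvalue_filter(fm, y, 0.10).selected
            fdps.append(len(sel) / 500)
        assert np.mean(fdps) <= 0.10


class TestFoldChangeFilter:
    def test_doubled_mean_is_one_log2_unit(self):
        values = pd.DataFrame(
            {"f": [2.0, 2.0, 2.0, 1.0, 1.0, 1.0]},
            index=[f"s{i}" for i in range(6)],
        )
        fm = FeatureMatrix(values, {"f": "metabolite"})
        y = pd.Series([1, 1, 1, 0, 0, 0], index=values.index)
        res = fold_change_filter(fm, y, min_abs_log2fc=1.0)
        assert res.scores["f"] == pytest.approx(1.0)
        assert res.selected == ["f"]

    def test_identical_means_never_selected(self):
        values = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=[f"s{i}" for i in range(6)],
        )
        fm = FeatureMatrix(values, {"f": "metabolite"})
        y = pd.Series([1, 1, 1, 0, 0, 0], index=values.index)
        assert fold_change_filter(fm, y, 0.1).selected == []

    def test_label_swap_preserves_magnitude(self):
        fm, y = make_matrix(seed=7, planted={"a": 1.0}, n_null=5)
        res1 = fold_change_filter(fm, y, 0.5)
        res2 = fold_change_filter(fm, 1 - y, 0.5)
        for f in res1.scores:
            assert res1.scores[f] == pytest.approx(res2.scores[f])

    def test_nonpositive_mean_skipped_with_warning(self, caplog):
        values = pd.DataFrame(
            {"neg": [-1.0, -2.0, 1.0, 2.0]}, index=["a", "b", "c", "d"]
        )
        fm = FeatureMatrix(values, {"neg": "metabolite"})
        y = pd.Series([1, 1, 0, 0], index=values.index)
        with caplog.at_level("WARNING"):
            res = fold_change_filter(fm, y, 0.5)
        assert "neg" not in res.scores
        assert any("neg" in r.message for r in caplog.records)


class TestSvmRfe:
    def test_planted_feature_survives(self):
        wins = 0
        for seed in range(20):
            fm, y = make_matrix(seed=seed, n=150, n_null=1,
                                planted={"signal": 3.0})
            res = svm_rfe_select(fm, y, step=1, top_k=1)
            wins += res.selected == ["signal"]
        assert wins >= 19  # >= 95% of seeds

    def test_matches_exhaustive_refit_oracle(self):
        """step=1 must reproduce an oracle that refits the SVM each round
        and removes the argmin squared weight (ties by feature id)."""
        for seed in range(5):
            fm, y = make_matrix(seed=seed, n=40, n_null=4,
                                planted={"a": 1.0, "b": 0.5})
            res = svm_rfe_select(fm, y, step=1, top_k=2)
            X = fm.values
            remaining = list(X.columns)
            while len(remaining) > 2:
                clf = SVC(kernel="linear", C=1.0)
                clf.fit(X[remaining].to_numpy(), y.to_numpy())
                w2 = np.square(np.asarray(clf.coef_).ravel())
                drop = min(zip(w2, remaining))[1]
                remaining.remove(drop)
            assert set(res.selected) == set(remaining)

    def test_top_k_equal_feature_count_returns_all(self):
        fm, y = make_matrix(seed=8, n_null=5)
        res = svm_rfe_select(fm, y, step=1, top_k=fm.n_features)
        assert set(res.selected) == set(fm.feature_ids)


class TestRfRank:
    def test_seed_determinism(self):
        fm, y = make_matrix(seed=9, planted={"a": 1.0}, n_null=10)
        r1 = rf_rank_select(fm, y, top_k=5, seed=42)
        r2 = rf_rank_select(fm, y, top_k=5, seed=42)
        assert r1.selected == r2.selected
        assert r1.scores == r2.scores

    def test_planted_feature_ranked_first(self):
        firsts = 0
        for seed in range(10):
            fm, y = make_matrix(seed=seed, n=150, n_null=100,
                                planted={"signal": 2.0})
            res = rf_rank_select(fm, y, top_k=1, seed=seed)
            firsts += res.selected == ["signal"]
        assert firsts >= 9

    def test_top_k_zero_empty(self):
        fm, y = make_matrix(seed=10, n_null=3)
        assert rf_rank_select(fm, y, top_k=0).selected == []


class TestUnion:
    def test_union_with_provenance(self):
        a = SelectorResult("A", ["f1", "f2"], {"f1": 0.1, "f2": 0.2})
        b = SelectorResult("B", ["f2", "f3"], {"f2": 0.3, "f3": 0.4})
        panel = union_panels([a, b])
        assert panel.feature_ids == ["f1", "f2", "f3"]
        assert panel.provenance["f2"] == {"A", "B"}
        assert panel.stage == "candidate"

    def test_single_result_identity(self):
        a = SelectorResult("A", ["x", "y"], {"x": 1.0, "y": 2.0})
        assert union_panels([a]).feature_ids == ["x", "y"]

    def test_disjoint_results_sum(self):
        a = SelectorResult("A", ["x"], {"x": 1.0})
        b = SelectorResult("B", ["y"], {"y": 1.0})
        assert len(union_panels([a, b])) == 2

    def test_union_superset_of_each_selection(self):
        results = [
            SelectorResult(f"S{i}", [f"f{j}" for j in range(i, i + 3)],
                           {f"f{j}": 1.0 for j in range(i, i + 3)})
            for i in range(4)
        ]
        panel = union_panels(results)
        assert len(panel) <= sum(len(r.selected) for r in results)
        for r in results:
            assert set(r.selected) <= set(panel.feature_ids)

    def test_fixed_list_selector_plugs_in(self, small_matrix):
        res = fixed_list_select(small_matrix, ["prot_a", "not_here"],
                                name="external_hypothesis")
        assert res.selected == ["prot_a"]
        panel = union_panels([res])
        assert panel.provenance["prot_a"] == {"external_hypothesis"}
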