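import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptsdpanel.core import FeatureMatrix, Panel, ValidationError, labels_for
from ptsdpanel.evaluate import (
    LeakageError,
    auc_mann_whitney,
    closest_to_01,
    compile_report,
    datatype_subpanels,
    predict_scores,
    roc_with_bootstrap,
    severity_correlation,
    single_marker_accuracy,
    stratified_performance,
    train_panel_model,
)
from ptsdpanel.pipeline import refinement_data
from conftest import make_record, tiny_sim_config
from ptsdpanel.simulate import generate_study


def random_instance(rng, max_n=20):
    n1 = int(rng.integers(1, max_n // 2))
    n0 = int(rng.integers(1, max_n // 2))
    # coarse grid scores to provoke plenty of ties
    scores = rng.integers(0, 6, size=n1 + n0) / 5.0
    y = np.array([1] * n1 + [0] * n0)
    return scores, y


class TestAucOracle:
    def test_equals_mann_whitney_on_random_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(500):
            s, y = random_instance(rng)
            assert roc_auc_score(y, s) == pytest.approx(
                auc_mann_whitney(s, y), abs=1e-12
            )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_flip_property(self, seed):
        rng = np.random.default_rng(seed)
        s, y = random_instance(rng)
        assert auc_mann_whitney(-s, y) == pytest.approx(
            1.0 - auc_mann_whitney(s, y)
        )


class TestRocWithBootstrap:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        roc = roc_with_bootstrap(s, y, n_bootstrap=50, seed=0)
        assert roc.auc == 1.0
        assert roc.ci_low == roc.ci_high == 1.0

    def test_all_tied_scores_give_half(self):
        s = np.full(10, 0.5)
        y = np.array([1] * 5 + [0] * 5)
        roc = roc_with_bootstrap(s, y, n_bootstrap=20, seed=0)
        assert roc.auc == 0.5

    def test_point_estimate_matches_pairwise_statistic(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s, y = random_instance(rng)
            roc = roc_with_bootstrap(s, y, n_bootstrap=2, seed=0)
            assert roc.auc == pytest.approx(auc_mann_whitney(s, y), abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([rng.normal(1, 1, 26), rng.normal(0, 1, 26)])
        y = np.array([1] * 26 + [0] * 26)
        roc = roc_with_bootstrap(s, y, n_bootstrap=500, seed=3)
        assert roc.ci_low <= roc.auc <= roc.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_with_bootstrap(np.ones(3), np.ones(3), n_bootstrap=5)


def brute_force_operating_point(s, y):
    """Independent exhaustive search over all distinct thresholds."""
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    best = None
    for t in list(np.unique(s)) + [np.max(s) + 1]:
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / n1
        fpr = (pred & (y == 0)).sum() / n0
        key = (np.hypot(fpr, 1 - tpr), -tpr, fpr)
        if best is None or key < best[0]:
            best = (key, tpr, 1 - fpr)
    return best[1], best[2]


class TestClosestTo01:
    def test_perfect_classifier(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        op = closest_to_01(s, y)
        assert op.sensitivity == op.specificity == op.accuracy == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            s, y = random_instance(rng)
            op = closest_to_01(s, y)
            sens, spec = brute_force_operating_point(s, y)
            assert op.sensitivity == pytest.approx(sens)
            assert op.specificity == pytest.approx(spec)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s, y = random_instance(rng)
            op = closest_to_01(s, y)
            n1, n0 = (y == 1).sum(), (y == 0).sum()
            expected = (op.sensitivity * n1 + op.specificity * n0) / (n1 + n0)
            assert op.accuracy == pytest.approx(expected)


class TestSeverityCorrelation:
    def test_affine_scores_give_unit_correlation(self):
        caps = pd.Series({"a": 50.0, "b": 70.0, "c": 90.0, "d": 110.0})
        scores = pd.Series({"a": 0.2, "b": 0.4, "c": 0.6, "d": 0.8})
        r, p = severity_correlation(scores, caps)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        caps = pd.Series({"a": 50.0, "b": 70.0, "c": 90.0})
        scores = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        with pytest.raises(ValidationError):
            severity_correlation(scores, caps)

    def test_needs_three_cases(self):
        with pytest.raises(ValidationError):
            severity_correlation(pd.Series({"a": 0.1, "b": 0.9}),
                                 pd.Series({"a": 50.0, "b": 60.0}))


@pytest.fixture(scope="module")
def trained_setup():
    """Planted study, model trained on discovery + recall, validation scores."""
    study = generate_study(tiny_sim_config(seed=21, severity_coupling=1.0))
    panel = Panel(feature_ids=study.truth_ids)
    disc = study.matrices["discovery"]
    combined = FeatureMatrix(
        pd.concat([disc.values, study.matrices["recall"].values]),
        dict(disc.feature_types),
    )
    model = train_panel_model(combined, study.metadata, panel, seed=3)
    val = study.matrices["validation"]
    y_val = labels_for(study.records_for("validation"),
                       sample_ids=val.sample_ids)
    scores = predict_scores(model, val, list(y_val.index))
    return study, panel, combined, model, val, y_val, scores


class TestPanelModel:
    def test_scores_are_probabilities(self, trained_setup):
        *_, scores = trained_setup
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_determinism(self, trained_setup):
        study, panel, combined, model, val, y_val, scores = trained_setup
        model2 = train_panel_model(combined, study.metadata, panel, seed=3)
        scores2 = predict_scores(model2, val, list(y_val.index))
        pd.testing.assert_series_equal(scores, scores2)

    def test_duplicated_sample_row_scores_identically(self, trained_setup):
        *_, model, val, y_val, scores = trained_setup[2:]
        sid = val.sample_ids[0]
        values = pd.concat(
            [val.values, val.values.loc[[sid]].rename(index={sid: "copy"})]
        )
        doubled = FeatureMatrix(values, dict(val.feature_types))
        out = predict_scores(model, doubled, [sid, "copy"])
        assert out.loc[sid] == out.loc["copy"]

    def test_planted_panel_separates_validation(self, trained_setup):
        *_, y_val, scores = trained_setup
        assert auc_mann_whitney(scores.to_numpy(), y_val.to_numpy()) > 0.85

    def test_leakage_guard(self, trained_setup):
        study, panel, combined, *_ = trained_setup
        with pytest.raises(LeakageError):
            train_panel_model(combined, study.metadata, panel, seed=3,
                              validation_sample_ids=[combined.sample_ids[0]])

    def test_missing_panel_feature_named(self, trained_setup):
        study, panel, combined, model, val, *_ = trained_setup
        crippled = val.subset_features(val.feature_ids[:3])
        with pytest.raises(KeyError):
            predict_scores(model, crippled)

    def test_null_study_scores_near_chance(self):
        study = generate_study(tiny_sim_config(seed=23,
                                               effect_sizes=[0.0] * 6))
        panel = Panel(feature_ids=study.truth_ids)
        disc = study.matrices["discovery"]
        combined = FeatureMatrix(
            pd.concat([disc.values, study.matrices["recall"].values]),
            dict(disc.feature_types),
        )
        model = train_panel_model(combined, study.metadata, panel, seed=1)
        val = study.matrices["validation"]
        y_val = labels_for(study.records_for("validation"),
                           sample_ids=val.sample_ids)
        scores = predict_scores(model, val, list(y_val.index))
        auc = auc_mann_whitney(scores.to_numpy(), y_val.to_numpy())
        assert abs(auc - 0.5) < 0.25  # ±3 MC SE at n=26/26


class TestStratifiedAndSubpanels:
    def test_full_cohort_stratum_matches_unstratified(self, trained_setup):
        study, *_ , y_val, scores = trained_setup[:1] + trained_setup[2:]
        val_records = study.records_for("validation")
        res = stratified_performance(scores, val_records,
                                     strata={"all": "within"},
                                     n_bootstrap=20, seed=0)
        full = roc_with_bootstrap(scores, y_val, n_bootstrap=20, seed=0)
        assert res["all"].roc.auc == pytest.approx(full.auc)

    def test_cases_only_stratum_not_evaluable(self):
        records = [
            make_record(sample_id=f"v{i}", cohort="validation", label="ptsd",
                        caps_total=70.0, ethnicity="nh_other")
            for i in range(3)
        ]
        scores = pd.Series({f"v{i}": 0.8 for i in range(3)})
        res = stratified_performance(scores, records,
                                     strata={"ethnicity:nh_other": "within"},
                                     n_bootstrap=10)
        assert res["ethnicity:nh_other"].roc is None
        assert res["ethnicity:nh_other"].reason

    def test_severity_coupled_scores_track_caps(self, trained_setup):
        study, *_ , y_val, scores = trained_setup[:1] + trained_setup[2:]
        case_ids = [s for s in y_val.index if y_val[s] == 1]
        caps = pd.Series({r.sample_id: r.caps_total
                          for r in study.records_for("validation")})
        r, _ = severity_correlation(scores.loc[case_ids], caps)
        assert r > 0.0

    def test_datatype_subpanels_cover_panel_types(self, trained_setup):
        study, panel, combined, model, val, *_ = trained_setup
        res = datatype_subpanels(combined, study.metadata, panel, val,
                                 seed=0, n_trees=50, n_bootstrap=10)
        types = set(combined.types_of(panel.feature_ids).values())
        assert set(res) == types
        for roc in res.values():
            assert 0.0 <= roc.auc <= 1.0


class TestSingleMarkerAccuracy:
    def test_perfect_marker(self):
        values = pd.DataFrame({"m": [5.0, 4.0, 1.0, 0.0]},
                              index=["a", "b", "c", "d"])
        fm = FeatureMatrix(values, {"m": "protein"})
        y = pd.Series([1, 1, 0, 0], index=values.index)
        acc = single_marker_accuracy(fm, y, Panel(feature_ids=["m"]))
        assert acc["m"] == 1.0

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=20)
        y = pd.Series((rng.random(20) > 0.5).astype(int),
                      index=[f"s{i}" for i in range(20)])
        y.iloc[0], y.iloc[1] = 1, 0  # ensure both classes
        fm1 = FeatureMatrix(
            pd.DataFrame({"m": v}, index=y.index), {"m": "physiological"}
        )
        fm2 = FeatureMatrix(
            pd.DataFrame({"m": -v}, index=y.index), {"m": "physiological"}
        )
        p = Panel(feature_ids=["m"])
        assert single_marker_accuracy(fm1, y, p) == single_marker_accuracy(
            fm2, y, p
        )


class TestReport:
    def test_json_round_trip(self, trained_setup, tmp_path):
        from ptsdpanel.io import read_json, write_json

        *_, y_val, scores = trained_setup
        roc = roc_with_bootstrap(scores, y_val, n_bootstrap=20, seed=0)
        op = closest_to_01(scores, y_val)
        report = compile_report(roc, op, (0.4, 0.03), panel_size=6)
        write_json(report.to_dict(), tmp_path / "r.json")
        back = read_json(tmp_path / "r.json")
        assert back["roc"]["auc"] == pytest.approx(roc.auc)
        assert back["operating_point"]["accuracy"] == pytest.approx(op.accuracy)
        assert back["severity_correlation"]["r"] == pytest.approx(0.4)

    def test_summary_renders_without_optional_sections(self, trained_setup):
        *_, y_val, scores = trained_setup
        roc = roc_with_bootstrap(scores, y_val, n_bootstrap=20, seed=0)
        op = closest_to_01(scores, y_val)
        report = compile_report(roc, op, (0.4, 0.03), panel_size=6)
        text = report.summary()
        assert "AUC" in text and "accuracy" in text.lower()
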