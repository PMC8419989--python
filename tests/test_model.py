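"""Diagnostic model: metrics, CV, bootstrap, balanced-RF behaviour."""

import numpy as np
import pytest

from conftest import PHENOTYPE_5
from lesionrad.model import (
    MMRFModel, ModelBundle, auc_rsd, bootstrap_evaluate, compute_metrics,
    cross_validate, train_balanced_rf)
from lesionrad.synthetic import SynthConfig, generate_feature_cohort


def cells(ms3, nmo3, ms15, nmo15):
    return {("MS", "3T"): ms3, ("NMO", "3T"): nmo3,
            ("MS", "1.5T"): ms15, ("NMO", "1.5T"): nmo15}


class TestMetrics:
    def test_perfect_scores(self):
        m = compute_metrics([0.9, 0.8, 0.1, 0.2], ["NMO", "NMO", "MS", "MS"])
        assert m == {"auc": 1.0, "accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_null_scores_auc_near_half(self, rng):
        labels = np.where(rng.random(2000) < 0.3, "NMO", "MS")
        m = compute_metrics(rng.random(2000), labels)
        assert abs(m["auc"] - 0.5) < 0.05

    def test_hard_predictor_auc_equals_balanced_accuracy(self, rng):
        # provable identity, asserted on random confusion matrices
        for _ in range(200):
            tp, fn, tn, fp = rng.integers(1, 40, size=4)
            scores = np.concatenate([np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)])
            labels = np.array(["NMO"] * (tp + fn) + ["MS"] * (tn + fp))
            m = compute_metrics(scores, labels)
            assert m["auc"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.5], ["MS"])


class TestAucRSD:
    def test_zero_dispersion(self):
        assert auc_rsd([0.8, 0.8, 0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_two_folds(self):
        # {0.9, 0.7}: mean 0.8, sample SD (ddof=1) ~0.1414, RSD ~0.1768
        assert auc_rsd([0.9, 0.7]) == pytest.approx(0.17677669529663687, abs=1e-12)

    def test_scale_invariance(self, rng):
        aucs = rng.uniform(0.5, 1.0, size=10)
        assert auc_rsd(aucs) == pytest.approx(auc_rsd(3.7 * aucs), abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            auc_rsd([0.0, 0.0])


class TestBalancedRF:
    def test_separable_data_training_auc_one(self, rng):
        cfg = SynthConfig(n_features=4, n_discriminative=2, effect_size=8.0, seed=0)
        tab = generate_feature_cohort(cfg)
        bundle = train_balanced_rf(tab, tab.feature_names[:2], seed=0, n_trees=100)
        m = compute_metrics(bundle.predict_scores(tab), tab.labels)
        assert m["auc"] == 1.0

    def test_same_seed_identical_scores(self, cohort):
        a = train_balanced_rf(cohort, PHENOTYPE_5, seed=3, n_trees=50)
        b = train_balanced_rf(cohort, PHENOTYPE_5, seed=3, n_trees=50)
        assert (a.predict_scores(cohort) == b.predict_scores(cohort)).all()

    def test_prior_neutrality_out_of_sample(self):
        # label-independent features, 80/20 imbalance: mean predicted
        # positive-class score stays near 0.5, not the 0.2 prior
        train = generate_feature_cohort(SynthConfig(
            n_per_class_per_scanner=cells(100, 25, 100, 25), n_features=8,
            n_discriminative=0, effect_size=0.0, seed=5))
        fresh = generate_feature_cohort(SynthConfig(
            n_per_class_per_scanner=cells(100, 25, 100, 25), n_features=8,
            n_discriminative=0, effect_size=0.0, seed=6))
        bundle = train_balanced_rf(train, train.feature_names, seed=0, n_trees=150)
        assert abs(bundle.predict_scores(fresh).mean() - 0.5) < 0.05

    def test_single_class_or_empty_phenotype_rejected(self, cohort):
        with pytest.raises(ValueError):
            train_balanced_rf(cohort, [], seed=0)
        single = cohort.subset(cohort.frame.index[cohort.labels == "MS"])
        with pytest.raises(ValueError):
            train_balanced_rf(single, PHENOTYPE_5, seed=0)

    def test_bundle_serialization_round_trips_predictions(self, cohort, tmp_path):
        bundle = train_balanced_rf(cohort, PHENOTYPE_5, seed=1, n_trees=50)
        path = tmp_path / "model.bin"
        bundle.save(path)
        back = ModelBundle.load(path)
        assert (back.predict_scores(cohort) == bundle.predict_scores(cohort)).all()
        assert back.phenotype == bundle.phenotype


class TestCrossValidate:
    def test_planted_cohort_reaches_high_auc(self, cohort):
        rep = cross_validate(cohort, PHENOTYPE_5, k=10, seed=0, n_trees=150)
        assert rep.auc_mean > 0.85
        assert rep.auc_rsd == pytest.approx(rep.auc_std / rep.auc_mean, abs=1e-12)
        assert rep.auc.ci_low <= rep.auc_mean <= rep.auc.ci_high

    def test_k_larger_than_minority_rejected(self, cohort):
        with pytest.raises(ValueError):
            cross_validate(cohort, PHENOTYPE_5, k=50, seed=0)


class TestBootstrap:
    def test_perfect_classifier_reports_one_with_zero_spread(self):
        cfg = SynthConfig(n_features=4, n_discriminative=2, effect_size=10.0, seed=1)
        tab = generate_feature_cohort(cfg)
        bundle = train_balanced_rf(tab, tab.feature_names[:2], seed=0, n_trees=100)
        rep = bootstrap_evaluate(bundle, tab, B=50, seed=0)
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            ms = getattr(rep, name)
            assert ms.mean == pytest.approx(1.0, abs=1e-12)
            assert ms.std == pytest.approx(0.0, abs=1e-12)

    def test_single_resample_flagged(self, cohort, fitted):
        rep = bootstrap_evaluate(fitted.bundle, cohort, B=1, seed=0)
        assert rep.n_resamples == 1
        assert rep.auc_std == 0.0
        assert rep.flags

    def test_bootstrap_mean_tracks_point_estimate(self, split, fitted):
        _, test = split
        point = compute_metrics(fitted.bundle.predict_scores(test), test.labels)
        rep = bootstrap_evaluate(fitted.bundle, test, B=1000, seed=0)
        assert abs(rep.auc_mean - point["auc"]) < 0.02

    def test_report_json_round_trip_preserves_rsd_identity(self, fitted, tmp_path):
        rep = fitted.cv_report
        rep.to_json(tmp_path / "rep.json")
        from lesionrad.model import EvalReport

        back = EvalReport.from_json(tmp_path / "rep.json")
        assert back.auc_rsd == pytest.approx(back.auc_std / back.auc_mean, abs=1e-12)
        assert back.to_dict() == rep.to_dict()


class TestModelSurface:
    def test_fit_returns_results_with_summary(self, fitted):
        text = fitted.summary()
        assert "Random Forest" in text
        assert "edss" in text
        assert "auc" in text

    def test_monotone_in_planted_effect_size(self):
        means = []
        for d in (0.0, 0.75, 1.5):
            tab = generate_feature_cohort(SynthConfig(
                n_per_class_per_scanner=cells(30, 30, 30, 30), n_features=4,
                n_discriminative=2, effect_size=d, seed=17))
            rep = cross_validate(tab, tab.feature_names[:2], k=5, seed=4, n_trees=100)
            means.append(rep.auc_mean)
        assert means[0] - 0.03 <= means[1] <= means[2] + 0.03
        assert means[2] > means[0]
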