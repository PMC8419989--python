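"""Multi-level feature selection: rank filters and pyramid RF-SFS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lesionrad.selection import (
    Phenotype, pyramid_select, rank_sum_test, relevance_filter, rf_sfs,
    robustness_filter, univariate_auc, univariate_records)
from lesionrad.synthetic import SynthConfig, generate_feature_cohort
from lesionrad.tables import FeatureTable


def cells(ms3, nmo3, ms15, nmo15):
    return {("MS", "3T"): ms3, ("NMO", "3T"): nmo3,
            ("MS", "1.5T"): ms15, ("NMO", "1.5T"): nmo15}


class TestRankSum:
    def test_exact_small_sample_by_enumeration(self):
        # [1,2] vs [3,4]: of the C(4,2)=6 equally likely rank assignments only
        # the two extremes are as or more extreme -> two-sided p = 2/6
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_with_ties_give_p_one(self):
        _, p = rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_rank_sum_statistic_value(self):
        w, _ = rank_sum_test([1, 2], [3, 4])
        assert w == 3.0  # ranks 1 + 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_null_rejection_rate_near_nominal(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            _, p = rank_sum_test(rng.standard_normal(50), rng.standard_normal(50))
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.025

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(25) + 0.5
        _, p0 = rank_sum_test(x, y)
        for f in (np.exp, np.arctan, lambda v: v**3):
            _, p = rank_sum_test(f(x), f(y))
            assert p == pytest.approx(p0, abs=1e-12)


class TestUnivariateAUC:
    def test_perfect_separation(self):
        assert univariate_auc([0, 0, 1, 1], ["MS", "MS", "NMO", "NMO"]) == 1.0

    def test_pair_counting_oracle_with_ties(self):
        # x=[1,2,3] (MS) vs y=[2,3,4] (NMO): 6 wins + 2 ties of 9 pairs
        values = [1, 2, 3, 2, 3, 4]
        labels = ["MS"] * 3 + ["NMO"] * 3
        wins = ties = 0
        for a, b in itertools.product(values[:3], values[3:]):
            wins += b > a
            ties += b == a
        assert (wins + 0.5 * ties) / 9 == pytest.approx(7 / 9)
        assert univariate_auc(values, labels, orient=False) == pytest.approx(7 / 9)

    def test_null_feature_near_half(self, rng):
        labels = np.where(rng.random(4000) < 0.5, "NMO", "MS")
        auc = univariate_auc(rng.standard_normal(4000), labels, orient=False)
        assert abs(auc - 0.5) < 0.05

    def test_orientation_folds_auc(self, rng):
        values = [0, 0, 1, 1]
        labels = ["NMO", "NMO", "MS", "MS"]
        assert univariate_auc(values, labels, orient=False) == 0.0
        assert univariate_auc(values, labels, orient=True) == 1.0


@pytest.fixture(scope="module")
def filter_cohort():
    return generate_feature_cohort(SynthConfig(
        n_per_class_per_scanner=cells(40, 40, 40, 40), n_features=15,
        n_discriminative=2, effect_size=1.5, n_scanner_shifted=2, shift_size=3.0,
        seed=21))


class TestFilters:
    def test_scanner_shifted_features_removed(self, filter_cohort):
        from lesionrad.synthetic import planted_feature_names

        kept, pvals = robustness_filter(filter_cohort)
        shifted = [c for c in filter_cohort.feature_names
                   if abs(filter_cohort.frame.loc[filter_cohort.scanner == "3T", c].mean()
                          - filter_cohort.frame.loc[filter_cohort.scanner == "1.5T", c].mean()) > 1.5]
        assert shifted and not set(shifted) & set(kept)

    def test_identical_strata_kept_and_alpha_zero_keeps_all(self, filter_cohort):
        kept, _ = robustness_filter(filter_cohort, alpha=0.0)
        assert set(kept) == set(filter_cohort.feature_names)

    def test_planted_features_pass_relevance(self, filter_cohort):
        from lesionrad.synthetic import planted_feature_names

        cfg = SynthConfig(n_per_class_per_scanner=cells(40, 40, 40, 40),
                          n_features=15, n_discriminative=2, effect_size=1.5,
                          n_scanner_shifted=2, shift_size=3.0, seed=21)
        kept, _ = relevance_filter(filter_cohort)
        assert set(planted_feature_names(cfg)) <= set(kept)

    def test_alpha_one_keeps_everything(self, filter_cohort):
        kept, _ = relevance_filter(filter_cohort, alpha=1.0)
        assert set(kept) == set(filter_cohort.feature_names)

    def test_filters_commute_with_monotone_maps(self, filter_cohort):
        col = filter_cohort.feature_names[0]
        mapped = filter_cohort.frame.copy()
        mapped[col] = np.exp(mapped[col] / 3.0)
        t2 = FeatureTable(mapped)
        _, p_a = relevance_filter(filter_cohort, candidates=[col])
        _, p_b = relevance_filter(t2, candidates=[col])
        assert p_a[col] == pytest.approx(p_b[col], abs=1e-12)

    def test_univariate_records_fields(self, filter_cohort):
        recs = univariate_records(filter_cohort, candidates=filter_cohort.feature_names[:3])
        for r in recs:
            assert 0 <= r.p_robust <= 1 and 0 <= r.p_class <= 1
            assert 0 <= r.auc_uni <= 1


def make_table(X, labels, names):
    n = len(labels)
    frame = pd.DataFrame(X, columns=names)
    frame.index = [f"S{i}" for i in range(n)]
    frame.index.name = "subject_id"
    frame.insert(0, "duration", 10.0)
    frame.insert(0, "edss", 2.0)
    frame.insert(0, "sex", 0)
    frame.insert(0, "age", 40.0)
    frame.insert(0, "scanner", ["3T", "1.5T"] * (n // 2))
    frame.insert(0, "diagnosis", labels)
    return FeatureTable(frame)


class TestRFSFS:
    @pytest.fixture(scope="module")
    def planted_table(self):
        rng = np.random.default_rng(8)
        n = 80
        labels = ["MS"] * 40 + ["NMO"] * 40
        X = rng.standard_normal((n, 12))
        X[:, 5] += np.where(np.array(labels) == "NMO", 3.0, -3.0)  # separator
        names = [f"H-T2-original-glcm-{s}" for s in
                 "ABCDEFGHIJKL"]
        return make_table(X, labels, names), names

    def test_perfect_feature_selected_first(self, planted_table):
        table, names = planted_table
        phen = rf_sfs(table, names, cap=4, seed=0)
        assert phen.features[0] == names[5]
        assert phen.trace[0] > 0.95

    def test_cap_one_returns_best_single_feature(self, planted_table):
        table, names = planted_table
        phen = rf_sfs(table, names, cap=1, seed=0)
        assert phen.features == [names[5]]
        assert len(phen.trace) == 1

    def test_duplicate_column_enters_once_with_deterministic_tie_break(self, planted_table):
        table, names = planted_table
        frame = table.frame.copy()
        frame["H-T2-original-glcm-Z"] = frame[names[5]]  # exact duplicate
        t2 = FeatureTable(frame)
        phen = rf_sfs(t2, names + ["H-T2-original-glcm-Z"], cap=3, seed=0)
        # the earlier (lower-id) duplicate wins the tie and the copy never helps
        assert phen.features[0] == names[5]
        assert "H-T2-original-glcm-Z" not in phen.features

    def test_trace_reproducible_bit_exact(self, planted_table):
        table, names = planted_table
        a = rf_sfs(table, names, cap=4, seed=42)
        b = rf_sfs(table, names, cap=4, seed=42)
        assert a.features == b.features
        assert a.trace == b.trace

    def test_phenotype_is_argmax_prefix(self, planted_table):
        table, names = planted_table
        phen = rf_sfs(table, names, cap=6, seed=1, patience=None)
        assert len(phen.features) == int(np.argmax(phen.full_trace)) + 1
        assert phen.trace[-1] == max(phen.full_trace)

    def test_empty_candidates_and_bad_cap_rejected(self, planted_table):
        table, _ = planted_table
        with pytest.raises(ValueError):
            rf_sfs(table, [], cap=2)
        with pytest.raises(ValueError):
            rf_sfs(table, ["H-T2-original-glcm-A"], cap=0)


class TestPyramid:
    @pytest.fixture(scope="module")
    def pyramid_run(self):
        cfg = SynthConfig(n_per_class_per_scanner=cells(15, 15, 15, 15),
                          n_features=20, n_discriminative=4, effect_size=1.8,
                          n_scanner_shifted=2, shift_size=3.0,
                          clinical_effect_size=1.5, seed=2)
        table = generate_feature_cohort(cfg)
        return cfg, table, pyramid_select(table, seed=2)

    def test_selection_chain_is_nested_for_radiomic_features(self, pyramid_run):
        _, table, res = pyramid_run
        prelim = {f for mod in ("T2", "MPR") for f in res.preliminary[mod].features}
        radiomic_final = {f for f in res.phenotype.features if f.startswith("H-")}
        assert radiomic_final <= prelim | set(res.preliminary["clinical"].features)
        assert prelim <= set(res.relevant_survivors) <= set(res.robust_survivors)

    def test_preliminary_phenotypes_are_per_modality(self, pyramid_run):
        _, _, res = pyramid_run
        assert all(f.startswith("H-T2-") for f in res.preliminary["T2"].features)
        assert all(f.startswith("H-MPR-") for f in res.preliminary["MPR"].features)
        assert set(res.preliminary["clinical"].features) <= {"age", "sex", "edss", "duration"}

    def test_clinical_signal_survives_fusion(self, pyramid_run):
        # EDSS carries a planted d=1.5 class difference, so the fusion stage
        # should retain it
        _, _, res = pyramid_run
        assert "edss" in res.phenotype.features

    def test_phenotype_round_trips_through_json_dict(self, pyramid_run):
        _, _, res = pyramid_run
        d = res.phenotype.to_dict()
        back = Phenotype.from_dict(d)
        assert back.features == res.phenotype.features
        assert back.trace == res.phenotype.trace
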