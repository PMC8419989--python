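"""Synthetic cohort generator: determinism, planted-effect calibration, splits."""

import numpy as np
import pytest

from lesionrad.features.extract import extract_cohort
from lesionrad.selection import rank_sum_test, relevance_filter
from lesionrad.synthetic import (
    SynthConfig, generate_feature_cohort, generate_volume_cohort,
    planted_feature_names, split_train_test)


def cells(ms3, nmo3, ms15, nmo15):
    return {("MS", "3T"): ms3, ("NMO", "3T"): nmo3,
            ("MS", "1.5T"): ms15, ("NMO", "1.5T"): nmo15}


class TestConfig:
    def test_default_cells_match_study_design(self):
        cfg = SynthConfig()
        assert cfg.n_per_class_per_scanner == cells(38, 30, 40, 8)

    def test_zero_subjects_in_a_class_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            SynthConfig(n_per_class_per_scanner=cells(10, 0, 10, 0))

    def test_lesion_radius_exceeding_volume_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            SynthConfig(shape=(16, 16, 16), lesion_radius_range_mm=(3.0, 10.0))

    @pytest.mark.parametrize("bad", [
        dict(effect_size=-1.0), dict(block_correlation=1.0), dict(n_features=-1)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SynthConfig(**bad)

    def test_json_round_trip(self):
        cfg = SynthConfig(n_features=12, effect_size=0.7, seed=9)
        assert SynthConfig.from_dict(cfg.to_dict()) == cfg


class TestFeatureCohort:
    def test_seed_determinism_bit_exact(self):
        a = generate_feature_cohort(SynthConfig(seed=7)).frame
        b = generate_feature_cohort(SynthConfig(seed=7)).frame
        assert a.equals(b)

    def test_structure_and_naming(self):
        tab = generate_feature_cohort(SynthConfig(n_features=10, seed=0))
        assert tab.n_subjects == 116
        assert len(tab.feature_names) == 20
        assert all(c.startswith(("H-T2-", "H-MPR-")) for c in tab.feature_names)
        assert list(tab.frame.columns[:6]) == ["diagnosis", "scanner", "age",
                                               "sex", "edss", "duration"]
        assert tab.labels.isin(["MS", "NMO"]).all()
        assert ((tab.clinical["edss"] * 2) % 1 == 0).all()
        assert tab.clinical["edss"].between(0, 10).all()

    def test_planted_effect_calibration(self):
        # large n so the sampling error of the realized d is well below the band
        cfg = SynthConfig(n_per_class_per_scanner=cells(750, 750, 750, 750),
                          n_features=20, n_discriminative=10, effect_size=1.2, seed=0)
        tab = generate_feature_cohort(cfg)
        planted = set(planted_feature_names(cfg))
        lab = tab.labels
        for col in tab.feature_names:
            a = tab.frame.loc[lab == "MS", col]
            b = tab.frame.loc[lab == "NMO", col]
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
            d = (b.mean() - a.mean()) / sp
            target = 1.2 if col in planted else 0.0
            assert abs(d - target) < 0.15, col

    def test_scanner_shift_is_planted(self):
        cfg = SynthConfig(n_per_class_per_scanner=cells(100, 100, 100, 100),
                          n_features=10, n_discriminative=2, effect_size=0.0,
                          n_scanner_shifted=2, shift_size=2.0, seed=1)
        tab = generate_feature_cohort(cfg)
        shifted = [c for c in tab.feature_names
                   if abs(tab.frame.loc[tab.scanner == "3T", c].mean()
                          - tab.frame.loc[tab.scanner == "1.5T", c].mean()) > 1.0]
        assert len(shifted) == 2

    def test_null_configuration_rejects_at_nominal_rate(self):
        # effect 0 / shift 0: relevance filter keeps ~5% of features at alpha=0.05
        kept = total = 0
        for seed in range(20):
            cfg = SynthConfig(n_per_class_per_scanner=cells(30, 30, 30, 30),
                              n_features=100, n_discriminative=0, effect_size=0.0,
                              n_scanner_shifted=0, seed=seed)
            tab = generate_feature_cohort(cfg)
            k, _ = relevance_filter(tab)
            kept += len(k)
            total += len(tab.feature_names)
        assert abs(kept / total - 0.05) < 0.02


class TestVolumeCohort:
    CFG = dict(n_per_class_per_scanner=cells(2, 2, 0, 1), shape=(16, 16, 16),
               lesion_radius_range_mm=(2.5, 4.0))

    def test_seed_determinism_voxel_exact(self):
        a = generate_volume_cohort(SynthConfig(seed=5, **self.CFG))
        b = generate_volume_cohort(SynthConfig(seed=5, **self.CFG))
        for pa, pb in zip(a, b):
            assert (pa.t2 == pb.t2).all() and (pa.mpr == pb.mpr).all()
            assert (pa.mask == pb.mask).all()

    def test_noiseless_constant_lesion_has_zero_within_mask_variance(self):
        cfg = SynthConfig(seed=2, noise_sd=0.0, texture_amplitude=0.0,
                          lesion_count_range=(1, 1), **{k: v for k, v in self.CFG.items()
                                                        if k != "lesion_radius_range_mm"},
                          lesion_radius_range_mm=(2.5, 3.0))
        pair = generate_volume_cohort(cfg)[0]
        assert pair.t2[pair.mask].var() == 0.0

    def test_masks_mark_lesions_and_grids_align(self):
        pairs = generate_volume_cohort(SynthConfig(seed=3, **self.CFG))
        for p in pairs:
            assert p.t2.shape == p.mpr.shape == p.mask.shape
            assert p.mask.sum() >= 1

    def test_planted_texture_difference_is_detectable(self):
        # two-class cohort through extraction + rank-sum screen: at least one
        # texture feature separates the classes strongly (planted by design)
        cfg = SynthConfig(n_per_class_per_scanner=cells(10, 10, 10, 10),
                          shape=(16, 16, 16), lesion_radius_range_mm=(2.5, 4.0),
                          seed=4)
        tab = extract_cohort(generate_volume_cohort(cfg))
        lab = tab.labels
        texture = [c for c in tab.feature_names if "-glcm-" in c and "original" in c]
        pvals = []
        for col in texture:
            _, p = rank_sum_test(tab.frame.loc[lab == "MS", col],
                                 tab.frame.loc[lab == "NMO", col])
            pvals.append(p)
        assert min(pvals) < 0.01


class TestSplit:
    def test_disjoint_exhaustive_86_30(self, cohort):
        train, test = split_train_test(cohort, 86, seed=0)
        assert train.n_subjects == 86 and test.n_subjects == 30
        assert not set(train.frame.index) & set(test.frame.index)
        assert set(train.frame.index) | set(test.frame.index) == set(cohort.frame.index)

    def test_degenerate_n_train_rejected(self, cohort):
        with pytest.raises(ValueError):
            split_train_test(cohort, cohort.n_subjects, seed=0)
        with pytest.raises(ValueError):
            split_train_test(cohort, 0, seed=0)

    def test_same_seed_same_membership(self, cohort):
        a, _ = split_train_test(cohort, 86, seed=9)
        b, _ = split_train_test(cohort, 86, seed=9)
        assert list(a.frame.index) == list(b.frame.index)
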