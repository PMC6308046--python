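"""Synthetic cohort generators: design counts, growth law, retest structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad import (
    CohortDesignParams,
    simulate_feature_table,
    simulate_screening_cohort,
)


def small_params(**kw):
    defaults = dict(n_cases_train=6, n_controls_train=12, n_cases_test=5,
                    n_controls_test=10, seed=0)
    defaults.update(kw)
    return CohortDesignParams(**defaults)


class TestDesign:
    def test_default_arm_sizes_match_study_design(self):
        p = CohortDesignParams()
        assert (p.n_cases_train, p.n_controls_train) == (83, 172)
        assert (p.n_cases_test, p.n_controls_test) == (77, 135)

    def test_generated_counts_exact(self):
        bundle = simulate_screening_cohort(small_params())
        d = bundle.design_frame()
        counts = d.groupby(["cohort", "label"]).size()
        assert counts[("train", "case")] == 6
        assert counts[("train", "control")] == 12
        assert counts[("test", "case")] == 5
        assert counts[("test", "control")] == 10

    def test_two_to_one_control_case_ratio_default(self):
        p = CohortDesignParams()
        assert p.n_controls_train / p.n_cases_train == pytest.approx(2.0, rel=0.05)

    def test_size_mix_allocation(self):
        p = CohortDesignParams(seed=1)
        d = simulate_screening_cohort(p).design_frame()
        train_cases = d[(d.cohort == "train") & (d.label == "case")]
        mix = train_cases["size_class"].value_counts()
        assert mix["small"] == 14 and mix["intermediate"] == 53 and mix["large"] == 16

    def test_every_subject_complete(self):
        d = simulate_screening_cohort(small_params()).design_frame()
        assert d["label"].isin(["case", "control"]).all()
        assert d["cohort"].isin(["train", "test"]).all()
        assert (d["ld_mm"] > 0).all()

    def test_determinism(self):
        a = simulate_screening_cohort(small_params()).design_frame()
        b = simulate_screening_cohort(small_params()).design_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CohortDesignParams(n_cases_train=-1)
        with pytest.raises(ValueError):
            CohortDesignParams(case_size_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortDesignParams(case_growth_factor=0.9)


class TestImageMode:
    def test_stable_controls_have_zero_volume_delta(self):
        p = small_params(n_cases_train=0, n_cases_test=0, n_controls_test=0,
                        n_controls_train=3, measurement_noise_sd=0.0)
        b = simulate_screening_cohort(p)
        for rec in b.subjects:
            _, m0, _ = b.images_for(rec.subject_id, "T0")
            _, m1, _ = b.images_for(rec.subject_id, "T1")
            assert m0.voxel_count == m1.voxel_count

    def test_case_growth_follows_cube_law(self):
        p = small_params(n_cases_train=3, n_controls_train=0, n_cases_test=0,
                        n_controls_test=0, measurement_noise_sd=0.0,
                        case_growth_factor=1.26)
        b = simulate_screening_cohort(p)
        for rec in b.subjects:
            _, m0, _ = b.images_for(rec.subject_id, "T0")
            _, m1, _ = b.images_for(rec.subject_id, "T1")
            ratio = m1.voxel_count / m0.voxel_count
            assert ratio == pytest.approx(1.26**3, rel=0.05)

    def test_feature_view_available(self):
        p = CohortDesignParams(n_cases_train=1, n_controls_train=1, n_cases_test=0,
                              n_controls_test=0, seed=3)
        b = simulate_screening_cohort(p)
        table = b.extract_features("T0")
        assert len(table) == 2
        assert table.notna().all().all()


class TestFeatureTable:
    def test_null_design_auroc_near_half(self):
        from deltarad import ModelSpec, evaluate, train_model
        from deltarad.pipeline import build_model_table
        from deltarad.stability import delta_table

        params = CohortDesignParams(n_cases_train=70, n_controls_train=140,
                                    n_cases_test=70, n_controls_test=140, seed=5)
        t0, t1, design = simulate_feature_table(10, 0, 0, 0.0, 0.95, params)
        X = build_model_table(t0, delta_table(t0, t1))
        train = design.cohort == "train"
        model = train_model(ModelSpec(classifier="naive_bayes", seed=0),
                            X[train], design.label[train])
        res = evaluate(model, X[~train], design.label[~train])
        assert 0.35 <= res.auroc <= 0.65

    def test_perfect_retest_controls_identical(self):
        params = small_params()
        t0, t1, design = simulate_feature_table(8, 1, 1, 1.0, 1.0, params)
        controls = design.index[design.label == "control"]
        assert np.array_equal(t0.loc[controls].to_numpy(), t1.loc[controls].to_numpy())

    def test_informative_delta_strongly_detectable(self):
        params = CohortDesignParams(seed=11)  # full-size design, n_train = 255
        t0, t1, design = simulate_feature_table(40, 1, 1, 1.5, 0.99, params)
        train = design.cohort == "train"
        d = (t1 - t0).loc[train, "feat_001"]
        case = design.label[train] == "case"
        t_stat = stats.ttest_ind(d[case], d[~case]).statistic
        assert t_stat > 3

    def test_retest_target_achieved_on_controls(self):
        from deltarad import concordance_correlation

        params = CohortDesignParams(seed=4)
        t0, t1, design = simulate_feature_table(20, 0, 0, 0.0, 0.8, params)
        controls = design.index[(design.label == "control") & (design.cohort == "train")]
        cccs = [concordance_correlation(t0.loc[controls, c], t1.loc[controls, c])
                for c in t0.columns]
        assert np.mean(cccs) == pytest.approx(0.8, abs=0.05)

    def test_impossible_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature_table(5, 0, 0, 0.0, 1.5, small_params())
        with pytest.raises(ValueError):
            simulate_feature_table(5, 4, 4, 1.0, 0.9, small_params())

    def test_determinism(self):
        a = simulate_feature_table(10, 1, 1, 1.0, 0.9, small_params())
        b = simulate_feature_table(10, 1, 1, 1.0, 0.9, small_params())
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
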