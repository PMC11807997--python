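
import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from uromet.config import PipelineConfig
from uromet.io import Comparison
from uromet.staging import (
    KeyPanel, fit_staging_model, random_sampling_validation, roc_auc,
    select_key_panel, stage_comparison,
)
from uromet.validate import (
    null_resampling_auc, panel_recovery_counts, run_cohort_screens,
    strong_effect_spec, two_group_spec,
)
from uromet.simulate import PlantedEffect, generate_cohort
from uromet.preprocess import preprocess_table
from uromet.screen import screen_comparison
from oracles import brute_force_auc


class TestROC:
    def test_hand_computed_example(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)  # 3 of 4 case-control pairs concordant

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_rank_formula_matches_pair_counting_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels))
        assert res.auc == pytest.approx(roc_auc_score(labels, scores))

    @pytest.mark.parametrize("seed", range(4))
    def test_curve_trapezoid_area_equals_rank_auc(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auc)


@pytest.fixture(scope="module")
def strong_cohort():
    spec, strong = strong_effect_spec(seed=41)
    neg, pos, meta, _, truth = generate_cohort(spec)
    clean = {}
    for t in (neg, pos):
        clean[t.ion_mode], _, _ = preprocess_table(t, meta)
    comp = Comparison("CN", "AD")
    screen = screen_comparison(clean["negative"], clean["positive"], meta,
                               comp, PipelineConfig())
    return {"tables": clean, "metadata": meta, "screen": screen,
            "comparison": comp, "strong": strong}


class TestKeyPanel:
    def test_perfectly_separating_feature_ranks_first(self):
        """One feature separates the groups exactly; it must dominate the
        tree's impurity decrease."""
        planted = [PlantedEffect("neg_f000", "CN-AD", 8.0)]
        spec = two_group_spec(30, planted, 20, 20, seed=31,
                              baseline_log_sd=0.15, frac_high_cv=0.0,
                              missing_rate_random=0.0, missing_low_prob=0.0)
        screens, env, _ = run_cohort_screens(spec)
        screen = screens["CN-AD"]
        panel = select_key_panel(screen, env["tables"]["negative"],
                                 env["tables"]["positive"], env["metadata"],
                                 Comparison("CN", "AD"), n_keys=5, seed=1)
        assert panel.features[0][0] == "neg_f000"
        assert panel.features[0][1] > 0.5

    def test_small_differential_set_returned_whole(self, strong_cohort):
        screen = strong_cohort["screen"]
        few = [r.feature_id for r in screen.records if r.status != "ns"][:4]

        class _Mini:
            comparison = screen.comparison
            records = screen.records
            differential_ids = few
        panel = select_key_panel(_Mini(), strong_cohort["tables"]["negative"],
                                 strong_cohort["tables"]["positive"],
                                 strong_cohort["metadata"],
                                 strong_cohort["comparison"], n_keys=10, seed=2)
        assert sorted(panel.feature_ids) == sorted(few)

    def test_strong_planted_effects_dominate_panel(self):
        """Median over seeds: >= 8 of the 10 strongest planted effects are
        selected into the 10-feature key panel."""
        counts = panel_recovery_counts(n_seeds=7, base_seed=900)
        assert np.median(counts) >= 8

    def test_no_differential_features_rejected(self, strong_cohort):
        class _Empty:
            comparison = "CN-AD"
            records = []
            differential_ids = []
        with pytest.raises(ValueError, match="differential"):
            select_key_panel(_Empty(), strong_cohort["tables"]["negative"],
                             strong_cohort["tables"]["positive"],
                             strong_cohort["metadata"],
                             strong_cohort["comparison"])


class TestStagingModel:
    def test_separated_groups_reach_extreme_probabilities(self):
        """With one perfectly separating feature the weakly penalised
        logistic fit saturates: P(case) >= 0.99 for cases, <= 0.01 for
        controls."""
        planted = [PlantedEffect("neg_f000", "CN-AD", 8.0)]
        spec = two_group_spec(25, planted, 12, 12, seed=37,
                              baseline_log_sd=0.12, frac_high_cv=0.0,
                              missing_rate_random=0.0, missing_low_prob=0.0)
        neg, pos, meta, _, _ = generate_cohort(spec)
        tables = {t.ion_mode: t.subset_samples(meta.biological_ids)
                  for t in (neg, pos)}
        comp = Comparison("CN", "AD")
        panel = KeyPanel("CN-AD", [("neg_f000", 1.0)], seed=0)
        model = fit_staging_model(panel, tables["negative"], tables["positive"],
                                  meta, comp)
        from uromet.staging import _comparison_matrix
        mat, labels = _comparison_matrix(tables["negative"], tables["positive"],
                                         meta, comp, panel.feature_ids)
        prob = model.predict_proba(mat)
        assert np.all(prob[labels == "AD"] >= 0.99)
        assert np.all(prob[labels == "CN"] <= 0.01)

    def test_coefficients_invariant_to_panel_order(self, strong_cohort):
        ids = strong_cohort["screen"].differential_ids[:6]
        args = (strong_cohort["tables"]["negative"],
                strong_cohort["tables"]["positive"],
                strong_cohort["metadata"], strong_cohort["comparison"])
        m1 = fit_staging_model(KeyPanel("CN-AD", [(f, 0.0) for f in ids], 0), *args)
        m2 = fit_staging_model(KeyPanel("CN-AD", [(f, 0.0) for f in ids[::-1]], 0), *args)
        assert m1.feature_ids == m2.feature_ids
        assert np.allclose(m1.coefficients, m2.coefficients)
        assert m1.intercept == pytest.approx(m2.intercept)

    def test_missing_panel_feature_rejected(self, strong_cohort):
        panel = KeyPanel("CN-AD", [("ghost_feature", 1.0)], seed=0)
        with pytest.raises(ValueError, match="ghost"):
            fit_staging_model(panel, strong_cohort["tables"]["negative"],
                              strong_cohort["tables"]["positive"],
                              strong_cohort["metadata"],
                              strong_cohort["comparison"])


class TestResampling:
    def test_separable_panel_keeps_perfect_test_auc(self, strong_cohort):
        panel = KeyPanel("CN-AD", [(f"neg_f{i:03d}", 1.0) for i in range(5)], 0)
        report = random_sampling_validation(
            panel, strong_cohort["tables"]["negative"],
            strong_cohort["tables"]["positive"], strong_cohort["metadata"],
            strong_cohort["comparison"], n_resamples=50, seed=3)
        assert report.mean_auc > 0.95
        assert np.all((report.test_auc >= 0) & (report.test_auc <= 1))

    def test_null_cohort_centres_on_chance(self):
        """Held-out AUC on cohorts with nothing planted averages ~0.5."""
        aucs = [null_resampling_auc(seed=s, n_resamples=60) for s in (1, 2, 4)]
        assert 0.4 < np.mean(aucs) < 0.6

    def test_too_small_group_rejected(self):
        spec = two_group_spec(3, [], 12, 12, seed=5, missing_rate_random=0.0,
                              missing_low_prob=0.0, frac_high_cv=0.0)
        neg, pos, meta, _, _ = generate_cohort(spec)
        clean = {}
        for t in (neg, pos):
            clean[t.ion_mode] = t.subset_samples(meta.biological_ids)
        panel = KeyPanel("CN-AD", [("neg_f000", 1.0)], 0)
        with pytest.raises(ValueError, match="4 samples"):
            random_sampling_validation(panel, clean["negative"], clean["positive"],
                                       meta, Comparison("CN", "AD"))


class TestStageComparison:
    def test_end_to_end_outputs_are_consistent(self, strong_cohort):
        out = stage_comparison(strong_cohort["screen"],
                               strong_cohort["tables"]["negative"],
                               strong_cohort["tables"]["positive"],
                               strong_cohort["metadata"],
                               strong_cohort["comparison"],
                               config=PipelineConfig(n_resamples=30), seed=7)
        assert len(out.panel.features) == 10
        assert out.roc.auc >= 0.95
        assert len(out.model.coefficients) == len(out.panel.features)
        assert set(out.probabilities["group"]) == {"CN", "AD"}
        assert np.trapezoid(out.roc.tpr, out.roc.fpr) == pytest.approx(out.roc.auc)
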