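import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from uromet.cohortstats import (
    chi_square_independence, cohort_table, hotelling_t2,
    kruskal_then_pairwise, normality_gate,
)

# Printed 3x2 contingency tables of the staged cohort (AD/MCI/CN rows) and
# the published p-values they reproduce under Pearson chi-square.
TABLE1_CATEGORICAL = {
    "gender": ([[27, 30], [14, 29], [22, 40]], 0.253),
    "smoking": ([[15, 42], [8, 35], [10, 52]], 0.366),
    "hypertension": ([[22, 35], [15, 28], [31, 31]], 0.247),
    "diabetes": ([[11, 46], [5, 38], [16, 46]], 0.199),
    "hyperlipidemia": ([[23, 34], [23, 20], [35, 27]], 0.186),
    "heart_disease": ([[16, 41], [10, 33], [10, 52]], 0.288),
    "cerebrovascular": ([[14, 43], [8, 35], [11, 51]], 0.618),
    "family_history": ([[10, 47], [7, 36], [13, 49]], 0.808),
    "apoe_e4": ([[27, 30], [21, 22], [14, 48]], 0.005),
}


class TestChiSquare:
    @pytest.mark.parametrize("variable", sorted(TABLE1_CATEGORICAL))
    def test_reproduces_published_cohort_p_values(self, variable):
        counts, expected_p = TABLE1_CATEGORICAL[variable]
        res = chi_square_independence(counts)
        assert res.p_value == pytest.approx(expected_p, abs=5e-4)
        assert res.df == 2

    def test_observed_equal_expected_gives_zero_statistic(self):
        res = chi_square_independence([[10, 20], [20, 40]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.lists(st.integers(1, 40), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    def test_statistic_invariant_to_row_and_column_permutation(self, rows):
        obs = np.array(rows)
        rng = np.random.default_rng(0)
        perm = obs[rng.permutation(obs.shape[0])][:, rng.permutation(obs.shape[1])]
        a = chi_square_independence(obs)
        b = chi_square_independence(perm)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 5]])

    def test_low_expected_counts_flagged_but_tested(self):
        with pytest.warns(UserWarning, match="expected"):
            res = chi_square_independence([[1, 9], [2, 8]])
        assert res.low_expected_warning
        assert np.isfinite(res.p_value)


class TestKruskalPairwise:
    def test_identical_groups_show_no_differences(self):
        res = kruskal_then_pairwise({g: np.array([5.0, 5.0, 5.0])
                                     for g in ("CN", "MCI", "AD")})
        assert res.overall_p == pytest.approx(1.0)
        assert not any(res.bonferroni_flags.values())

    def test_separated_triplets_hit_exact_rank_sum_floor(self):
        """Fully separated groups of 3: the omnibus test fires but every
        pairwise exact p is 2/C(6,3) = 0.1, so no flag survives a
        Bonferroni factor of 3."""
        res = kruskal_then_pairwise({
            "CN": np.array([1.0, 2.0, 3.0]),
            "MCI": np.array([11.0, 12.0, 13.0]),
            "AD": np.array([21.0, 22.0, 23.0]),
        })
        assert res.overall_p < 0.05
        for p in res.pairwise_p.values():
            assert p == pytest.approx(0.1)
        assert not any(res.bonferroni_flags.values())

    def test_invariant_to_within_group_order(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(size=9) for g in ("CN", "MCI", "AD")}
        shuffled = {g: rng.permutation(v) for g, v in groups.items()}
        a = kruskal_then_pairwise(groups)
        b = kruskal_then_pairwise(shuffled)
        assert a.overall_p == pytest.approx(b.overall_p)
        assert a.pairwise_p == pytest.approx(b.pairwise_p)

    def test_bonferroni_flags_monotone_in_p(self):
        rng = np.random.default_rng(3)
        base = {"CN": rng.normal(0, 1, 20), "MCI": rng.normal(1, 1, 20),
                "AD": rng.normal(3, 1, 20)}
        res = kruskal_then_pairwise(base)
        for pair, flagged in res.bonferroni_flags.items():
            if flagged:
                assert res.pairwise_p[pair] < 0.05 / 3


class TestHotelling:
    def test_identical_groups_give_zero(self):
        a = np.array([[1.0, 2.0], [3.0, 7.0], [5.0, 3.0], [2.0, 6.0]])
        t2, f_stat, p = hotelling_t2(a, a.copy())
        assert t2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_one_dimension_equals_squared_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        t2, _, p = hotelling_t2(a, b)
        t_res = stats.ttest_ind(a, b, equal_var=True)
        assert t2 == pytest.approx(t_res.statistic ** 2)
        assert p == pytest.approx(t_res.pvalue)

    def test_detects_two_sd_shift_in_two_dimensions(self):
        """A 2-sd mean shift at n=50/group is essentially always detected."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            a = rng.normal(0, 1, size=(50, 2))
            b = rng.normal(2, 1, size=(50, 2))
            hits += hotelling_t2(a, b)[2] < 0.001
        assert hits >= 19

    def test_singular_covariance_advises_reduction(self):
        a = np.tile([1.0, 2.0], (10, 1))
        b = np.tile([1.5, 3.0], (10, 1))
        with pytest.raises(ValueError, match="singular|dimension"):
            hotelling_t2(a, b)

    def test_dimension_exceeding_samples_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="dimension"):
            hotelling_t2(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)))


class TestNormalityGate:
    def test_gaussian_samples_usually_pass(self):
        passed = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = {"CN": rng.normal(size=100)}
            passed += normality_gate(groups) == "normal"
        assert passed >= 32  # ~95% single-group pass rate at alpha 0.05

    def test_lognormal_samples_rejected(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            groups = {"CN": np.exp(rng.normal(0, 1, size=100))}
            assert normality_gate(groups) == "non-normal"

    def test_constant_or_tiny_groups_warned_non_normal(self):
        with pytest.warns(UserWarning):
            assert normality_gate({"CN": np.array([3.0, 3.0, 3.0])}) == "non-normal"
        with pytest.warns(UserWarning):
            assert normality_gate({"CN": np.array([1.0, 2.0])}) == "non-normal"


class TestCohortTable:
    def test_synthetic_cohort_summary_structure(self, cohort):
        table = cohort_table(cohort["metadata"])
        assert set(["variable", "CN", "MCI", "AD", "test", "p", "flags"]) \
            <= set(table.columns)
        cognitive = table[table["variable"].isin(["mmse", "moca"])]
        # planted stage-dependent cognitive decline must be detected
        assert (cognitive["p"] < 1e-6).all()
        assert cognitive["flags"].str.contains("a").all()
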