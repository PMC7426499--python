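"""Mann-Whitney U implementation, group summaries and comparison tables."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from flysla import (build_comparison_table, mann_whitney_u, significance_tier,
                    summarize_group, summary_table)


class TestMannWhitney:
    def test_exact_p_by_full_enumeration(self):
        # a=(1,2), b=(3,4): U=0, and 2 of the C(4,2)=6 rank splits are as extreme
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.U == 0.0
        assert res.p_two_tailed == pytest.approx(1 / 3, rel=1e-12)

    def test_swapping_groups_complements_u_and_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=9)
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.U + r2.U == pytest.approx(6 * 9)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    def test_identical_samples_not_significant(self):
        a = [1.0, 2.0, 5.5, 3.2, 8.0]
        res = mann_whitney_u(a, a)
        assert res.p_two_tailed == pytest.approx(1.0, abs=1e-9)
        assert res.tier == 0

    def test_exact_method_refuses_ties(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_u([1, 2, 2], [2, 3], method="exact")

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_independent_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(0.8, 1, size=6)
        res = mann_whitney_u(a, b, method="exact")
        oracle = mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert res.p_two_tailed == pytest.approx(oracle.pvalue, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_approximation_matches_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=25)
        b = np.round(rng.normal(0.3, 1, size=30), 1)  # induces occasional ties
        res = mann_whitney_u(a, b)
        assert res.method == "normal_approximation"
        oracle = mannwhitneyu(a, b, method="asymptotic", use_continuity=True,
                              alternative="two-sided")
        assert res.p_two_tailed == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_exact_and_approximation_agree_for_n8(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b = rng.normal(size=8), rng.normal(0.5, 1, size=8)
            pe = mann_whitney_u(a, b, method="exact").p_two_tailed
            pa = mann_whitney_u(a, b, method="normal_approximation").p_two_tailed
            assert abs(pe - pa) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestSummaries:
    def test_mean_and_sem(self):
        mean, sem, n = summarize_group([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert sem == pytest.approx(1 / np.sqrt(3))
        assert n == 3

    def test_singleton_has_no_sem(self):
        assert summarize_group([5.0]) == (5.0, None, 1)

    def test_constant_group_sem_zero(self):
        _, sem, _ = summarize_group([2.0, 2.0, 2.0])
        assert sem == 0.0

    @pytest.mark.parametrize("p,tier", [(0.03, 1), (0.005, 2), (0.0005, 3),
                                        (0.2, 0), (0.05, 0), (0.01, 1), (0.001, 2)])
    def test_significance_tiers_strict_inequalities(self, p, tier):
        assert significance_tier(p) == tier


def _profiles(seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for strain, delta in (("CS", 0.0), ("cd1", shift)):
        for age in (5, 20):
            for _ in range(12):
                rows.append({"strain": strain, "age": age,
                             "index_of_activity": rng.normal(0.5 + delta, 0.1),
                             "running_speed": rng.normal(4 + 10 * delta, 0.5)})
    return pd.DataFrame(rows)


class TestComparisonTable:
    def test_identical_distributions_mostly_tier_zero(self):
        table = build_comparison_table(_profiles(), ["index_of_activity"],
                                       baseline_age=5)
        kinds = set(table["comparison"])
        assert kinds == {"between_strain", "vs_baseline_age"}
        # 2 matched-age + 2 vs-baseline comparisons
        assert len(table) == 4

    def test_constructed_effect_detected_between_strains(self):
        table = build_comparison_table(_profiles(seed=3, shift=0.3),
                                       ["running_speed"], baseline_age=5)
        between = table[table["comparison"] == "between_strain"]
        assert (between["tier"] == 3).all()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="not in profile"):
            build_comparison_table(_profiles(), ["nope"])

    def test_holm_correction_never_lowers_p(self):
        raw = build_comparison_table(_profiles(seed=5), ["index_of_activity"])
        adj = build_comparison_table(_profiles(seed=5), ["index_of_activity"],
                                     correction="holm")
        assert np.all(adj["p"].to_numpy() >= raw["p"].to_numpy() - 1e-15)

    def test_summary_table_mean_sem_n(self):
        s = summary_table(_profiles(), ["index_of_activity"])
        assert set(s.columns) == {"strain", "age", "parameter", "mean", "sem", "n"}
        assert (s["n"] == 12).all()
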