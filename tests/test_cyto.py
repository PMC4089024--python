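"""Cell-cycle gating, PI death fractions, budding index, ANOVA/Tukey."""

import numpy as np
import pytest
from scipy import stats

from cgscreen.cyto import (
    GroupComparison,
    UnevaluableSample,
    anova_tukey,
    budding_index,
    fold_change_g1,
    gate_g1_fraction,
    pi_positive_fraction,
)
from cgscreen.synth import CytometrySample, simulate_cytometry


class TestG1Gate:
    def test_recovers_planted_g1_fraction(self):
        sample = simulate_cytometry(10000, 0.6, 0.0, seed=11)
        assert gate_g1_fraction(sample) == pytest.approx(0.6, abs=0.02)

    def test_equal_mixture_gates_half(self):
        sample = simulate_cytometry(10000, 0.5, 0.0, seed=4)
        assert gate_g1_fraction(sample) == pytest.approx(0.5, abs=0.02)

    def test_fully_arrested_population_with_reference(self):
        sample = simulate_cytometry(2000, 1.0, 0.0, seed=2)
        assert gate_g1_fraction(sample, c1_reference=100.0) == 1.0

    def test_unresolvable_modes_without_reference_unevaluable(self):
        sample = simulate_cytometry(2000, 1.0, 0.0, seed=2)
        with pytest.raises(UnevaluableSample):
            gate_g1_fraction(sample)

    def test_too_few_events_unevaluable(self):
        sample = simulate_cytometry(100, 0.5, 0.0, seed=1)
        with pytest.raises(UnevaluableSample):
            gate_g1_fraction(sample)

    def test_invariant_to_global_rescaling(self):
        sample = simulate_cytometry(5000, 0.55, 0.0, seed=8)
        scaled = CytometrySample("scaled", sample.dna_content * 37.2, sample.pi_value)
        assert gate_g1_fraction(scaled) == gate_g1_fraction(sample)

    def test_sphase_bridge_tolerated(self):
        sample = simulate_cytometry(10000, 0.6, 0.0, seed=11, s_phase_frac=0.05)
        assert gate_g1_fraction(sample) == pytest.approx(0.6, abs=0.02)


class TestFoldChange:
    @pytest.mark.parametrize("pair,expected", [((0.9, 0.5), 1.8), ((0.5, 0.5), 1.0), ((0.25, 0.5), 0.5)])
    def test_ratio(self, pair, expected):
        assert fold_change_g1(*pair) == pytest.approx(expected)

    def test_zero_control_unevaluable(self):
        with pytest.raises(UnevaluableSample):
            fold_change_g1(0.5, 0.0)


class TestPIPositive:
    def test_control_against_itself_sits_at_gate_tail(self):
        ctrl = simulate_cytometry(10000, 0.5, 0.0, seed=3)
        assert pi_positive_fraction(ctrl, ctrl) == pytest.approx(0.005, abs=0.002)

    def test_recovers_planted_death_fraction(self):
        ctrl = simulate_cytometry(10000, 0.5, 0.0, seed=5)
        treated = simulate_cytometry(10000, 0.5, 0.15, seed=6)
        assert pi_positive_fraction(treated, ctrl) == pytest.approx(0.15, abs=0.01)

    def test_all_events_above_control_maximum(self):
        ctrl = simulate_cytometry(1000, 0.5, 0.0, seed=7)
        hot = CytometrySample("dead", ctrl.dna_content, ctrl.pi_value + ctrl.pi_value.max() + 1)
        assert pi_positive_fraction(hot, ctrl) == 1.0

    def test_small_control_unevaluable(self):
        ctrl = simulate_cytometry(100, 0.5, 0.0, seed=7)
        with pytest.raises(UnevaluableSample):
            pi_positive_fraction(ctrl, ctrl)


class TestBuddingIndex:
    @pytest.mark.parametrize("b,u,expected", [(50, 50, 0.5), (0, 100, 0.0), (16, 84, 0.16)])
    def test_fraction(self, b, u, expected):
        assert budding_index(b, u) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            budding_index(0, 0)


class TestAnovaTukey:
    def test_identical_groups_null_result(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]})
        assert res.f_statistic == 0.0 and res.p_anova == 1.0
        assert res.significant_pairs() == []

    def test_two_groups_match_equal_variance_t_test(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = anova_tukey({"a": a, "b": b})
        _, t_p = stats.ttest_ind(a, b)
        assert res.pairwise[("a", "b")] == pytest.approx(t_p, rel=1e-6)

    def test_shifted_group_detected_and_confirmed_by_permutation(self):
        rng = np.random.default_rng(20)
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5), "c": rng.normal(5, 1, 5)}
        res = anova_tukey(groups)
        assert res.pairwise[("a", "c")] < 0.001
        assert res.pairwise[("b", "c")] < 0.001
        # permutation oracle for the ANOVA F statistic
        pooled = np.concatenate(list(groups.values()))
        obs_f = res.f_statistic
        perm_rng = np.random.default_rng(21)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            f, _ = stats.f_oneway(perm[:5], perm[5:10], perm[10:])
            count += f >= obs_f
        assert (count + 1) / (n_perm + 1) < 0.001

    def test_tukey_p_not_below_unadjusted_pooled_t_for_three_groups(self):
        # the honest unadjusted comparator shares Tukey's pooled MSE and df
        rng = np.random.default_rng(30)
        for _ in range(5):
            groups = {k: rng.normal(rng.normal(), 1, n) for k, n in [("a", 5), ("b", 7), ("c", 4)]}
            res = anova_tukey(groups)
            arrays = list(groups.values())
            df = sum(len(a) - 1 for a in arrays)
            mse = sum((len(a) - 1) * np.var(a, ddof=1) for a in arrays) / df
            for (g1, g2), p_adj in res.pairwise.items():
                a, b = groups[g1], groups[g2]
                se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
                t = abs(a.mean() - b.mean()) / se
                p_unadj = 2 * stats.t.sf(t, df)
                assert p_adj >= p_unadj - 1e-9

    def test_unequal_group_sizes_accepted(self):
        res = anova_tukey({"a": [1, 2, 3], "b": [2, 3, 4, 5], "c": [10, 11]})
        assert isinstance(res, GroupComparison)
        assert res.p_anova < 0.05

    def test_degenerate_groups_excluded_then_unevaluable(self):
        res = anova_tukey({"a": [1, 2, 3], "b": [2.0], "c": [3, 4, 5]})
        assert res.excluded == ["b"]
        with pytest.raises(UnevaluableSample):
            anova_tukey({"a": [1, 2, 3], "b": [2.0]})
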