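"""Paired tests, exact signed-rank enumeration, Friedman/Dunn, power."""

import numpy as np
import pytest
from scipy import stats as sps

from pclt2.stats import (
    friedman_dunn,
    minimum_sample_size,
    paired_ttest,
    power_paired_t,
    power_two_sample_t,
    wilcoxon_paired,
)


class TestPairedT:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = paired_ttest(x, x)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        x = np.zeros(4)
        with pytest.warns(UserWarning, match="degenerate"):
            r = paired_ttest(x, x + 1.0)
        assert r.p_value == 0.0

    def test_power_against_closed_form(self):
        """Monte-Carlo detection rate matches the noncentral-t power."""
        rng = np.random.default_rng(2024)
        n, mu, sd, alpha = 10, 6.2, 1.0, 0.01
        hits = 0
        reps = 400
        for _ in range(reps):
            d = rng.normal(mu, sd, n)
            r = paired_ttest(np.zeros(n), d, alpha=alpha)
            hits += r.significant
        predicted = power_paired_t(n, mu / sd, alpha)
        assert predicted > 0.999
        assert hits / reps >= 0.99


class TestWilcoxon:
    def test_all_positive_n10_exact_enumeration(self):
        x = np.zeros(10)
        y = np.arange(1.0, 11.0)
        r = wilcoxon_paired(x, y)
        assert r.p_value == pytest.approx(2 / 1024)       # 0.001953

    def test_identical_gives_p_one(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="zero"):
            r = wilcoxon_paired(x, x)
        assert r.p_value == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.5, 1, 12)
        assert wilcoxon_paired(x, y).p_value == pytest.approx(
            wilcoxon_paired(y, x).p_value)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 14)
        y = x + rng.normal(0.4, 1, 14)
        ours = wilcoxon_paired(x, y)
        ref = sps.wilcoxon(y, x, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_differences_pratt_handling(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.0, 2, 4, 6, 7, 9])  # two zeros
        r = wilcoxon_paired(x, y)
        assert 0 < r.p_value <= 1

    def test_type_one_error_calibrated_under_null(self):
        """Empirical size at alpha=0.01 stays within the binomial band."""
        rng = np.random.default_rng(7)
        reps, n = 2000, 10
        hits = 0
        for _ in range(reps):
            d = rng.normal(0, 1, n)
            hits += wilcoxon_paired(np.zeros(n), d, alpha=0.01).significant
        # exact attainable size at n=10 is 10/1024 ~ 0.0098
        se = np.sqrt(0.01 * 0.99 / reps)
        assert hits / reps == pytest.approx(0.01, abs=4 * se)


class TestFriedmanDunn:
    def test_identical_groups(self):
        blocks = np.tile([3.0, 3.0, 3.0], (8, 1))
        overall, pairwise = friedman_dunn(blocks)
        assert overall.statistic == 0.0 and overall.p_value == 1.0
        assert pairwise == []

    def test_monotone_blocks_identify_extreme_pair(self):
        rng = np.random.default_rng(0)
        n = 10
        blocks = np.column_stack([
            3.0 + rng.random(n) * 0.1,   # PR always highest
            2.0 + rng.random(n) * 0.1,
            1.0 + rng.random(n) * 0.1,   # DR always lowest
        ])
        overall, pairwise = friedman_dunn(blocks)
        assert overall.p_value < 0.001
        ps = {d.pair: d.p_uncorrected for d in pairwise}
        assert ps[("PR", "DR")] == min(ps.values())
        assert all(d.p_bonferroni >= d.p_uncorrected for d in pairwise)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        blocks = rng.normal(0, 1, (9, 3)) + np.array([0.0, 1.0, 0.2])
        _, pw1 = friedman_dunn(blocks, ("PR", "CR", "DR"), always_posthoc=True)
        perm = blocks[:, [1, 2, 0]]
        _, pw2 = friedman_dunn(perm, ("CR", "DR", "PR"), always_posthoc=True)
        p1 = {frozenset(d.pair): d.p_uncorrected for d in pw1}
        p2 = {frozenset(d.pair): d.p_uncorrected for d in pw2}
        assert p1 == pytest.approx(p2)

    def test_incomplete_blocks_rejected(self):
        blocks = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman_dunn(blocks)

    def test_specimen_order_invariance(self):
        rng = np.random.default_rng(4)
        blocks = rng.normal(0, 1, (10, 3)) + np.array([0.0, 0.8, 1.4])
        o1, _ = friedman_dunn(blocks)
        o2, _ = friedman_dunn(blocks[::-1])
        assert o1.p_value == pytest.approx(o2.p_value)


class TestSampleSize:
    def test_study_design_needs_eight(self):
        assert minimum_sample_size(0.8, 0.05, 1.6, "two", "two-sample") == 8

    def test_agrees_with_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        n = smp.tt_ind_solve_power(effect_size=1.6, alpha=0.05, power=0.8)
        assert minimum_sample_size(0.8, 0.05, 1.6) == int(np.ceil(n))

    def test_huge_effect_hits_minimum_feasible_n(self):
        assert minimum_sample_size(0.8, 0.05, 50.0) == 2

    def test_power_monotone_in_n(self):
        vals = [power_two_sample_t(n, 1.6) for n in range(2, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            minimum_sample_size(0.8, 0.05, -1.0)
        with pytest.raises(ValueError):
            minimum_sample_size(1.5, 0.05, 1.6)
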