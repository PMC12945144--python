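"""Descriptive battery: count reconstruction, Mann-Whitney, Welch,
Shapiro-Wilk gating, and tiered Spearman matrices."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from epicohort import (
    InputError,
    compare_groups,
    mann_whitney_ordinal,
    normality_test,
    reconstruct_counts,
    spearman_matrix,
    welch_t,
)
from conftest import make_cohort

counts_strategy = st.lists(st.integers(0, 12), min_size=2, max_size=5).filter(
    lambda c: sum(c) >= 2
)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "pcts, n, expected",
        [
            ([10, 44, 44, 2], 48, [5, 21, 21, 1]),
            ([100, 0, 0], 50, [50, 0, 0]),
            ([22, 36, 42], 50, [11, 18, 21]),
        ],
    )
    def test_rounding_inversion(self, pcts, n, expected):
        assert reconstruct_counts(pcts, n) == expected

    def test_inconsistent_row_warns(self):
        with pytest.warns(UserWarning, match="sum to"):
            reconstruct_counts([38, 2, 23, 19, 12], 48)  # row sums to 94%

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(InputError):
            reconstruct_counts([120, 0], 10)


class TestMannWhitneyOrdinal:
    def test_identical_count_vectors_give_p_one(self):
        cmp = mann_whitney_ordinal([4, 3, 2], [4, 3, 2])
        assert cmp.statistic == pytest.approx(9 * 9 / 2)
        assert cmp.p_value == pytest.approx(1.0)

    def test_degenerate_single_category(self):
        with pytest.warns(UserWarning, match="one tied category"):
            cmp = mann_whitney_ordinal([5, 0], [7, 0])
        assert cmp.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_ordinal([0, 0], [3, 1])

    @settings(max_examples=60, derandomize=True)
    @given(a=counts_strategy, b=counts_strategy)
    def test_group_swap_symmetry(self, a, b):
        b = b + [0] * (len(a) - len(b)) if len(b) < len(a) else b
        a = a + [0] * (len(b) - len(a)) if len(a) < len(b) else a
        p_ab = mann_whitney_ordinal(a, b).p_value
        p_ba = mann_whitney_ordinal(b, a).p_value
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_invariant_under_monotone_ladder_relabel(self):
        """Stretching the category ladder (0,1,2 -> 0,5,50) changes nothing:
        the test sees only ranks."""
        a, b = [5, 3, 1], [2, 4, 3]
        base = mann_whitney_ordinal(a, b)
        va = np.repeat([0.0, 5.0, 50.0], a)
        vb = np.repeat([0.0, 5.0, 50.0], b)
        res = sps.mannwhitneyu(va, vb, method="asymptotic", use_continuity=True)
        assert res.pvalue == pytest.approx(base.p_value)

    @staticmethod
    def _exact_enumeration_p(counts_a, counts_b):
        """Brute-force oracle: two-sided permutation p of the midrank U
        statistic over every split of the pooled observations."""
        pooled_counts = np.add(counts_a, counts_b)
        ends = np.cumsum(pooled_counts)
        mid = (ends - pooled_counts + ends + 1) / 2.0  # midrank per category
        values = np.repeat(mid, pooled_counts)
        n_a, N = sum(counts_a), int(pooled_counts.sum())
        centre = n_a * (N - n_a) / 2
        u_obs = np.repeat(mid, counts_a).sum() - n_a * (n_a + 1) / 2
        hits = total = 0
        for idx in itertools.combinations(range(N), n_a):
            u = values[list(idx)].sum() - n_a * (n_a + 1) / 2
            hits += abs(u - centre) >= abs(u_obs - centre) - 1e-9
            total += 1
        return hits / total

    @pytest.mark.parametrize(
        "counts_a, counts_b",
        [
            ([5, 3, 2, 0], [2, 3, 3, 2]),
            ([4, 4, 2, 0], [1, 3, 4, 2]),
            ([6, 2, 1, 1], [3, 4, 2, 1]),
        ],
    )
    def test_agrees_with_exact_enumeration(self, counts_a, counts_b):
        """10+10 observations: the tie/continuity-corrected asymptotic p is
        within 0.02 of the exact permutation p from full enumeration (at
        very small n, e.g. 3+3, the normal approximation is still crude and
        no such bound holds)."""
        exact_p = self._exact_enumeration_p(counts_a, counts_b)
        asymptotic_p = mann_whitney_ordinal(counts_a, counts_b).p_value
        assert asymptotic_p == pytest.approx(exact_p, abs=0.02)


class TestWelch:
    def test_identical_samples(self):
        cmp = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert cmp.statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        expected_p = 2 * sps.t.sf(abs(t), df)
        cmp = welch_t(a, b)
        assert cmp.statistic == pytest.approx(t)
        assert cmp.p_value == pytest.approx(expected_p, rel=1e-9)

    def test_single_observation_rejected(self):
        with pytest.raises(InputError):
            welch_t([1.0], [1.0, 2.0, 3.0])

    def test_double_zero_variance_rejected(self):
        with pytest.raises(InputError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    @settings(max_examples=40, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 1.5, 12)
        p0 = welch_t(a, b).p_value
        p1 = welch_t(scale * a + shift, scale * b + shift).p_value
        assert p0 == pytest.approx(p1, rel=1e-9)


class TestNormality:
    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            normality_test([2.0, 2.0, 2.0])
        with pytest.raises(InputError):
            normality_test([1.0, 2.0])

    def test_calibrated_on_normal_draws(self):
        reps = 200
        rejections = sum(
            normality_test(np.random.default_rng(s).normal(size=500)) < 0.05
            for s in range(reps)
        )
        assert 0.02 <= rejections / reps <= 0.09

    def test_power_against_lognormal(self):
        reps = 200
        hits = sum(
            normality_test(np.exp(np.random.default_rng(s).normal(size=50))) < 0.001
            for s in range(reps)
        )
        assert hits / reps >= 0.90


class TestCompareGroups:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n1, n2 = 30, 32
        group = np.r_[np.ones(n1, int), np.zeros(n2, int)]
        restricted = np.r_[rng.normal(700, 100, n1), np.full(n2, np.nan)]
        return make_cohort(
            group,
            continuous={
                "clearly_normal": rng.normal(10, 1, n1 + n2),
                "clearly_lognormal": np.exp(rng.normal(0, 1.2, n1 + n2)),
                "cd4_like": restricted,
            },
            ordinal={"likert": rng.integers(0, 4, n1 + n2)},
            dependent={"outcome": np.exp(rng.normal(0, 1, n1 + n2))},
            restricted=("cd4_like",),
        )

    def test_normality_gate_selects_tests(self):
        by_var = {c.variable: c for c in compare_groups(self._cohort())}
        assert by_var["clearly_normal"].test == "welch"
        assert by_var["clearly_lognormal"].test == "mann-whitney"
        assert by_var["likert"].test == "mann-whitney"
        assert by_var["likert"].normality_p is None

    def test_welch_only_when_both_groups_normal(self):
        for c in compare_groups(self._cohort()):
            if c.test == "welch":
                assert min(c.normality_p) > 0.05

    def test_restricted_variable_summarized_without_test(self):
        by_var = {c.variable: c for c in compare_groups(self._cohort())}
        cmp = by_var["cd4_like"]
        assert cmp.test is None and cmp.p_value is None
        assert cmp.summary_group1["mean"] == pytest.approx(700, rel=0.1)
        assert cmp.summary_group2 == {}

    def test_too_small_group_rejected(self):
        cohort = self._cohort()
        cohort.data = cohort.data[cohort.data.group == 0].iloc[:5].assign(group=[1, 0, 0, 0, 0])
        with pytest.raises(InputError):
            compare_groups(cohort)


class TestSpearmanMatrix:
    def _cohort(self, seed=1, n=40):
        rng = np.random.default_rng(seed)
        group = np.r_[np.ones(n, int), np.zeros(n, int)]
        x = rng.normal(size=2 * n)
        return make_cohort(
            group,
            continuous={
                "x": x,
                "x_exp": np.exp(x),  # strictly increasing transform of x
                "neg_x": -x,
                "indep": rng.normal(size=2 * n),
            },
        )

    def test_monotone_transform_gives_rho_one_top_tier(self):
        m = spearman_matrix(self._cohort(), group=1)
        assert m.rho.loc["x", "x_exp"] == pytest.approx(1.0)
        assert m.tier.loc["x", "x_exp"] == "0.001"
        assert m.rho.loc["x", "neg_x"] == pytest.approx(-1.0)

    def test_symmetry_and_diagonal(self):
        m = spearman_matrix(self._cohort(), group=0)
        assert np.allclose(m.rho.values, m.rho.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.rho.values), 1.0)
        assert m.rho.values.max() <= 1.0 and m.rho.values.min() >= -1.0

    def test_tiers_consistent_with_p(self):
        m = spearman_matrix(self._cohort(), group=1)
        for i in m.variables:
            for j in m.variables:
                if i == j:
                    continue
                p = m.p.loc[i, j]
                tier = m.tier.loc[i, j]
                if p < 0.001:
                    assert tier == "0.001"
                elif p >= 0.05:
                    assert tier == "none"

    def test_constant_column_marked_missing(self):
        cohort = self._cohort()
        cohort.data["flat"] = 1.0
        cohort.continuous = cohort.continuous + ("flat",)
        m = spearman_matrix(cohort, group=1)
        assert np.isnan(m.rho.loc["flat", "x"])
        assert m.tier.loc["flat", "x"] == ""

    def test_null_calibration_of_005_tier(self):
        """Independent columns, n=50 per group: mean |rho| is small and the
        0.05 tier fires at roughly its nominal rate over 200 replicates."""
        hits = pairs = 0
        rho_abs = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            cohort = make_cohort(
                np.r_[np.ones(50, int), np.zeros(2, int)],
                continuous={f"v{i}": rng.normal(size=52) for i in range(4)},
            )
            m = spearman_matrix(cohort, group=1)
            iu = np.triu_indices(4, 1)
            rho_abs.extend(np.abs(m.rho.values[iu]))
            hits += int(np.sum(m.p.values[iu] < 0.05))
            pairs += len(iu[0])
        assert np.mean(rho_abs) < 0.2
        assert 0.02 <= hits / pairs <= 0.09
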