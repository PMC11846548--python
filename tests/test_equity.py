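import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equicast.equity import (
    Basis,
    FairnessLabel,
    build_lorenz,
    classify_gini,
    gini_summation,
    gini_trapezoid,
    theil_decompose,
    theil_total,
)
from equicast.errors import DegenerateInputError, DomainError, GroupingError

from .conftest import random_share_panel

LN2 = math.log(2.0)


def curve_of(pairs, **kw):
    return build_lorenz(pairs, **kw)


class TestBuildLorenz:
    def test_equal_densities_give_diagonal(self):
        curve = curve_of([(1.0, 5.0), (1.0, 5.0)])
        np.testing.assert_allclose(
            curve.points, [[0, 0], [0.5, 0.5], [1, 1]], atol=1e-15
        )

    def test_maximal_two_region_inequality(self):
        curve = curve_of([(1.0, 0.0), (1.0, 10.0)])
        np.testing.assert_allclose(curve.points, [[0, 0], [0.5, 0], [1, 1]])

    def test_three_region_cumulative_shares(self):
        curve = curve_of([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])
        np.testing.assert_allclose(
            curve.points,
            [[0, 0], [1 / 3, 1 / 6], [2 / 3, 1 / 2], [1, 1]],
            atol=1e-15,
        )

    def test_sorted_ascending_by_density(self):
        curve = curve_of(
            [(1.0, 9.0), (1.0, 1.0)], labels=["rich", "poor"]
        )
        assert curve.region_order == ("poor", "rich")

    def test_tie_break_by_label_is_stable(self):
        c1 = curve_of([(1.0, 2.0), (1.0, 2.0)], labels=["b", "a"])
        c2 = curve_of([(1.0, 2.0), (1.0, 2.0)], labels=["a", "b"])
        assert c1.region_order == c2.region_order == ("a", "b")

    def test_single_region_rejected(self):
        with pytest.raises(DomainError):
            curve_of([(1.0, 1.0)])

    def test_zero_total_resource_degenerate(self):
        with pytest.raises(DegenerateInputError):
            curve_of([(1.0, 0.0), (1.0, 0.0)])

    def test_negative_resource_rejected(self):
        with pytest.raises(DomainError):
            curve_of([(1.0, -1.0), (1.0, 2.0)])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(DomainError):
            curve_of([(0.0, 1.0), (1.0, 2.0)])


class TestGini:
    def test_equal_density_zero(self):
        curve = curve_of([(1.0, 3.0), (1.0, 3.0), (1.0, 3.0)])
        assert gini_summation(curve) == pytest.approx(0.0, abs=1e-15)
        assert gini_trapezoid(curve) == pytest.approx(0.0, abs=1e-15)

    def test_two_region_extreme_half(self):
        curve = curve_of([(1.0, 0.0), (1.0, 10.0)])
        assert gini_summation(curve) == pytest.approx(0.5, abs=1e-15)
        assert gini_trapezoid(curve) == pytest.approx(0.5, abs=1e-15)

    def test_three_region_two_ninths(self):
        curve = curve_of([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])
        assert gini_summation(curve) == pytest.approx(2 / 9, abs=1e-15)
        assert gini_trapezoid(curve) == pytest.approx(2 / 9, abs=1e-15)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_summation_equals_trapezoid(self, seed):
        # algebraic identity: 2 V_i - Y_i = V_i + V_{i-1}
        rng = np.random.default_rng(seed)
        weights, resources = random_share_panel(rng)
        curve = build_lorenz(list(zip(weights, resources)))
        assert abs(gini_summation(curve) - gini_trapezoid(curve)) < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        weights, resources = random_share_panel(rng)
        labels = [f"r{i}" for i in range(len(weights))]
        order = rng.permutation(len(weights))
        g1 = gini_summation(build_lorenz(list(zip(weights, resources)), labels=labels))
        g2 = gini_summation(
            build_lorenz(
                list(zip(weights[order], resources[order])),
                labels=[labels[i] for i in order],
            )
        )
        assert g1 == pytest.approx(g2, abs=1e-12)

    @given(seed=st.integers(0, 10_000), frac=st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_transfer_principle(self, seed, frac):
        # moving resource from a denser to a sparser region cannot raise G
        rng = np.random.default_rng(seed)
        weights, resources = random_share_panel(rng)
        density = resources / weights
        rich, poor = int(np.argmax(density)), int(np.argmin(density))
        if rich == poor:
            return
        moved = resources.copy()
        # cap so neither region crosses the other's density (no re-ranking)
        transfer = frac * min(
            resources[rich],
            (density[rich] - density[poor]) * min(weights[rich], weights[poor]) / 2,
        )
        moved[rich] -= transfer
        moved[poor] += transfer
        g_before = gini_summation(build_lorenz(list(zip(weights, resources))))
        g_after = gini_summation(build_lorenz(list(zip(weights, moved))))
        assert g_after <= g_before + 1e-10

    def test_value_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            weights, resources = random_share_panel(rng)
            g = gini_summation(build_lorenz(list(zip(weights, resources))))
            assert 0.0 <= g < 1.0


class TestClassifyGini:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.09, FairnessLabel.ABSOLUTE_FAIRNESS),
            (0.06, FairnessLabel.ABSOLUTE_FAIRNESS),
            (0.25, FairnessLabel.MODERATE_FAIRNESS),
            (0.34, FairnessLabel.RELATIVE_FAIRNESS),
            (0.5, FairnessLabel.INEQUALITY_WARNING),
            (0.61, FairnessLabel.HIGH_INEQUALITY),
        ],
    )
    def test_values(self, value, label):
        assert classify_gini(value) is label

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, FairnessLabel.ABSOLUTE_FAIRNESS),
            (0.2, FairnessLabel.MODERATE_FAIRNESS),
            (0.3, FairnessLabel.RELATIVE_FAIRNESS),
            (0.4, FairnessLabel.INEQUALITY_WARNING),
            (0.6, FairnessLabel.INEQUALITY_WARNING),
            (0.6000001, FairnessLabel.HIGH_INEQUALITY),
        ],
    )
    def test_band_boundaries(self, value, label):
        assert classify_gini(value) is label

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_out_of_domain(self, bad):
        with pytest.raises(DomainError):
            classify_gini(bad)


class TestTheilTotal:
    def test_equality_is_zero(self):
        assert theil_total([20, 20, 20]) == pytest.approx(0.0, abs=1e-15)

    def test_frozen_example(self):
        # (1/3)(0.5 ln 0.5 + 0.5 ln 0.5 + 2 ln 2) = ln(2)/3
        assert theil_total([10, 10, 40]) == pytest.approx(LN2 / 3, abs=1e-14)
        assert LN2 / 3 == pytest.approx(0.23105, abs=5e-6)

    @given(c=st.floats(1e-6, 1e6), seed=st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        counts = np.exp(rng.normal(0, 1, int(rng.integers(2, 30))))
        assert theil_total(counts) == pytest.approx(
            theil_total(c * counts), rel=1e-9, abs=1e-12
        )

    def test_zero_counts_contribute_zero(self):
        # 0 ln 0 -> 0 convention: finite result with zero-count regions
        t = theil_total([0, 10, 20])
        assert np.isfinite(t) and t > 0

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            theil_total([0, 0, 0])

    def test_short_input_rejected(self):
        with pytest.raises(DomainError):
            theil_total([5])

    def test_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = np.exp(rng.normal(0, 2, int(rng.integers(2, 40))))
            assert theil_total(counts) >= 0


def brute_force_decomposition(counts, groups):
    """Direct evaluation of T_B = sum S_p ln(S_p/P_p), T_w = sum S_p T_p."""
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    total = counts.sum()
    n = len(counts)
    tb = tw = 0.0
    for g in np.unique(groups):
        sub = counts[groups == g]
        s_p = sub.sum() / total
        p_p = len(sub) / n
        if s_p > 0:
            tb += s_p * math.log(s_p / p_p)
            mean = sub.mean()
            tp = np.mean([
                (y / mean) * math.log(y / mean) if y > 0 else 0.0 for y in sub
            ])
            tw += s_p * tp
    return tw, tb


class TestTheilDecompose:
    def test_single_group_all_within(self):
        res = theil_decompose([10, 10, 40], ["g", "g", "g"])
        assert res.between == pytest.approx(0.0, abs=1e-14)
        assert res.within == pytest.approx(res.total, abs=1e-14)

    def test_internally_equal_groups_all_between(self):
        res = theil_decompose([10, 10, 40, 40], ["a", "a", "b", "b"])
        assert res.within == pytest.approx(0.0, abs=1e-14)
        assert res.between == pytest.approx(res.total, abs=1e-14)

    def test_frozen_example_split(self):
        res = theil_decompose([10, 10, 40], ["g1", "g1", "g2"])
        tw, tb = brute_force_decomposition([10, 10, 40], ["g1", "g1", "g2"])
        assert res.total == pytest.approx(LN2 / 3, abs=1e-14)
        assert res.within == pytest.approx(tw, abs=1e-14)
        assert res.between == pytest.approx(tb, abs=1e-14)
        assert res.within + res.between == pytest.approx(res.total, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_identity_and_contributions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        counts = np.exp(rng.normal(0, 1.5, n))
        groups = rng.integers(0, max(1, n // 3) + 1, n).astype(str)
        res = theil_decompose(counts, groups)
        assert res.total == pytest.approx(res.within + res.between, abs=1e-12)
        assert res.within >= -1e-15 and res.between >= -1e-15
        if res.total > 0:
            assert res.contribution_within + res.contribution_between == (
                pytest.approx(1.0, abs=1e-9)
            )
        tw, tb = brute_force_decomposition(counts, groups)
        assert res.within == pytest.approx(tw, abs=1e-12)
        assert res.between == pytest.approx(tb, abs=1e-12)

    def test_perfect_equality_flags_contributions_undefined(self):
        res = theil_decompose([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.total == pytest.approx(0.0, abs=1e-15)
        assert res.contribution_within is None
        assert res.contribution_between is None

    def test_unassigned_region_rejected(self):
        with pytest.raises(GroupingError):
            theil_decompose([1, 2, 3], ["a", None, "b"])

    def test_misaligned_groups_rejected(self):
        with pytest.raises(GroupingError):
            theil_decompose([1, 2, 3], ["a", "b"])

    @given(seed=st.integers(0, 5000), frac=st.floats(0.05, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_transfer_principle(self, seed, frac):
        rng = np.random.default_rng(seed)
        counts = np.exp(rng.normal(0, 1, int(rng.integers(3, 30))))
        hi, lo = int(np.argmax(counts)), int(np.argmin(counts))
        moved = counts.copy()
        transfer = frac * (counts[hi] - counts[lo]) / 2
        moved[hi] -= transfer
        moved[lo] += transfer
        assert theil_total(moved) <= theil_total(counts) + 1e-10


class TestPanelIntegration:
    def test_gini_by_both_bases_on_default_panel(self, default_panel):
        from equicast.equity import gini_for_year

        for basis in (Basis.POPULATION, Basis.AREA):
            res = gini_for_year(default_panel, 2022, basis)
            assert 0.0 <= res.value < 1.0
            assert res.fairness_label is classify_gini(res.value)
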