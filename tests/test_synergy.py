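"""Epistatic coefficient, growth-curve AUC machinery, hypothesis tests."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from defensekit.synergy import (
    anova_multcomp,
    area_under_curve,
    baseline_subtract,
    call_auc_synergy,
    epistatic_coefficient,
    normalize_reporter,
    one_sided_greater_test,
    replicate_band,
)

pos_eop = st.floats(1e-10, 1.0, exclude_min=True)


class TestEpsilon:
    def test_hand_evaluated_formula(self):
        res = epistatic_coefficient(1e-6, 1e-2, 1e-1, wt_mean_eop=1e-6)
        assert res.epsilon == pytest.approx(6 - 2 - 1)
        assert not res.zeroed

    def test_multiplicative_eops_give_zero(self):
        res = epistatic_coefficient(1e-3, 1e-2, 1e-1, wt_mean_eop=1e-3)
        assert res.epsilon == pytest.approx(0.0, abs=1e-12)

    def test_zeroing_rule(self):
        res = epistatic_coefficient(1e-6, 1e-2, 1e-1, wt_mean_eop=0.5)
        assert res.epsilon == 0.0 and res.zeroed
        assert res.epsilon_raw == pytest.approx(3.0)  # diagnostics preserved

    def test_zeroing_boundary_is_inclusive(self):
        at = epistatic_coefficient(1e-6, 1e-2, 1e-1, wt_mean_eop=1e-2)
        below = epistatic_coefficient(1e-6, 1e-2, 1e-1, wt_mean_eop=1e-2 * (1 - 1e-9))
        assert at.zeroed and not below.zeroed

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            epistatic_coefficient(0.0, 0.1, 0.1, 0.001)

    @given(eop_both=pos_eop, eop_a=pos_eop, eop_b=pos_eop)
    @settings(max_examples=300, deadline=None)
    def test_log_ratio_identity_for_eops_below_one(self, eop_both, eop_a, eop_b):
        """For EOPs <= 1, epsilon equals log10(eop_a*eop_b/eop_both)."""
        res = epistatic_coefficient(eop_both, eop_a, eop_b, wt_mean_eop=1e-6)
        assert res.epsilon == pytest.approx(
            math.log10(eop_a * eop_b / eop_both), abs=1e-9
        )

    def test_strictly_increasing_as_both_drops(self):
        values = [
            epistatic_coefficient(b, 1e-2, 1e-1, 1e-6).epsilon
            for b in (1e-3, 1e-4, 1e-5, 1e-6)
        ]
        assert values == sorted(values) and len(set(values)) == len(values)


class TestGrowthCurves:
    def test_baseline_subtract(self):
        np.testing.assert_allclose(baseline_subtract([0.3] * 10), np.zeros(10))
        np.testing.assert_allclose(baseline_subtract([0.1, 0.2, 0.4]), [0, 0.1, 0.3])

    def test_baseline_subtract_idempotent(self):
        once = baseline_subtract([0.2, 0.5, 0.9])
        np.testing.assert_allclose(baseline_subtract(once), once)

    def test_auc_triangle_and_zero(self):
        t = np.arange(0, 61, 10.0)
        assert area_under_curve(np.zeros_like(t), t) == 0.0
        rise = t / 60.0  # 0 -> 1 OD over one hour
        assert area_under_curve(rise, t) == pytest.approx(0.5)

    def test_auc_quadratic_against_analytic_integral(self):
        t = np.arange(0, 61, 10.0)
        y = (t / 60.0) ** 2
        # trapezoid overestimates a convex curve by (b-a)h^2 f''/12 = 0.46%
        # of the range, i.e. 1.4% of the 1/3 integral at 10-min sampling
        assert area_under_curve(y, t) == pytest.approx(1 / 3, rel=0.015)

    def test_auc_linearity(self):
        t = np.arange(0, 101, 10.0)
        f, g = np.sin(t / 30.0), np.cos(t / 40.0)
        lhs = area_under_curve(2.0 * f + 3.0 * g, t)
        rhs = 2.0 * area_under_curve(f, t) + 3.0 * area_under_curve(g, t)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_auc_validation(self):
        with pytest.raises(ValueError):
            area_under_curve([1, 2, 3], [0, 10])
        with pytest.raises(ValueError, match="increasing"):
            area_under_curve([1, 2, 3], [0, 10, 5])

    def test_synergy_call_strict(self):
        assert call_auc_synergy(10, 3, 4).synergy
        assert not call_auc_synergy(7, 3, 4).synergy  # equality is not synergy
        assert call_auc_synergy(7, 3, 4).expected_additive == 7


class TestReporterNormalization:
    def test_identity_and_linearity(self):
        od = np.array([0.1, 0.5, 1.0])
        out, flagged = normalize_reporter(od, od)
        np.testing.assert_allclose(out, 1.0)
        assert not flagged.any()
        out2, _ = normalize_reporter(2 * od, od)
        np.testing.assert_allclose(out2, 2.0)

    def test_floor_applied_and_flagged(self):
        out, flagged = normalize_reporter([5.0, 5.0], [0.001, 0.5], floor_od=0.01)
        assert out[0] == pytest.approx(5.0 / 0.01)
        assert flagged.tolist() == [True, False]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            normalize_reporter([1.0], [1.0, 2.0])


class TestReplicateBand:
    def test_identical_replicates_zero_width(self):
        mean, lo, hi = replicate_band([[0.2, 0.4], [0.2, 0.4], [0.2, 0.4]])
        np.testing.assert_allclose(lo, hi)
        np.testing.assert_allclose(mean, [0.2, 0.4])

    def test_t_table_half_width(self):
        """n=3 at one point: half-width = t_{.975,2} * sd / sqrt(3)."""
        mean, lo, hi = replicate_band([[0.1], [0.2], [0.3]])
        sd = np.std([0.1, 0.2, 0.3], ddof=1)
        expected = 4.302652729911275 * sd / math.sqrt(3)
        assert mean[0] == pytest.approx(0.2)
        assert (hi - mean)[0] == pytest.approx(expected, rel=1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            replicate_band([[1.0, 2.0]])


class TestHypothesisTests:
    def test_separated_samples_significant(self):
        res = one_sided_greater_test([5, 6, 7], [1, 2, 3])
        assert res.p_value < 0.01
        # cross-check against the Welch t computed directly
        direct = stats.ttest_ind([5, 6, 7], [1, 2, 3], equal_var=False,
                                 alternative="greater")
        assert res.statistic == pytest.approx(direct.statistic)

    def test_swap_identity(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 8), rng.normal(0.3, 1.2, 6)
        p_xy = one_sided_greater_test(x, y).p_value
        p_yx = one_sided_greater_test(y, x).p_value
        assert p_xy + p_yx == pytest.approx(1.0, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            one_sided_greater_test([1.0], [1.0, 2.0])

    def test_nonnormal_sample_warns_but_reports(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 2, 30))  # heavy-tailed
        y = rng.normal(0, 1, 30)
        with pytest.warns(UserWarning, match="normality"):
            res = one_sided_greater_test(x, y)
        assert 0 <= res.p_value <= 1
        assert res.normality_p[0] < 0.05


class TestAnovaMultcomp:
    GROUPS = {
        "control": [1.0, 2.0, 3.0],
        "g1": [2.0, 3.0, 4.0],
        "g2": [6.0, 7.0, 8.0],
    }

    def test_f_matches_hand_computed_table(self):
        """Textbook one-way ANOVA: SSB=42 (df 2), SSW=6 (df 6) => F=21."""
        f, p, _ = anova_multcomp(self.GROUPS, control="control")
        assert f == pytest.approx(21.0, abs=1e-6)
        assert p == pytest.approx(stats.f.sf(21.0, 2, 6), abs=1e-9)

    def test_dunnett_flags_separated_group_only(self):
        _, _, table = anova_multcomp(self.GROUPS, control="control")
        sig = dict(zip(table["group"], table["significant"]))
        assert sig["g2"] and not sig["g1"]

    def test_adjusted_p_never_below_unadjusted(self):
        for method in ("dunnett", "holm"):
            _, _, table = anova_multcomp(self.GROUPS, control="control",
                                         method=method)
            assert (table["p_adjusted"] >= table["p_unadjusted"] - 1e-3).all()

    def test_identical_groups_nothing_significant(self):
        groups = {
            "control": [1.0, 1.001, 0.999],
            "a": [1.0005, 0.9995, 1.0],
            "b": [1.001, 0.999, 1.0002],
        }
        _, _, table = anova_multcomp(groups, control="control")
        assert not table["significant"].any()

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            anova_multcomp({"only": [1.0, 2.0]}, control="only")
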