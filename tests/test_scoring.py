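"""Per-indicator A/B/C assembly, liver gates and the composite patient score."""

import math

import numpy as np
import pytest

from qdscore import (
    LIVER_PANEL,
    PHI,
    ContractError,
    IndicatorScore,
    IndicatorSpec,
    InputError,
    LiverRule,
    PairedMeasurement,
    liver_modification,
    normal_range_score,
    score_indicator,
    score_patient,
)


def liver_score(indicator, a, b, c):
    return IndicatorScore(indicator=indicator, a=a, b=b, c=c, l_tau=0.0, is_liver_panel=True)


class TestNormalRangeScore:
    def test_both_above_post_closer(self):
        spec = IndicatorSpec("total_bilirubin", "umol/L", ref_low=3.4, ref_high=21)
        assert normal_range_score(375.23, 220.75, spec) == 1

    def test_both_below_post_farther(self):
        spec = IndicatorSpec("hemoglobin", "g/L", ref_low=130, ref_high=175)
        assert normal_range_score(112.47, 89.53, spec) == -1

    def test_both_inside_is_improvement(self):
        spec = IndicatorSpec("x", ref_low=10, ref_high=20)
        assert normal_range_score(12.0, 18.0, spec) == 1

    def test_equal_distance_outside_is_zero(self):
        spec = IndicatorSpec("x", ref_low=10, ref_high=20)
        # both 50% above the upper bound / below the lower bound relatively
        assert normal_range_score(30.0, 30.0, spec) == 0
        assert normal_range_score(30.0, 5.0, spec) == 0  # 0.5 above vs 0.5 below

    def test_overshoot_across_the_interval(self):
        spec = IndicatorSpec("x", ref_low=10, ref_high=20)
        # from 100% above the upper bound to 10% below the lower bound: closer
        assert normal_range_score(40.0, 9.0, spec) == 1
        # from just above to far below: farther
        assert normal_range_score(22.0, 1.0, spec) == -1

    def test_open_ended_interval(self):
        spec = IndicatorSpec("conjugated_bilirubin", ref_high=6.8)
        assert normal_range_score(100.0, 5.0, spec) == 1  # into range
        assert normal_range_score(1.0, 0.1, spec) == 1  # both inside (no lower bound)


class TestScoreIndicator:
    def test_alt_strong_responder(self):
        spec = IndicatorSpec("alanine_aminotransferase", "U/L", ref_low=7, ref_high=40,
                             is_liver_panel=True)
        s = score_indicator(PairedMeasurement("alanine_aminotransferase", 689.29, 50.58), spec)
        assert (s.a, s.b, s.c, s.product) == (1, 3, 1, 3)
        assert s.l_tau == pytest.approx(5.429, abs=1e-2)
        assert s.is_liver_panel

    def test_tie_annihilates(self):
        spec = IndicatorSpec("x", ref_low=1, ref_high=2)
        s = score_indicator(PairedMeasurement("x", 5.0, 5.0), spec)
        assert s.a == 0 and s.product == 0

    def test_double_negative_product_is_positive(self):
        # worsening far out of range: a=-1, c=-1, product = +b — the literal
        # A*B*C algebra, kept on purpose and exposed in the breakdown
        spec = IndicatorSpec("x", ref_low=7, ref_high=40)
        s = score_indicator(PairedMeasurement("x", 50.0, 200.0), spec)
        assert s.a == -1 and s.c == -1
        assert s.b == 3  # L_tau = ln(4)/ln(phi) = 2.881 > 1.69
        assert s.l_tau == pytest.approx(math.log(4) / math.log(PHI), abs=1e-12)
        assert s.product == 3

    def test_per_indicator_scheme_override(self):
        spec = IndicatorSpec("x", ref_high=40, scheme="organ_tissue")
        s = score_indicator(PairedMeasurement("x", 100.0, 60.0), spec)
        # L_tau = ln(5/3)/ln(phi) = 1.061: bucket 1 molecular, 2 organ/tissue
        assert s.b == 2


class TestLiverModification:
    def test_full_response_opens_both_gates(self):
        scores = [liver_score(n, 1, 3, 1) for n in LIVER_PANEL]
        assert liver_modification(scores) == (1, 1, 12)

    def test_partial_decrease_closes_d_gate(self):
        # only transaminases decreased — the non-survivor pattern
        a_values = dict(zip(LIVER_PANEL, (1, 1, -1, -1)))
        scores = [liver_score(n, a_values[n], 3, 1) for n in LIVER_PANEL]
        d, e, contribution = liver_modification(scores)
        assert d == 0 and contribution == 0

    def test_sum_b_boundary_nine_is_inclusive(self):
        b_values = dict(zip(LIVER_PANEL, (3, 3, 3, 0)))
        scores = [liver_score(n, 1, b_values[n], 1) for n in LIVER_PANEL]
        d, e, contribution = liver_modification(scores)
        assert (d, e) == (1, 1)
        assert contribution == 9
        # one notch below the boundary closes E
        b_values = dict(zip(LIVER_PANEL, (3, 3, 2, 0)))
        scores = [liver_score(n, 1, b_values[n], 1) for n in LIVER_PANEL]
        assert liver_modification(scores)[1:] == (0, 0)

    def test_wrong_indicator_set_is_a_contract_error(self):
        scores = [liver_score(n, 1, 3, 1) for n in LIVER_PANEL[:3]]
        scores.append(liver_score("hemoglobin", 1, 3, 1))
        with pytest.raises(ContractError):
            liver_modification(scores)

    @pytest.mark.parametrize(
        "rule, expected",
        [
            (LiverRule("gated_sum"), 12),
            (LiverRule("flat_bonus", bonus=5), 5),
            (LiverRule("ungated_plus_bonus", bonus=5), 17),
        ],
    )
    def test_combination_rules_gates_open(self, rule, expected):
        scores = [liver_score(n, 1, 3, 1) for n in LIVER_PANEL]
        assert liver_modification(scores, rule)[2] == expected

    def test_ungated_rule_keeps_panel_sum_when_gates_closed(self):
        a_values = dict(zip(LIVER_PANEL, (1, 1, 1, -1)))
        scores = [liver_score(n, a_values[n], 3, 1) for n in LIVER_PANEL]
        assert liver_modification(scores, LiverRule("ungated_plus_bonus", bonus=5))[2] == 6

    def test_unknown_rule_rejected(self):
        with pytest.raises(ContractError):
            LiverRule("bogus")


class TestScorePatient:
    def _panel(self, registry, ratios):
        # pre-treatment values far above each upper bound, so a falling
        # indicator always moves toward its reference interval
        return {
            name: (pre, pre * ratios.get(name, 1.0))
            for name, pre in (
                (n, (registry[n].ref_high or registry[n].ref_low) * 20.0)
                for n in registry
            )
        }

    def test_all_ties_score_zero(self, registry):
        panel = {name: (10.0, 10.0) for name in registry}
        bd = score_patient(panel, registry)
        assert bd.total == 0 and bd.d_gate == 0

    def test_strong_responder_scores_twelve(self, registry):
        # liver panel falls by more than phi^1.69 toward range, all else unchanged
        ratios = {name: 1 / PHI**2.0 for name in LIVER_PANEL}
        panel = self._panel(registry, ratios)
        bd = score_patient(panel, registry)
        assert (bd.d_gate, bd.e_gate) == (1, 1)
        assert bd.liver_contribution == 12
        assert bd.non_liver_sum == 0
        assert bd.total == 12

    def test_non_responder_liver_contributes_nothing(self, registry):
        ratios = {
            "alanine_aminotransferase": 0.2,
            "aspartate_aminotransferase": 0.2,
            "total_bilirubin": 2.0,
            "conjugated_bilirubin": 2.0,
        }
        bd = score_patient(self._panel(registry, ratios), registry)
        assert bd.d_gate == 0 and bd.liver_contribution == 0
        assert bd.total <= 0

    def test_missing_values_skipped_and_listed(self, registry):
        panel = {name: (10.0, 10.0) for name in registry}
        panel["hemoglobin"] = (float("nan"), 120.0)
        bd = score_patient(panel, registry)
        assert bd.skipped == ("hemoglobin",)
        assert bd.total == 0

    def test_incomplete_liver_panel_warns_and_undefines_gates(self, registry):
        panel = {name: (10.0, 5.0) for name in registry if name != "total_bilirubin"}
        with pytest.warns(UserWarning, match="liver panel incomplete"):
            bd = score_patient(panel, registry)
        assert bd.d_gate is None and bd.e_gate is None
        assert not bd.gates_defined
        assert bd.liver_contribution == 0

    def test_empty_panel_rejected(self, registry):
        with pytest.raises(InputError):
            score_patient({}, registry)

    def test_deterministic_and_bounded(self, registry, rng):
        for _ in range(50):
            panel = {
                name: tuple(np.exp(rng.normal(3, 1, size=2))) for name in registry
            }
            bd1 = score_patient(panel, registry)
            bd2 = score_patient(panel, registry)
            assert bd1 == bd2
            n_non_liver = sum(
                1 for s in bd1.per_indicator if not s.is_liver_panel
            )
            assert abs(bd1.total) <= 3 * n_non_liver + 12

    def test_annihilation_removing_zero_product_indicator(self, registry):
        panel = {name: (10.0, 10.0) for name in registry}
        panel["hemoglobin"] = (160.0, 80.0)  # only contributor
        bd_full = score_patient(panel, registry)
        del panel["glucose"]  # product 0: removal must not change the total
        bd_less = score_patient(panel, registry)
        assert bd_full.total == bd_less.total

    def test_gate_soundness_random_panels(self, registry, rng):
        # liver contribution must vanish whenever any liver indicator rose
        for _ in range(2_000):
            panel = {
                name: tuple(np.exp(rng.normal(3.0, 1.5, size=2)))
                for name in LIVER_PANEL
            }
            panel["hemoglobin"] = (140.0, 140.0)  # keep the panel scoreable
            bd = score_patient(panel, registry)
            if any(post > pre for pre, post in (panel[n] for n in LIVER_PANEL)):
                assert bd.d_gate == 0 and bd.liver_contribution == 0
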