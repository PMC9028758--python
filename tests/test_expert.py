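"""Weighted rule evaluation, plan classification, and its brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ichtriage.case_model import CaseFacts, TreatmentPlan
from ichtriage.expert import (
    Condition,
    LogicRule,
    LogicTable,
    LogicTableError,
    classify_plan,
    compute_weighted_score,
    evaluate_rules,
    explain_decision,
)


def fired_ids(facts, table):
    return [f.rule_id for f in evaluate_rules(facts, table) if f.fired]


class TestRuleEvaluation:
    def test_all_unknown_fires_nothing(self, table):
        firings = evaluate_rules(CaseFacts(), table)
        assert not any(f.fired for f in firings)
        assert len(firings) == len(table.rules)  # one entry per rule, in order

    def test_large_supratentorial_volume_fires(self, table):
        facts = CaseFacts(hematoma_volume_ml=50, bleed_location="basal_ganglia")
        assert "supratentorial_large_volume" in fired_ids(facts, table)

    def test_cerebellar_volume_mandate_fires(self, table):
        facts = CaseFacts(bleed_location="cerebellum", hematoma_volume_ml=12)
        firings = {f.rule_id: f for f in evaluate_rules(facts, table)}
        assert firings["cerebellar_volume"].fired and firings["cerebellar_volume"].mandate

    def test_unknown_field_in_predicate_rejected_at_load(self):
        doc = {"cut_high": 0.5, "cut_low": 0.1,
               "rules": [{"rule_id": "bad", "weight": 1,
                          "when": [{"field": "no_such", "op": "eq", "value": 1}]}]}
        with pytest.raises(LogicTableError, match="no_such"):
            LogicTable.from_dict(doc)

    def test_invalid_cutpoints_rejected(self):
        with pytest.raises(LogicTableError):
            LogicTable(rules=(LogicRule("r", (Condition("gcs_total", "le", 8),), 1.0),),
                       cut_high=0.2, cut_low=0.4)


class TestWeightedScore:
    def test_empty_sum_is_zero(self, table):
        assert compute_weighted_score(evaluate_rules(CaseFacts(), table), table) == 0.0

    def test_all_rules_fired_normalises_to_one(self):
        t = LogicTable(
            rules=(
                LogicRule("a", (Condition("gcs_total", "le", 15),), 3.0),
                LogicRule("b", (Condition("gcs_total", "ge", 3),), 7.0),
            ),
            cut_high=0.5, cut_low=0.1,
        )
        firings = evaluate_rules(CaseFacts(gcs_total=8), t)
        assert compute_weighted_score(firings, t) == 1.0

    def test_hand_arithmetic(self):
        t = LogicTable(
            rules=(
                LogicRule("a", (Condition("gcs_total", "le", 8),), 3.0),
                LogicRule("b", (Condition("midline_shift_mm", "ge", 5),), 2.0),
                LogicRule("c", (Condition("hematoma_volume_ml", "ge", 99),), 5.0),
            ),
            cut_high=0.5, cut_low=0.1,
        )
        firings = evaluate_rules(CaseFacts(gcs_total=7, midline_shift_mm=8), t)
        assert compute_weighted_score(firings, t) == pytest.approx(0.5)


class TestClassify:
    @pytest.mark.parametrize(
        "facts,expected",
        [
            (dict(bleed_location="basal_ganglia", hematoma_volume_ml=50,
                  gcs_total=7, midline_shift_mm=8), TreatmentPlan.PLAN_I),
            (dict(bleed_location="lobar", hematoma_volume_ml=8, gcs_total=15,
                  condition_trend="stable", midline_shift_mm=0), TreatmentPlan.PLAN_IIB),
            (dict(bleed_location="basal_ganglia", hematoma_volume_ml=25,
                  gcs_total=13, midline_shift_mm=3,
                  condition_trend="deteriorating"), TreatmentPlan.PLAN_IIA),
        ],
    )
    def test_reference_cases(self, table, facts, expected):
        assert classify_plan(CaseFacts(**facts), table).plan is expected

    def test_score_at_cutpoint_takes_aggressive_plan(self):
        # weights sum to 10; firing exactly 5 hits cut_high, 2 hits cut_low
        t = LogicTable(
            rules=(
                LogicRule("five", (Condition("gcs_total", "le", 8),), 5.0),
                LogicRule("two", (Condition("midline_shift_mm", "ge", 5),), 2.0),
                LogicRule("three", (Condition("hematoma_volume_ml", "ge", 99),), 3.0),
            ),
            cut_high=0.5, cut_low=0.2,
        )
        at_high = classify_plan(CaseFacts(gcs_total=7), t)
        assert at_high.weighted_score == 0.5 and at_high.plan is TreatmentPlan.PLAN_I
        at_low = classify_plan(CaseFacts(midline_shift_mm=6), t)
        assert at_low.weighted_score == 0.2 and at_low.plan is TreatmentPlan.PLAN_IIA

    def test_mandate_overrides_low_score(self, table):
        decision = classify_plan(
            CaseFacts(bleed_location="cerebellum", hematoma_volume_ml=15), table
        )
        assert decision.plan is TreatmentPlan.PLAN_I and decision.mandated
        assert decision.weighted_score < table.cut_high

    def test_insufficient_data_warning(self, table):
        decision = classify_plan(CaseFacts(), table)
        assert any("insufficient data" in w for w in decision.warnings)


# independent oracle: a naive evaluator written from the rule semantics
def _oracle_plan(facts: CaseFacts, table: LogicTable) -> TreatmentPlan:
    import enum

    def holds(c):
        v = getattr(facts, c.field)
        if c.op == "is_unknown":
            return v is None
        if v is None:
            return False
        if isinstance(v, enum.Enum):
            v = v.value
        return {
            "eq": lambda: v == c.value,
            "ne": lambda: v != c.value,
            "lt": lambda: v < c.value,
            "le": lambda: v <= c.value,
            "gt": lambda: v > c.value,
            "ge": lambda: v >= c.value,
            "in": lambda: v in c.value,
            "contains": lambda: c.value in {getattr(x, "value", x) for x in v},
        }[c.op]()

    fired = [r for r in table.rules if all(holds(c) for c in r.conditions)]
    if any(r.mandate for r in fired):
        return TreatmentPlan.PLAN_I
    score = sum(r.weight for r in fired) / sum(r.weight for r in table.rules)
    if score >= table.cut_high:
        return TreatmentPlan.PLAN_I
    if score >= table.cut_low:
        return TreatmentPlan.PLAN_IIA
    return TreatmentPlan.PLAN_IIB


_maybe = lambda s: st.none() | s  # noqa: E731

facts_strategy = st.builds(
    CaseFacts,
    gcs_total=_maybe(st.integers(3, 15)),
    hematoma_volume_ml=_maybe(st.floats(0, 150, allow_nan=False)),
    midline_shift_mm=_maybe(st.floats(0, 25, allow_nan=False)),
    bleed_location=_maybe(st.sampled_from(
        ["basal_ganglia", "thalamus", "lobar", "cerebellum", "brainstem",
         "intraventricular_primary"])),
    pupil_state=_maybe(st.sampled_from(
        ["equal_reactive", "anisocoria", "bilateral_fixed_dilated"])),
    consciousness_grade=_maybe(st.sampled_from(["alert", "drowsy", "stupor", "coma"])),
    ventricle_cast=_maybe(st.sampled_from(["present", "absent"])),
    pathological_reflex=_maybe(st.sampled_from(["present", "absent"])),
    condition_trend=_maybe(st.sampled_from(["stable", "deteriorating"])),
)


@given(facts=facts_strategy)
@settings(max_examples=300)
def test_classifier_matches_bruteforce_oracle(table, facts):
    decision = classify_plan(facts, table)
    assert decision.plan is _oracle_plan(facts, table)
    assert 0.0 <= decision.weighted_score <= 1.0


@given(facts=facts_strategy)
@settings(max_examples=200)
def test_score_monotone_under_added_severity(table, facts):
    """Raising volume or lowering GCS never demotes the plan."""
    base = classify_plan(facts, table)
    worse_vol = facts.model_copy(
        update={"hematoma_volume_ml": (facts.hematoma_volume_ml or 0) + 20}
    )
    worse_gcs = facts.model_copy(
        update={"gcs_total": max(3, (facts.gcs_total or 15) - 4),
                "gcs_eye": None, "gcs_verbal": None, "gcs_motor": None}
    )
    assert classify_plan(worse_vol, table).plan.severity >= base.plan.severity
    assert classify_plan(worse_gcs, table).plan.severity >= base.plan.severity


class TestExplain:
    def test_mandated_decision_names_mandating_rule(self, table):
        d = classify_plan(CaseFacts(pupil_state="bilateral_fixed_dilated"), table)
        assert "bilateral_fixed_pupils" in explain_decision(d, table)

    def test_empty_decision_states_zero_score_and_plan(self, table):
        text = explain_decision(classify_plan(CaseFacts(), table), table)
        assert "IIB" in text and "score 0" in text

    def test_fired_rules_listed_in_table_order(self, table):
        facts = CaseFacts(gcs_total=7, midline_shift_mm=9)
        d = classify_plan(facts, table)
        text = explain_decision(d, table)
        assert text.index("low_gcs") < text.index("midline_shift")
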