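"""Expert module: logical judgment of extracted clinical facts.

A logic table is an ordered set of rules, each a conjunction of field
comparators over :class:`~ichtriage.case_model.CaseFacts`.  Rules either carry
a non-negative weight (the fired weights sum into a score normalised to
[0, 1]) or a *mandate* flag, which forces emergency surgery (Plan I)
regardless of score.  The score is thresholded into the three plans:

    score >= cut_high          -> Plan I
    cut_low <= score < cut_high -> Plan IIA
    score < cut_low            -> Plan IIB

Ties at a cut-point classify into the more aggressive plan (clinical safety
bias).  Unknown fields never satisfy a comparator — missing data can never
mandate surgery — but a warning is attached when both GCS and hematoma volume
are unknown, since the score is then nearly meaningless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

from .case_model import CaseFacts, PlanDecision, TreatmentPlan

_OPS = ("eq", "ne", "lt", "le", "gt", "ge", "in", "contains", "is_unknown")


class LogicTableError(ValueError):
    """Logic-table configuration problem, raised at load time."""


@dataclass(frozen=True)
class Condition:
    field: str
    op: str
    value: object = None

    def holds(self, facts: CaseFacts) -> bool:
        v = getattr(facts, self.field)
        if self.op == "is_unknown":
            return v is None
        if v is None:
            return False
        if isinstance(v, enum.Enum):
            v = v.value
        if self.op == "eq":
            return v == self.value
        if self.op == "ne":
            return v != self.value
        if self.op == "lt":
            return v < self.value
        if self.op == "le":
            return v <= self.value
        if self.op == "gt":
            return v > self.value
        if self.op == "ge":
            return v >= self.value
        if self.op == "in":
            return v in self.value
        if self.op == "contains":
            members = {m.value if isinstance(m, enum.Enum) else m for m in v}
            return self.value in members
        raise LogicTableError(f"unknown comparator {self.op!r}")


@dataclass(frozen=True)
class LogicRule:
    rule_id: str
    conditions: tuple[Condition, ...]
    weight: float = 0.0
    mandate: bool = False

    def fires(self, facts: CaseFacts) -> bool:
        return all(c.holds(facts) for c in self.conditions)


@dataclass(frozen=True)
class RuleFiring:
    rule_id: str
    fired: bool
    weight: float
    mandate: bool


@dataclass(frozen=True)
class LogicTable:
    rules: tuple[LogicRule, ...]
    cut_high: float
    cut_low: float

    def __post_init__(self) -> None:
        if not (0 <= self.cut_low < self.cut_high <= 1):
            raise LogicTableError(
                f"cut-points must satisfy 0 <= cut_low < cut_high <= 1, "
                f"got cut_low={self.cut_low}, cut_high={self.cut_high}"
            )
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise LogicTableError("rule_id values must be unique within a table")
        if any(r.weight < 0 for r in self.rules):
            raise LogicTableError("rule weights must be non-negative")
        if self.total_weight <= 0:
            raise LogicTableError("sum of rule weights (the normalizer) must be > 0")

    @property
    def total_weight(self) -> float:
        return sum(r.weight for r in self.rules)

    def replace_cuts(self, cut_high: Optional[float] = None,
                     cut_low: Optional[float] = None) -> "LogicTable":
        return LogicTable(
            rules=self.rules,
            cut_high=self.cut_high if cut_high is None else cut_high,
            cut_low=self.cut_low if cut_low is None else cut_low,
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "LogicTable":
        valid_fields = set(CaseFacts.model_fields)
        rules = []
        for raw in doc.get("rules", []):
            rid = raw.get("rule_id")
            if not rid:
                raise LogicTableError("every rule needs a rule_id")
            conds = []
            for c in raw.get("when", []):
                f, op = c.get("field"), c.get("op")
                if f not in valid_fields:
                    raise LogicTableError(
                        f"rule {rid!r}: predicate references unknown field {f!r}"
                    )
                if op not in _OPS:
                    raise LogicTableError(f"rule {rid!r}: unknown comparator {op!r}")
                value = c.get("value")
                if op == "in":
                    value = tuple(value)
                conds.append(Condition(f, op, value))
            if not conds:
                raise LogicTableError(f"rule {rid!r}: empty predicate")
            rules.append(
                LogicRule(
                    rule_id=rid,
                    conditions=tuple(conds),
                    weight=float(raw.get("weight", 0.0)),
                    mandate=bool(raw.get("mandate", False)),
                )
            )
        return cls(
            rules=tuple(rules),
            cut_high=float(doc["cut_high"]),
            cut_low=float(doc["cut_low"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "LogicTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "LogicTable":
        text = resources.files("ichtriage.data").joinpath("logic_table.yaml").read_text("utf-8")
        return cls.from_dict(yaml.safe_load(text))


def evaluate_rules(facts: CaseFacts, table: LogicTable) -> list[RuleFiring]:
    """Evaluate every rule in table order; pure function of (facts, table)."""
    return [
        RuleFiring(r.rule_id, r.fires(facts), r.weight, r.mandate)
        for r in table.rules
    ]


def compute_weighted_score(firings: list[RuleFiring], table: LogicTable) -> float:
    """(sum of fired weights) / (sum of all weights); 0 when nothing fires."""
    return sum(f.weight for f in firings if f.fired) / table.total_weight


def classify_plan(facts: CaseFacts, table: LogicTable) -> PlanDecision:
    """Map facts to a treatment plan with fired-rule rationale."""
    firings = evaluate_rules(facts, table)
    score = compute_weighted_score(firings, table)
    mandated = any(f.fired and f.mandate for f in firings)
    if mandated or score >= table.cut_high:
        plan = TreatmentPlan.PLAN_I
    elif score >= table.cut_low:
        plan = TreatmentPlan.PLAN_IIA
    else:
        plan = TreatmentPlan.PLAN_IIB
    warnings = ()
    if facts.gcs_total is None and facts.hematoma_volume_ml is None:
        warnings = (
            "insufficient data: both GCS total and hematoma volume are unknown",
        )
    return PlanDecision(
        plan=plan,
        weighted_score=score,
        fired_rules=tuple((f.rule_id, f.weight) for f in firings if f.fired),
        mandated=mandated,
        warnings=warnings,
    )


def explain_decision(decision: PlanDecision, table: LogicTable) -> str:
    """Human-readable rationale; purely presentational, no recomputation."""
    lines = [f"plan: {decision.plan.value} (coarse {decision.plan.coarse.value})"]
    if decision.mandated:
        mandating = [rid for rid, _ in decision.fired_rules
                     if any(r.rule_id == rid and r.mandate for r in table.rules)]
        lines.append("mandatory-surgery rule fired: " + ", ".join(mandating))
    lines.append(
        f"weighted score: {decision.weighted_score:.4f} "
        f"(cut_high={table.cut_high}, cut_low={table.cut_low})"
    )
    if decision.fired_rules:
        lines.append("fired rules:")
        for rid, w in decision.fired_rules:
            lines.append(f"  - {rid} (weight {w:g})")
    else:
        lines.append("no rules fired; score 0")
    for w in decision.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)
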