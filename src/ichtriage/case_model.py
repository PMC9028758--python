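"""Domain types shared by every pipeline stage.

The pipeline moves a case through three representations:

``EmrRecord``
    One raw emergency electronic medical record (eEMR): an identifier,
    demographics, and five narrative text sections (chief complaint, history,
    physical examination, CT report).

``CaseFacts``
    The normalised clinical variables extracted from the narrative — GCS,
    vital signs, pupil state, hematoma location and volume, midline shift,
    ventricular involvement, and so on.  Emergency records are lossy, so
    *every* field supports an explicit unknown state, encoded as ``None``
    (never a sentinel number).

``PlanDecision``
    The expert module's output: a treatment plan (I / IIA / IIB), the
    normalised weighted score in [0, 1], and the fired-rule rationale.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, field_serializer, field_validator


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Consciousness(str, enum.Enum):
    alert = "alert"
    drowsy = "drowsy"
    stupor = "stupor"
    coma = "coma"


class TriState(str, enum.Enum):
    """Presence/absence for findings where absence is itself informative.

    The third state (not assessed / not mentioned) is ``None`` on the field.
    """

    present = "present"
    absent = "absent"


class PupilState(str, enum.Enum):
    equal_reactive = "equal_reactive"
    anisocoria = "anisocoria"
    bilateral_fixed_dilated = "bilateral_fixed_dilated"


class Symptom(str, enum.Enum):
    headache = "headache"
    nausea = "nausea"
    vomiting = "vomiting"


class BleedLocation(str, enum.Enum):
    basal_ganglia = "basal_ganglia"
    thalamus = "thalamus"
    lobar = "lobar"
    cerebellum = "cerebellum"
    brainstem = "brainstem"
    intraventricular_primary = "intraventricular_primary"


#: Locations above the tentorium; several surgical-indication rules apply
#: only here (infratentorial bleeds follow their own rules).
SUPRATENTORIAL = frozenset(
    {BleedLocation.basal_ganglia, BleedLocation.thalamus, BleedLocation.lobar}
)


class Laterality(str, enum.Enum):
    left = "left"
    right = "right"
    bilateral = "bilateral"
    midline = "midline"


class Trend(str, enum.Enum):
    stable = "stable"
    deteriorating = "deteriorating"


class TreatmentPlan(str, enum.Enum):
    """Triage plan: I = emergency surgery; IIA = no surgical indication for
    now but unstable (may need surgery on deterioration); IIB = stable, drug
    treatment only."""

    PLAN_I = "I"
    PLAN_IIA = "IIA"
    PLAN_IIB = "IIB"

    @property
    def coarse(self) -> "CoarsePlan":
        return CoarsePlan.PLAN_I if self is TreatmentPlan.PLAN_I else CoarsePlan.PLAN_II

    @property
    def severity(self) -> int:
        """Clinical aggressiveness order: IIB < IIA < I."""
        return {"IIB": 0, "IIA": 1, "I": 2}[self.value]


class CoarsePlan(str, enum.Enum):
    PLAN_I = "I"
    PLAN_II = "II"


class EmrRecord(BaseModel):
    """One raw emergency medical record."""

    model_config = ConfigDict(frozen=True)

    record_id: str
    age: Optional[int] = None
    sex: Optional[Sex] = None
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    chief_complaint: str = ""
    history: str = ""
    physical_exam: str = ""
    ct_report: str = ""

    @field_validator("record_id")
    @classmethod
    def _non_empty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("record_id must be non-empty")
        return v

    def to_json_dict(self) -> dict:
        """JSON Lines dialect: unknown optional fields omitted."""
        return self.model_dump(mode="json", exclude_none=True)


class CaseFacts(BaseModel):
    """Normalised clinical variables; ``None`` means unknown."""

    model_config = ConfigDict(frozen=True)

    gcs_eye: Optional[int] = None
    gcs_verbal: Optional[int] = None
    gcs_motor: Optional[int] = None
    gcs_total: Optional[int] = None
    heart_rate: Optional[float] = None
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    spo2: Optional[float] = None
    consciousness_grade: Optional[Consciousness] = None
    pathological_reflex: Optional[TriState] = None
    pupil_state: Optional[PupilState] = None
    symptoms: frozenset[Symptom] = frozenset()
    bleed_location: Optional[BleedLocation] = None
    laterality: Optional[Laterality] = None
    hematoma_volume_ml: Optional[float] = None
    ventricle_cast: Optional[TriState] = None
    ventricle_shape_abnormal: Optional[TriState] = None
    midline_shift_mm: Optional[float] = None
    condition_trend: Optional[Trend] = None

    @field_serializer("symptoms")
    def _sorted_symptoms(self, v: frozenset[Symptom]) -> list[str]:
        return sorted(s.value for s in v)

    def to_json_dict(self) -> dict:
        """JSON Lines dialect: unknown encoded as null."""
        return self.model_dump(mode="json")


@dataclass(frozen=True)
class FiredRule:
    rule_id: str
    weight: float


class PlanDecision(BaseModel):
    plan: TreatmentPlan
    weighted_score: float
    fired_rules: tuple[tuple[str, float], ...] = ()
    mandated: bool = False
    warnings: tuple[str, ...] = ()

    @field_validator("weighted_score")
    @classmethod
    def _score_in_unit_interval(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("weighted_score must lie in [0, 1]")
        return v


class GcsRangeError(ValueError):
    """A GCS component outside its legal range."""


_GCS_RANGES = {"eye": (1, 4), "verbal": (1, 5), "motor": (1, 6)}


def compute_gcs_total(eye: int, verbal: int, motor: int) -> int:
    """Sum the three Glasgow Coma Scale components (range 3-15)."""
    for name, value in (("eye", eye), ("verbal", verbal), ("motor", motor)):
        lo, hi = _GCS_RANGES[name]
        if not isinstance(value, int) or not (lo <= value <= hi):
            raise GcsRangeError(
                f"GCS {name} component must be an integer in [{lo}, {hi}], got {value!r}"
            )
    return eye + verbal + motor


@dataclass(frozen=True)
class Violation:
    """One invariant violation on a record; data, not an exception."""

    field: str
    message: str
    severity: str = "error"  # "error" | "warning"


def validate_case_facts(facts: CaseFacts) -> list[Violation]:
    """Check CaseFacts invariants; an empty list means the record is coherent.

    GCS total/component consistency is checked only when both sides are known
    (narratives often state only the total).
    """
    out: list[Violation] = []
    for name, (lo, hi) in (("gcs_eye", (1, 4)), ("gcs_verbal", (1, 5)),
                           ("gcs_motor", (1, 6)), ("gcs_total", (3, 15))):
        v = getattr(facts, name)
        if v is not None and not (lo <= v <= hi):
            out.append(Violation(name, f"{name}={v} outside legal range [{lo}, {hi}]"))
    comps = (facts.gcs_eye, facts.gcs_verbal, facts.gcs_motor)
    if facts.gcs_total is not None and all(c is not None for c in comps):
        s = sum(comps)  # type: ignore[arg-type]
        if s != facts.gcs_total:
            out.append(
                Violation(
                    "gcs_total",
                    f"gcs_total={facts.gcs_total} inconsistent with components summing to {s}",
                )
            )
    for name in ("hematoma_volume_ml", "midline_shift_mm"):
        v = getattr(facts, name)
        if v is not None and v < 0:
            out.append(Violation(name, f"{name}={v} must be non-negative"))
    return out


def validate_emr_record(record: EmrRecord) -> list[Violation]:
    """Structural checks on a raw record; age bounds are a warning only."""
    out: list[Violation] = []
    if record.age is not None and not (10 <= record.age <= 80):
        out.append(
            Violation("age", f"age={record.age} outside inclusion range 10-80", "warning")
        )
    for name in ("chief_complaint", "history", "physical_exam", "ct_report"):
        if not getattr(record, name).strip():
            out.append(Violation(name, f"narrative section {name} is empty", "warning"))
    return out


# --- JSON Lines helpers -----------------------------------------------------

def write_jsonl(path, rows: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_emr_corpus(path, records: Iterable[EmrRecord]) -> None:
    write_jsonl(path, (r.to_json_dict() for r in records))


def read_emr_corpus(path) -> list[EmrRecord]:
    return [EmrRecord.model_validate(d) for d in read_jsonl(path)]


def write_case_facts(path, rows: Iterable[tuple[str, CaseFacts]]) -> None:
    write_jsonl(
        path, ({"record_id": rid, **facts.to_json_dict()} for rid, facts in rows)
    )


def read_case_facts(path) -> list[tuple[str, CaseFacts]]:
    out = []
    for d in read_jsonl(path):
        rid = d.pop("record_id")
        out.append((rid, CaseFacts.model_validate(d)))
    return out
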