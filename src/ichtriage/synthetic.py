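"""Synthetic ICH cohort generator.

Emulates an emergency-record corpus with known ground truth: clinically
coherent :class:`CaseFacts` are drawn from configurable priors, a *gold*
logic table plays the role of the senior neurosurgeons who would label each
case, and narrative sections are rendered from sentence templates with
controllable corruption (misspellings, symbol runs, abbreviations, dropped
fields, unit variants).  With all noise rates at zero the rendering is
canonical and fully invertible by the default lexicon — the end-to-end oracle
every pipeline test leans on.

Noise streams are *decision-coupled*: each candidate corruption site always
consumes the same random draws whether or not it triggers, so under a shared
seed the set of corrupted sites at rate r is a subset of the set at any
r' > r.  Corruption only removes recoverable information, so pipeline
accuracy is non-increasing in each rate under paired seeds by construction.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .case_model import (
    BleedLocation,
    CaseFacts,
    Consciousness,
    EmrRecord,
    Laterality,
    PupilState,
    Sex,
    Symptom,
    TreatmentPlan,
    TriState,
    Trend,
    validate_case_facts,
    write_jsonl,
)
from .expert import LogicTable, classify_plan
from .text_extraction import Lexicon

SPLITS = ("train", "validation", "test")


class GenerationError(RuntimeError):
    """Rejection sampling could not achieve the requested plan mix."""


class NoiseModel(BaseModel):
    """Per-corruption probabilities; all rates in [0, 1].

    ``misspelling_rate`` applies per keyword token; a fraction
    ``unlisted_fraction`` of triggered misspellings are random character
    corruptions outside the lexicon's correction table (real typos are not
    all enumerable), the rest are table-listed variants the preprocessor can
    undo.
    """

    model_config = ConfigDict(frozen=True)

    misspelling_rate: float = Field(0.05, ge=0.0, le=1.0)
    symbol_noise_rate: float = Field(0.15, ge=0.0, le=1.0)
    abbreviation_rate: float = Field(0.25, ge=0.0, le=1.0)
    field_dropout_rate: float = Field(0.03, ge=0.0, le=1.0)
    unit_variant_rate: float = Field(0.15, ge=0.0, le=1.0)
    unlisted_fraction: float = Field(0.35, ge=0.0, le=1.0)

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(
            misspelling_rate=0.0,
            symbol_noise_rate=0.0,
            abbreviation_rate=0.0,
            field_dropout_rate=0.0,
            unit_variant_rate=0.0,
        )


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_cases: int = Field(..., ge=1)
    seed: int = 0
    plan_mix: Optional[dict[TreatmentPlan, float]] = None
    noise: NoiseModel = NoiseModel.none()
    split_ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)

    @model_validator(mode="after")
    def _check_proportions(self) -> "CohortSpec":
        if self.plan_mix is not None:
            total = sum(self.plan_mix.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.plan_mix.values()):
                raise ValueError("plan_mix proportions must be non-negative and sum to 1")
        if any(r < 0 for r in self.split_ratio) or abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must be non-negative and sum to 1")
        return self


#: Two-way preset matching a 700/300 train/validation design.
SPLIT_TRAIN_VALIDATION = (0.7, 0.3, 0.0)
#: Three-way 6:2:2 preset.
SPLIT_622 = (0.6, 0.2, 0.2)


# --- clinical priors --------------------------------------------------------

@dataclass(frozen=True)
class ClinicalPriors:
    """Literature-typical defaults; configurable, deliberately not tied to
    any single published cohort."""

    location_probs: tuple[tuple[BleedLocation, float], ...] = (
        (BleedLocation.basal_ganglia, 0.50),
        (BleedLocation.thalamus, 0.15),
        (BleedLocation.lobar, 0.20),
        (BleedLocation.cerebellum, 0.08),
        (BleedLocation.brainstem, 0.05),
        (BleedLocation.intraventricular_primary, 0.02),
    )
    #: per-location log-normal volume parameters (mu, sigma) on the mL scale
    volume_params: tuple[tuple[BleedLocation, float, float], ...] = (
        (BleedLocation.basal_ganglia, math.log(18.0), 0.70),
        (BleedLocation.thalamus, math.log(12.0), 0.65),
        (BleedLocation.lobar, math.log(25.0), 0.75),
        (BleedLocation.cerebellum, math.log(9.0), 0.60),
        (BleedLocation.brainstem, math.log(4.0), 0.60),
        (BleedLocation.intraventricular_primary, math.log(8.0), 0.60),
    )
    #: categorical prior over GCS totals 3..15 (weights, not yet normalised)
    gcs_total_weights: tuple[float, ...] = (2, 2, 3, 3, 4, 5, 6, 7, 8, 9, 12, 16, 23)

    def gcs_prior_mean(self) -> float:
        w = np.asarray(self.gcs_total_weights, dtype=float)
        totals = np.arange(3, 16)
        return float((w / w.sum()) @ totals)

    def gcs_prior_var(self) -> float:
        w = np.asarray(self.gcs_total_weights, dtype=float)
        p = w / w.sum()
        totals = np.arange(3, 16)
        m = p @ totals
        return float(p @ (totals - m) ** 2)


DEFAULT_PRIORS = ClinicalPriors()

_GCS_DECOMP: dict[int, list[tuple[int, int, int]]] = {
    t: [
        (e, v, m)
        for e, v, m in itertools.product(range(1, 5), range(1, 6), range(1, 7))
        if e + v + m == t
    ]
    for t in range(3, 16)
}


def _grade_for_total(total: int) -> Consciousness:
    if total >= 13:
        return Consciousness.alert
    if total >= 9:
        return Consciousness.drowsy
    if total >= 6:
        return Consciousness.stupor
    return Consciousness.coma


@dataclass(frozen=True)
class Demographics:
    age: int
    sex: Sex
    weight_kg: float
    height_cm: float


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(64):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return x
    return float(min(max(mu, lo), hi))


def sample_demographics(rng: np.random.Generator) -> Demographics:
    age = int(round(_truncated_normal(rng, 65, 15, 10, 80)))
    sex = Sex.female if rng.random() < 0.55 else Sex.male
    weight = round(_truncated_normal(rng, 62, 12, 35, 120), 1)
    height = round(_truncated_normal(rng, 160, 15, 120, 200), 0)
    return Demographics(age, sex, weight, height)


def sample_case_facts(
    rng: np.random.Generator, priors: ClinicalPriors = DEFAULT_PRIORS
) -> CaseFacts:
    """Draw one clinically coherent CaseFacts vector.

    Location comes from a categorical prior; volume from a
    location-conditional log-normal; GCS components are drawn jointly and the
    consciousness grade follows the total (alert 13-15, drowsy 9-12, stupor
    6-8, coma 3-5); midline shift is positively coupled to volume for
    supratentorial bleeds.  Every draw passes ``validate_case_facts``.
    """
    locs, probs = zip(*priors.location_probs)
    loc = locs[rng.choice(len(locs), p=np.asarray(probs) / sum(probs))]

    vol_mu, vol_sd = next((m, s) for l, m, s in priors.volume_params if l is loc)
    volume = float(np.clip(rng.lognormal(vol_mu, vol_sd), 0.5, 150.0))
    volume = round(volume, 1)

    w = np.asarray(priors.gcs_total_weights, dtype=float)
    total = int(rng.choice(np.arange(3, 16), p=w / w.sum()))
    eye, verbal, motor = _GCS_DECOMP[total][rng.integers(len(_GCS_DECOMP[total]))]
    grade = _grade_for_total(total)

    supra = loc in (BleedLocation.basal_ganglia, BleedLocation.thalamus, BleedLocation.lobar)
    if supra:
        shift = max(0.0, rng.normal(0.25 * max(0.0, volume - 12.0), 1.2))
        shift = 0.0 if shift < 1.0 else round(shift, 1)
    elif loc is BleedLocation.cerebellum and rng.random() < 0.12:
        shift = round(float(rng.uniform(2, 5)), 1)
    else:
        shift = 0.0

    cast_p = {
        BleedLocation.basal_ganglia: 0.15,
        BleedLocation.thalamus: 0.35,
        BleedLocation.lobar: 0.08,
        BleedLocation.cerebellum: 0.15,
        BleedLocation.brainstem: 0.10,
        BleedLocation.intraventricular_primary: 0.90,
    }[loc]
    cast = TriState.present if rng.random() < cast_p else TriState.absent
    shape_p = 0.7 if (cast is TriState.present or shift >= 5) else 0.1
    shape = TriState.present if rng.random() < shape_p else TriState.absent

    if grade is Consciousness.coma:
        pupil_probs = (0.30, 0.45, 0.25)
    elif grade is Consciousness.stupor:
        pupil_probs = (0.60, 0.35, 0.05)
    elif grade is Consciousness.drowsy:
        pupil_probs = (0.85, 0.15, 0.0)
    else:
        pupil_probs = (0.97, 0.03, 0.0)
    pupil = (
        PupilState.equal_reactive,
        PupilState.anisocoria,
        PupilState.bilateral_fixed_dilated,
    )[rng.choice(3, p=pupil_probs)]

    reflex_p = 0.8 if total <= 8 else (0.45 if total <= 12 else 0.15)
    reflex = TriState.present if rng.random() < reflex_p else TriState.absent

    symptoms = frozenset(
        s for s, p in ((Symptom.headache, 0.70), (Symptom.nausea, 0.50),
                       (Symptom.vomiting, 0.40))
        if rng.random() < p
    )

    det_p = 0.55 if total <= 8 else (0.30 if total <= 12 else 0.12)
    trend = Trend.deteriorating if rng.random() < det_p else Trend.stable

    if supra or loc is BleedLocation.cerebellum:
        laterality = (Laterality.left, Laterality.right, Laterality.bilateral)[
            rng.choice(3, p=(0.46, 0.46, 0.08))
        ]
    else:
        laterality = Laterality.midline

    facts = CaseFacts(
        gcs_eye=eye,
        gcs_verbal=verbal,
        gcs_motor=motor,
        gcs_total=total,
        heart_rate=float(int(round(_truncated_normal(rng, 86, 15, 40, 140)))),
        systolic_bp=float(int(round(_truncated_normal(rng, 165, 25, 90, 230)))),
        diastolic_bp=float(int(round(_truncated_normal(rng, 95, 15, 50, 130)))),
        spo2=float(int(round(_truncated_normal(rng, 96, 2, 70, 100)))),
        consciousness_grade=grade,
        pathological_reflex=reflex,
        pupil_state=pupil,
        symptoms=symptoms,
        bleed_location=loc,
        laterality=laterality,
        hematoma_volume_ml=volume,
        ventricle_cast=cast,
        ventricle_shape_abnormal=shape,
        midline_shift_mm=shift,
        condition_trend=trend,
    )
    assert validate_case_facts(facts) == []
    return facts


def derive_gold_plan(facts: CaseFacts, gold_table: LogicTable) -> TreatmentPlan:
    """Gold-standard plan: the reference table evaluated on the *true* facts
    (before any rendering), playing the senior-rater role."""
    return classify_plan(facts, gold_table).plan


# --- templates and rendering ------------------------------------------------

class Templates:
    def __init__(self, doc: dict):
        self.doc = doc

    @classmethod
    def from_yaml(cls, path) -> "Templates":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Templates":
        text = resources.files("ichtriage.data").joinpath("templates.yaml").read_text("utf-8")
        return cls(yaml.safe_load(text))


def _fmt(x: float) -> str:
    return f"{x:g}"


#: sentence keys -> CaseFacts fields they carry (used by the round-trip oracle)
_GROUP_FIELDS = {
    "symptoms": ("symptoms",),
    "trend": ("condition_trend",),
    "gcs": ("gcs_total", "gcs_eye", "gcs_verbal", "gcs_motor"),
    "consciousness": ("consciousness_grade",),
    "pupils": ("pupil_state",),
    "reflex": ("pathological_reflex",),
    "heart_rate": ("heart_rate",),
    "blood_pressure": ("systolic_bp", "diastolic_bp"),
    "spo2": ("spo2",),
    "bleeding": ("bleed_location", "hematoma_volume_ml", "laterality"),
    "cast": ("ventricle_cast",),
    "shape": ("ventricle_shape_abnormal",),
    "shift": ("midline_shift_mm",),
}


def recoverable_fields(facts: CaseFacts) -> set[str]:
    """Fields a noiseless rendering of ``facts`` encodes recoverably.

    ``laterality`` is implicit (not worded) for midline locations; unknown
    fields render nothing; ``symptoms`` is always comparable because an empty
    set renders no sentence and extracts back to an empty set.
    """
    out: set[str] = {"symptoms"}
    for key, fields in _GROUP_FIELDS.items():
        if key == "symptoms":
            continue
        for f in fields:
            if getattr(facts, f) is None:
                continue
            if f == "laterality" and facts.laterality is Laterality.midline:
                continue
            if f in ("gcs_eye", "gcs_verbal", "gcs_motor") and not all(
                getattr(facts, g) is not None
                for g in ("gcs_eye", "gcs_verbal", "gcs_motor")
            ):
                continue
            out.add(f)
    return out


def _case_sentences(
    facts: CaseFacts,
    demo: Demographics,
    tpl: dict,
    units_rng: np.random.Generator,
    unit_variant_rate: float,
) -> dict[str, list[tuple[Optional[str], str]]]:
    """Per-section list of (dropout-group key, sentence); key None = filler,
    never dropped."""
    # unit draws happen unconditionally so streams align across noise rates
    u_vol, u_shift = units_rng.random(), units_rng.random()
    vol_unit = "cc" if u_vol < unit_variant_rate else "ml"
    shift_cm = u_shift < unit_variant_rate

    cc: list[tuple[Optional[str], str]] = [
        (None, tpl["chief_complaint"]["opener"].format(
            age=demo.age, sex=demo.sex.value))
    ]
    if facts.symptoms:
        names = sorted(s.value for s in facts.symptoms)
        listing = names[0] if len(names) == 1 else ", ".join(names[:-1]) + " and " + names[-1]
        cc.append(("symptoms", tpl["chief_complaint"]["symptoms"].format(symptoms=listing)))

    hist: list[tuple[Optional[str], str]] = [(None, tpl["history"]["filler"])]
    if facts.condition_trend is not None:
        hist.append(("trend", tpl["history"]["trend"][facts.condition_trend.value]))

    pe: list[tuple[Optional[str], str]] = []
    t = tpl["physical_exam"]
    if facts.gcs_total is not None:
        if all(x is not None for x in (facts.gcs_eye, facts.gcs_verbal, facts.gcs_motor)):
            pe.append(("gcs", t["gcs_full"].format(
                total=facts.gcs_total, e=facts.gcs_eye, v=facts.gcs_verbal,
                m=facts.gcs_motor)))
        else:
            pe.append(("gcs", t["gcs_total_only"].format(total=facts.gcs_total)))
    if facts.consciousness_grade is not None:
        pe.append(("consciousness", t["consciousness"][facts.consciousness_grade.value]))
    if facts.pupil_state is not None:
        pe.append(("pupils", t["pupils"][facts.pupil_state.value]))
    if facts.pathological_reflex is not None:
        pe.append(("reflex", t["reflex"][facts.pathological_reflex.value]))
    if facts.heart_rate is not None:
        pe.append(("heart_rate", t["heart_rate"].format(hr=_fmt(facts.heart_rate))))
    if facts.systolic_bp is not None and facts.diastolic_bp is not None:
        pe.append(("blood_pressure", t["blood_pressure"].format(
            sbp=_fmt(facts.systolic_bp), dbp=_fmt(facts.diastolic_bp))))
    if facts.spo2 is not None:
        pe.append(("spo2", t["spo2"].format(spo2=_fmt(facts.spo2))))

    ct: list[tuple[Optional[str], str]] = []
    c = tpl["ct_report"]
    if facts.bleed_location is not None and facts.hematoma_volume_ml is not None:
        site = c["location_surface"][facts.bleed_location.value]
        if facts.laterality is not None and facts.laterality is not Laterality.midline:
            site = f"{facts.laterality.value} {site}"
        ct.append(("bleeding", c["bleeding"].format(
            vol=_fmt(facts.hematoma_volume_ml), vol_unit=vol_unit, site=site)))
    if facts.ventricle_cast is not None:
        ct.append(("cast", c["cast"][facts.ventricle_cast.value]))
    if facts.ventricle_shape_abnormal is not None:
        ct.append(("shape", c["shape"][facts.ventricle_shape_abnormal.value]))
    if facts.midline_shift_mm is not None:
        if facts.midline_shift_mm == 0:
            ct.append(("shift", c["no_shift"]))
        elif shift_cm:
            ct.append(("shift", c["shift"].format(
                mm=_fmt(facts.midline_shift_mm / 10.0), unit="cm")))
        else:
            ct.append(("shift", c["shift"].format(
                mm=_fmt(facts.midline_shift_mm), unit="mm")))

    return {"chief_complaint": cc, "history": hist, "physical_exam": pe, "ct_report": ct}


_SYMBOL_RUNS = ("***", "##", "~~", "@@", "^^^")
_CORRUPTIBLE_MIN_LEN = 4


def _corrupt_token(tok: str, r: float) -> str:
    """Out-of-table typo: delete, swap, or double one character."""
    i = int(r * (len(tok) - 1)) % (len(tok) - 1)
    op = int(r * 997) % 3
    if op == 0:
        return tok[:i] + tok[i + 1:]
    if op == 1:
        return tok[:i] + tok[i + 1] + tok[i] + tok[i + 2:]
    return tok[:i] + tok[i] + tok[i:]


def _apply_misspellings(
    text: str,
    rng: np.random.Generator,
    rate: float,
    unlisted_fraction: float,
    variants: dict[str, list[str]],
) -> str:
    out, pos = [], 0
    for m in re.finditer(r"[a-z]+", text):
        out.append(text[pos:m.start()])
        tok = m.group()
        pos = m.end()
        if tok in variants and len(tok) >= _CORRUPTIBLE_MIN_LEN:
            # three draws always consumed: trigger, listed-vs-unlisted, pick
            u, v, w = rng.random(), rng.random(), rng.random()
            if u < rate:
                if v < unlisted_fraction:
                    tok = _corrupt_token(tok, w)
                else:
                    opts = variants[tok]
                    tok = opts[int(w * len(opts)) % len(opts)]
        out.append(tok)
    out.append(text[pos:])
    return "".join(out)


def _apply_abbreviations(
    text: str, rng: np.random.Generator, rate: float, abbrev: dict[str, str]
) -> str:
    # expansion -> abbreviation, longest expansions first for stable behaviour
    for expansion, short in sorted(
        ((v, k) for k, v in abbrev.items()), key=lambda t: -len(t[0])
    ):
        pieces = text.split(expansion)
        if len(pieces) == 1:
            continue
        rebuilt = pieces[0]
        for piece in pieces[1:]:
            u = rng.random()
            rebuilt += (short if u < rate else expansion) + piece
        text = rebuilt
    return text


def _apply_symbols(
    sentences: list[str], rng: np.random.Generator, rate: float
) -> list[str]:
    out = []
    for s in sentences:
        u, v = rng.random(), rng.random()
        if u < rate:
            s = s + " " + _SYMBOL_RUNS[int(v * len(_SYMBOL_RUNS)) % len(_SYMBOL_RUNS)]
        out.append(s)
    return out


def render_narrative(
    facts: CaseFacts,
    templates: Optional[Templates] = None,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[NoiseModel] = None,
    record_id: str = "case-00000",
    demographics: Optional[Demographics] = None,
    lexicon: Optional[Lexicon] = None,
) -> EmrRecord:
    """Render one CaseFacts into an EmrRecord, applying the noise model."""
    templates = templates or Templates.default()
    rng = rng if rng is not None else np.random.default_rng(0)
    noise = noise or NoiseModel.none()
    lexicon = lexicon or Lexicon.default()
    rng_drop, rng_units, rng_abbrev, rng_missp, rng_sym, rng_demo = rng.spawn(6)
    if demographics is None:
        demographics = sample_demographics(rng_demo)

    per_section = _case_sentences(
        facts, demographics, templates.doc, rng_units, noise.unit_variant_rate
    )

    inv_missp: dict[str, list[str]] = {}
    for variant, canonical in lexicon.misspellings.items():
        inv_missp.setdefault(canonical, []).append(variant)
    for opts in inv_missp.values():
        opts.sort()
    inv_abbrev = dict(lexicon.abbreviations)

    sections: dict[str, str] = {}
    for section, sentences in per_section.items():
        kept = []
        for key, sentence in sentences:
            u = rng_drop.random()  # drawn unconditionally: nested dropout sets
            if key is not None and u < noise.field_dropout_rate:
                continue
            kept.append(sentence)
        if not kept:
            filler = templates.doc.get(section, {}).get("filler")
            kept = [filler] if filler else []
        text = " ".join(kept)
        text = _apply_abbreviations(text, rng_abbrev, noise.abbreviation_rate, inv_abbrev)
        text = _apply_misspellings(
            text, rng_missp, noise.misspelling_rate, noise.unlisted_fraction, inv_missp
        )
        parts = text.split(". ")
        sentences = [p + "." for p in parts[:-1]] + parts[-1:]
        text = " ".join(_apply_symbols(sentences, rng_sym, noise.symbol_noise_rate))
        sections[section] = text

    return EmrRecord(
        record_id=record_id,
        age=demographics.age,
        sex=demographics.sex,
        weight_kg=demographics.weight_kg,
        height_cm=demographics.height_cm,
        **sections,
    )


# --- cohort assembly --------------------------------------------------------

@dataclass
class CohortCase:
    record: EmrRecord
    true_facts: CaseFacts
    gold_plan: TreatmentPlan
    split: str


@dataclass
class Cohort:
    spec: CohortSpec
    cases: list[CohortCase]

    @property
    def split_sizes(self) -> dict[str, int]:
        out = {s: 0 for s in SPLITS}
        for c in self.cases:
            out[c.split] += 1
        return out

    def plan_counts(self) -> dict[TreatmentPlan, int]:
        out = {p: 0 for p in TreatmentPlan}
        for c in self.cases:
            out[c.gold_plan] += 1
        return out

    def write_corpus(self, path) -> None:
        write_jsonl(path, (c.record.to_json_dict() for c in self.cases))

    def write_gold(self, path) -> None:
        write_jsonl(
            path,
            (
                {
                    "record_id": c.record.record_id,
                    "gold_plan": c.gold_plan.value,
                    "true_facts": c.true_facts.to_json_dict(),
                }
                for c in self.cases
            ),
        )

    def write_splits(self, path) -> None:
        write_jsonl(
            path,
            ({"record_id": c.record.record_id, "split": c.split} for c in self.cases),
        )


def largest_remainder_split(n: int, ratios: Sequence[float]) -> list[int]:
    """Partition n into len(ratios) integers by largest-remainder rounding."""
    exact = [n * r for r in ratios]
    floors = [int(math.floor(x)) for x in exact]
    short = n - sum(floors)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def _case_rng(seed: int, draw: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), draw, stream]))


def generate_cohort(
    spec: CohortSpec,
    gold_table: Optional[LogicTable] = None,
    templates: Optional[Templates] = None,
    priors: ClinicalPriors = DEFAULT_PRIORS,
    lexicon: Optional[Lexicon] = None,
) -> Cohort:
    """Generate a corpus of exactly ``spec.n_cases`` records with gold plans.

    Plan mix, when requested, is achieved by rejection sampling against the
    gold table (bounded at 1000 x n draws).  Fully determined by
    ``spec.seed``; the underlying facts for a given seed are identical across
    noise settings, so cohorts at different noise levels are paired.
    """
    gold_table = gold_table or LogicTable.default()
    templates = templates or Templates.default()
    lexicon = lexicon or Lexicon.default()
    n = spec.n_cases

    targets: Optional[dict[TreatmentPlan, int]] = None
    if spec.plan_mix is not None:
        plans = list(TreatmentPlan)
        sizes = largest_remainder_split(n, [spec.plan_mix.get(p, 0.0) for p in plans])
        targets = dict(zip(plans, sizes))

    counts = {p: 0 for p in TreatmentPlan}
    cases: list[CohortCase] = []
    max_draws = 1000 * n
    draw = 0
    while len(cases) < n:
        if draw >= max_draws:
            raise GenerationError(
                f"plan mix {spec.plan_mix} infeasible: {len(cases)}/{n} cases "
                f"after {max_draws} draws (achieved counts {counts})"
            )
        facts_rng = _case_rng(spec.seed, draw, 0)
        facts = sample_case_facts(facts_rng, priors)
        demo = sample_demographics(facts_rng)
        plan = derive_gold_plan(facts, gold_table)
        draw += 1
        if targets is not None and counts[plan] >= targets[plan]:
            continue
        record = render_narrative(
            facts,
            templates,
            _case_rng(spec.seed, draw - 1, 1),
            spec.noise,
            record_id=f"case-{len(cases):05d}",
            demographics=demo,
            lexicon=lexicon,
        )
        counts[plan] += 1
        cases.append(CohortCase(record, facts, plan, split="train"))

    sizes = largest_remainder_split(n, spec.split_ratio)
    perm = _case_rng(spec.seed, 0, 2).permutation(n)
    bounds = np.cumsum(sizes)
    for pos, case_idx in enumerate(perm):
        split = SPLITS[int(np.searchsorted(bounds, pos, side="right"))]
        cases[case_idx].split = split
    return Cohort(spec=spec, cases=cases)
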