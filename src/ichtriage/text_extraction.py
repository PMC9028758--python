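"""Narrative text -> entity mentions -> assembled CaseFacts.

The reference tagger is a dictionary + regex matcher over a configurable
lexicon; it stands behind a pluggable contract (record in, mentions out), so a
learned sequence tagger can be substituted without touching the rest of the
pipeline.  Preprocessing lowercases, strips non-text symbol runs, corrects
table-listed misspellings and expands abbreviations, keeping a character-level
offset map back to the raw section text.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

import yaml

from .case_model import CaseFacts, EmrRecord

SECTIONS = ("chief_complaint", "history", "physical_exam", "ct_report")
_SECTION_RANK = {name: i for i, name in enumerate(SECTIONS)}

#: Characters retained verbatim by preprocessing; anything else (control
#: characters, decorative punctuation) becomes a single space.
_ALLOWED = frozenset(string.ascii_lowercase + string.digits + " .,;:%/()'-")

_NEGATION_CUES = frozenset({"no", "not", "without", "denies", "denied", "absent"})

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:/[a-z0-9]+)?")


class LexiconError(ValueError):
    """A lexicon entry failed to load or compile."""


@dataclass(frozen=True)
class PatternSpec:
    regex: re.Pattern
    fixed_value: Optional[object] = None


@dataclass(frozen=True)
class LexiconEntry:
    label: str
    target: str
    patterns: tuple[PatternSpec, ...]
    normalizer: Optional[str] = None  # int | float | volume_ml | length_mm
    negatable: bool = False
    negated_value: Optional[str] = None


@dataclass
class Lexicon:
    entries: tuple[LexiconEntry, ...]
    abbreviations: dict[str, str]
    misspellings: dict[str, str]

    @classmethod
    def from_dict(cls, doc: dict) -> "Lexicon":
        valid_fields = set(CaseFacts.model_fields)
        entries = []
        for raw in doc.get("entries", []):
            label = raw.get("label", "<unnamed>")
            target = raw.get("target")
            if target not in valid_fields:
                raise LexiconError(
                    f"lexicon entry {label!r}: target field {target!r} not in CaseFacts"
                )
            pats = []
            for p in raw.get("patterns", []):
                pat, value = (p["re"], p.get("value")) if isinstance(p, dict) else (p, None)
                try:
                    rx = re.compile(pat)
                except re.error as exc:
                    raise LexiconError(
                        f"lexicon entry {label!r}: pattern {pat!r} does not compile: {exc}"
                    ) from exc
                if value is None and "value" not in rx.groupindex:
                    raise LexiconError(
                        f"lexicon entry {label!r}: pattern {pat!r} has neither a fixed "
                        "value nor a named 'value' capture group"
                    )
                pats.append(PatternSpec(rx, value))
            if not pats:
                raise LexiconError(f"lexicon entry {label!r}: no patterns")
            entries.append(
                LexiconEntry(
                    label=label,
                    target=target,
                    patterns=tuple(pats),
                    normalizer=raw.get("normalizer"),
                    negatable=bool(raw.get("negatable", False)),
                    negated_value=raw.get("negated_value"),
                )
            )
        return cls(
            entries=tuple(entries),
            abbreviations=dict(doc.get("abbreviations", {})),
            misspellings=dict(doc.get("misspellings", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Lexicon":
        text = resources.files("ichtriage.data").joinpath("lexicon.yaml").read_text("utf-8")
        return cls.from_dict(yaml.safe_load(text))

    def target_of(self, label: str) -> str:
        for e in self.entries:
            if e.label == label:
                return e.target
        raise KeyError(label)


@dataclass(frozen=True)
class EntityMention:
    """One recognised span; offsets index the *preprocessed* section text."""

    label: str
    section: str
    start: int
    end: int
    raw_text: str
    normalized_value: object
    target: str
    negated: bool = False

    def to_json_dict(self, record_id: str) -> dict:
        value = self.normalized_value
        if not isinstance(value, (int, float, str, type(None))):
            value = str(value)
        return {
            "record_id": record_id,
            "label": self.label,
            "section": self.section,
            "start": self.start,
            "end": self.end,
            "raw_text": self.raw_text,
            "normalized_value": value,
            "negated": self.negated,
        }


@dataclass
class PreprocessedText:
    text: str
    #: to_original[i] = index into the raw section text for output character i
    to_original: list[int]

    def original_span(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span in the preprocessed text to raw-text offsets."""
        if start >= end or not self.to_original:
            return (0, 0)
        return (self.to_original[start], self.to_original[end - 1] + 1)


def preprocess_text(section_text: str, lexicon: Lexicon) -> PreprocessedText:
    """Lowercase, strip symbol runs, fix listed misspellings, expand
    abbreviations; returns the cleaned text plus an output->raw offset map."""
    # pass 1: lowercase + replace disallowed characters by spaces
    buf: list[str] = []
    idx: list[int] = []
    for i, ch in enumerate(section_text):
        lo = ch.lower()
        if len(lo) != 1:
            lo = ch
        buf.append(lo if lo in _ALLOWED else " ")
        idx.append(i)
    # pass 2: collapse whitespace runs, strip ends
    mid: list[str] = []
    mom: list[int] = []
    prev_space = True
    for ch, i in zip(buf, idx):
        if ch == " ":
            if prev_space:
                continue
            prev_space = True
        else:
            prev_space = False
        mid.append(ch)
        mom.append(i)
    while mid and mid[-1] == " ":
        mid.pop()
        mom.pop()
    text = "".join(mid)
    # pass 3: token-level misspelling correction then abbreviation expansion
    out: list[str] = []
    oom: list[int] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        s, e = m.span()
        out.append(text[pos:s])
        oom.extend(mom[pos:s])
        tok = m.group()
        repl = lexicon.misspellings.get(tok, tok)
        repl = lexicon.abbreviations.get(repl, repl)
        if repl == tok:
            out.append(tok)
            oom.extend(mom[s:e])
        else:
            out.append(repl)
            # every replacement character points into the original token span
            oom.extend(mom[s + min(j, e - s - 1)] for j in range(len(repl)))
        pos = e
    out.append(text[pos:])
    oom.extend(mom[pos:])
    return PreprocessedText("".join(out), oom)


def _clause_spans(text: str) -> list[tuple[int, int]]:
    spans, start = [], 0
    for i, ch in enumerate(text):
        if ch in ".,;":
            spans.append((start, i))
            start = i + 1
    spans.append((start, len(text)))
    return spans


def _negated_spans(text: str) -> list[tuple[int, int]]:
    out = []
    for s, e in _clause_spans(text):
        tokens = set(re.findall(r"[a-z]+", text[s:e]))
        if tokens & _NEGATION_CUES:
            out.append((s, e))
    return out


def _normalize(entry: LexiconEntry, spec: PatternSpec, m: re.Match) -> object:
    if spec.fixed_value is not None:
        return spec.fixed_value
    raw = m.group("value")
    if entry.normalizer == "int":
        return int(raw)
    if entry.normalizer == "float":
        return float(raw)
    if entry.normalizer == "volume_ml":
        return float(raw)  # ml and cc are the same scale
    if entry.normalizer == "length_mm":
        v = float(raw)
        unit = (m.groupdict().get("unit") or "mm").strip()
        return round(v * 10, 6) if unit == "cm" else v
    raise LexiconError(
        f"lexicon entry {entry.label!r}: unknown normalizer {entry.normalizer!r}"
    )


def extract_entities(record: EmrRecord, lexicon: Lexicon) -> list[EntityMention]:
    """Run the dictionary tagger over every section of a record.

    Per label, occurrences are kept scanning left to right, longest match
    first, with no overlaps; attribute captures populate the normalised value;
    negation cues in the same clause flip negatable findings.
    """
    mentions: list[EntityMention] = []
    for section in SECTIONS:
        pp = preprocess_text(getattr(record, section), lexicon)
        if not pp.text:
            continue
        neg = _negated_spans(pp.text)
        for entry in lexicon.entries:
            cands: list[tuple[int, int, PatternSpec, re.Match]] = []
            for spec in entry.patterns:
                for m in spec.regex.finditer(pp.text):
                    if m.start() < m.end():
                        cands.append((m.start(), m.end(), spec, m))
            cands.sort(key=lambda t: (t[0], -(t[1] - t[0])))
            taken: list[tuple[int, int]] = []
            for s, e, spec, m in cands:
                if any(s < te and ts < e for ts, te in taken):
                    continue
                taken.append((s, e))
                value = _normalize(entry, spec, m)
                negated = False
                if entry.negatable and any(cs <= s < ce for cs, ce in neg):
                    negated = True
                    if entry.negated_value is not None:
                        value = entry.negated_value
                mentions.append(
                    EntityMention(
                        label=entry.label,
                        section=section,
                        start=s,
                        end=e,
                        raw_text=pp.text[s:e],
                        normalized_value=value,
                        target=entry.target,
                        negated=negated,
                    )
                )
    mentions.sort(key=lambda m: (_SECTION_RANK[m.section], m.start, m.label))
    return mentions


@dataclass(frozen=True)
class ConflictNote:
    field: str
    values: tuple
    chosen: object
    message: str


def assemble_case_facts(
    mentions: list[EntityMention], record: EmrRecord
) -> tuple[CaseFacts, list[ConflictNote]]:
    """Collapse mentions into one CaseFacts.

    Conflicting values for a field resolve by section precedence
    ct_report > physical_exam > history > chief_complaint, then by later
    offset; every conflict is recorded.  Fields with no mention stay unknown.
    """
    by_field: dict[str, list[EntityMention]] = {}
    symptoms: set[str] = set()
    for m in mentions:
        if m.target == "symptoms":
            if not m.negated:
                symptoms.add(str(m.normalized_value))
            continue
        by_field.setdefault(m.target, []).append(m)

    values: dict[str, object] = {"symptoms": sorted(symptoms)}
    notes: list[ConflictNote] = []
    for fname, ms in by_field.items():
        best = max(ms, key=lambda m: (_SECTION_RANK[m.section], m.start))
        distinct = []
        for m in ms:
            if m.normalized_value not in distinct:
                distinct.append(m.normalized_value)
        if len(distinct) > 1:
            notes.append(
                ConflictNote(
                    field=fname,
                    values=tuple(distinct),
                    chosen=best.normalized_value,
                    message=(
                        f"{record.record_id}: field {fname!r} has conflicting values "
                        f"{distinct}; kept {best.normalized_value!r} from {best.section}"
                    ),
                )
            )
        values[fname] = best.normalized_value
    return CaseFacts.model_validate(values), notes


#: Pluggable tagger contract: anything (record, lexicon) -> mentions.
Tagger = Callable[[EmrRecord, Lexicon], list[EntityMention]]


def extract_record(
    record: EmrRecord, lexicon: Lexicon, tagger: Tagger = extract_entities
) -> tuple[CaseFacts, list[EntityMention], list[ConflictNote]]:
    """One-call convenience: tag a record and assemble its facts."""
    mentions = tagger(record, lexicon)
    facts, notes = assemble_case_facts(mentions, record)
    return facts, mentions, notes
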