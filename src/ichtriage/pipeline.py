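"""Reproducible end-to-end runs: generate -> extract -> decide -> evaluate.

Each stage reads and writes the documented JSON Lines / CSV dialects, so
stages compose through files alone and are individually re-runnable.  A run
is fully determined by its config (including the seed); the manifest records
the config hash, seed, versions, and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .case_model import (
    CaseFacts,
    EmrRecord,
    read_case_facts,
    read_emr_corpus,
    read_jsonl,
    write_case_facts,
    write_jsonl,
)
from .evaluation import MetricsReport, evaluate_run
from .expert import LogicTable, classify_plan
from .synthetic import Cohort, CohortSpec, NoiseModel, Templates, generate_cohort
from .text_extraction import Lexicon, extract_record

logger = logging.getLogger("ichtriage")


class ConfigError(ValueError):
    """Invalid or missing run configuration."""


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_cases: int = Field(200, ge=1)
    plan_mix: Optional[dict[str, float]] = None
    noise: NoiseModel = NoiseModel.none()
    split_ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    #: paths; None means the packaged default
    lexicon: Optional[str] = None
    logic_table: Optional[str] = None
    gold_table: Optional[str] = None
    templates: Optional[str] = None
    #: pre-existing corpus to analyse instead of generating one
    corpus: Optional[str] = None
    gold: Optional[str] = None
    eval_split: Optional[str] = None  # train | validation | test | None (all)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        try:
            cfg = cls.model_validate(doc)
        except Exception as exc:  # pydantic error carries the field path
            raise ConfigError(f"invalid config {path}: {exc}") from exc
        for name in ("lexicon", "logic_table", "gold_table", "templates",
                     "corpus", "gold"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: file not found: {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_lexicon(cfg: RunConfig) -> Lexicon:
    return Lexicon.from_yaml(cfg.lexicon) if cfg.lexicon else Lexicon.default()


def _load_table(path: Optional[str]) -> LogicTable:
    return LogicTable.from_yaml(path) if path else LogicTable.default()


def stage_generate(cfg: RunConfig, out_dir: Path) -> Cohort:
    spec = CohortSpec(
        n_cases=cfg.n_cases,
        seed=cfg.seed,
        plan_mix=cfg.plan_mix,
        noise=cfg.noise,
        split_ratio=cfg.split_ratio,
    )
    templates = Templates.from_yaml(cfg.templates) if cfg.templates else Templates.default()
    cohort = generate_cohort(
        spec, gold_table=_load_table(cfg.gold_table), templates=templates,
        lexicon=_load_lexicon(cfg),
    )
    cohort.write_corpus(out_dir / "corpus.jsonl")
    cohort.write_gold(out_dir / "gold.jsonl")
    cohort.write_splits(out_dir / "splits.jsonl")
    logger.info("generated %d cases (splits %s)", cfg.n_cases, cohort.split_sizes)
    return cohort


def stage_extract(
    records: list[EmrRecord], lexicon: Lexicon, out_dir: Optional[Path] = None
) -> list[tuple[str, CaseFacts]]:
    facts_rows: list[tuple[str, CaseFacts]] = []
    mention_rows: list[dict] = []
    n_conflicts = 0
    for record in records:
        facts, mentions, notes = extract_record(record, lexicon)
        facts_rows.append((record.record_id, facts))
        mention_rows.extend(m.to_json_dict(record.record_id) for m in mentions)
        for note in notes:
            n_conflicts += 1
            logger.info("extraction conflict: %s", note.message)
    if out_dir is not None:
        write_jsonl(out_dir / "mentions.jsonl", mention_rows)
        write_case_facts(out_dir / "facts.jsonl", facts_rows)
    logger.info("extracted %d records (%d conflicts)", len(records), n_conflicts)
    return facts_rows


def stage_decide(
    facts_rows: list[tuple[str, CaseFacts]],
    table: LogicTable,
    out_dir: Optional[Path] = None,
) -> list[dict]:
    rows = []
    for rid, facts in facts_rows:
        decision = classify_plan(facts, table)
        for w in decision.warnings:
            logger.warning("%s: %s", rid, w)
        rows.append(
            {
                "record_id": rid,
                "plan": decision.plan.value,
                "coarse_plan": decision.plan.coarse.value,
                "weighted_score": decision.weighted_score,
                "mandated": decision.mandated,
                "fired_rules": [
                    {"rule_id": r, "weight": w} for r, w in decision.fired_rules
                ],
            }
        )
    if out_dir is not None:
        write_jsonl(out_dir / "decisions.jsonl", rows)
    logger.info("decided %d records", len(rows))
    return rows


def stage_evaluate(
    decisions: list[dict],
    gold: list[dict],
    out_dir: Optional[Path] = None,
    rater2: Optional[list[dict]] = None,
) -> MetricsReport:
    report = evaluate_run(decisions, gold, rater2=rater2)
    if out_dir is not None:
        report.write_json(out_dir / "metrics.json")
        report.write_csv(out_dir / "metrics.csv")
        report.write_confusion_csv(out_dir / "confusion.csv")
    return report


def run_pipeline(cfg: RunConfig, out_dir) -> MetricsReport:
    """Execute the full pipeline into ``out_dir`` and return the report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lexicon = _load_lexicon(cfg)
    table = _load_table(cfg.logic_table)

    if cfg.corpus:
        records = read_emr_corpus(cfg.corpus)
        gold_rows = read_jsonl(cfg.gold) if cfg.gold else []
        split_of: dict[str, str] = {}
    else:
        cohort = stage_generate(cfg, out_dir)
        records = [c.record for c in cohort.cases]
        gold_rows = read_jsonl(out_dir / "gold.jsonl")
        split_of = {c.record.record_id: c.split for c in cohort.cases}

    facts_rows = stage_extract(records, lexicon, out_dir)
    decisions = stage_decide(facts_rows, table, out_dir)

    if cfg.eval_split:
        keep = {rid for rid, s in split_of.items() if s == cfg.eval_split}
        decisions_eval = [d for d in decisions if d["record_id"] in keep]
        gold_eval = [g for g in gold_rows if g["record_id"] in keep]
    else:
        decisions_eval, gold_eval = decisions, gold_rows

    report = None
    if gold_eval:
        report = stage_evaluate(decisions_eval, gold_eval, out_dir)

    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_sha256": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "counts": {
            "records": len(records),
            "facts": len(facts_rows),
            "decisions": len(decisions),
            "evaluated": len(decisions_eval) if gold_eval else 0,
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
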