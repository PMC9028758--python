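"""Metric suite for comparing plan assignments against a gold standard.

Binary metrics (sensitivity, specificity, accuracy, PPV, NPV) are computed on
the coarse dichotomy with Plan I (emergency surgery) as the positive class;
the full 3x3 table over {I, IIA, IIB} additionally yields per-plan accuracy
(recall of each plan).  AUC is the Mann-Whitney statistic on a continuous
triage score (ties count one half), with a Hanley-McNeil standard error;
proportions get Wald intervals (Wilson available); inter-rater agreement is
Cohen's kappa with its large-sample standard error.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .case_model import CoarsePlan, TreatmentPlan

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

PLAN_ORDER = (TreatmentPlan.PLAN_I, TreatmentPlan.PLAN_IIA, TreatmentPlan.PLAN_IIB)


class EvaluationInputError(ValueError):
    """Mismatched or empty evaluation inputs."""


@dataclass(frozen=True)
class MetricEstimate:
    point: float
    ci_low: float
    ci_high: float
    n: int  # denominator the estimate (and its CI) is based on

    def as_dict(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n": self.n}


@dataclass(frozen=True)
class ConfusionMatrix2:
    """Coarse 2x2 counts; positive class is Plan I (emergency surgery)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _proportion_ci(p: float, m: int, method: str = "wald") -> tuple[float, float]:
    if method == "wald":
        half = _Z95 * math.sqrt(p * (1 - p) / m)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "wilson":
        z2 = _Z95**2
        centre = (p + z2 / (2 * m)) / (1 + z2 / m)
        half = (_Z95 / (1 + z2 / m)) * math.sqrt(p * (1 - p) / m + z2 / (4 * m**2))
        return (max(0.0, centre - half), min(1.0, centre + half))
    raise ValueError(f"unknown CI method {method!r}")


def _estimate(k: int, m: int, method: str) -> Optional[MetricEstimate]:
    if m == 0:
        return None  # undefined, never reported as 0
    p = k / m
    lo, hi = _proportion_ci(p, m, method)
    return MetricEstimate(p, lo, hi, m)


def confusion_counts(
    predicted: Sequence[TreatmentPlan], gold: Sequence[TreatmentPlan]
) -> tuple[ConfusionMatrix2, np.ndarray]:
    """Coarse 2x2 counts plus the fine 3x3 table (rows gold, cols predicted,
    order I / IIA / IIB)."""
    if len(predicted) != len(gold):
        raise EvaluationInputError(
            f"length mismatch: {len(predicted)} predictions vs {len(gold)} gold labels"
        )
    if not predicted:
        raise EvaluationInputError("empty input")
    idx = {p: i for i, p in enumerate(PLAN_ORDER)}
    table = np.zeros((3, 3), dtype=int)
    tp = fp = tn = fn = 0
    for p, g in zip(predicted, gold):
        table[idx[g], idx[p]] += 1
        pos_p = p.coarse is CoarsePlan.PLAN_I
        pos_g = g.coarse is CoarsePlan.PLAN_I
        if pos_p and pos_g:
            tp += 1
        elif pos_p and not pos_g:
            fp += 1
        elif not pos_p and pos_g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix2(tp, fp, tn, fn), table


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    accuracy: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]


def binary_metrics(cm: ConfusionMatrix2, ci_method: str = "wald") -> BinaryMetrics:
    """Point estimates with 95% CIs; a zero denominator yields None
    (undefined), not zero."""
    if cm.total < 1:
        raise EvaluationInputError("confusion matrix has no observations")
    return BinaryMetrics(
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, ci_method),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, ci_method),
        accuracy=_estimate(cm.tp + cm.tn, cm.total, ci_method),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_estimate(cm.tn, cm.tn + cm.fn, ci_method),
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    #: (fpr, tpr) at every distinct score threshold, descending, with the
    #: (0,0) and (1,1) endpoints
    curve: tuple[tuple[float, float], ...]
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], gold: Sequence[TreatmentPlan]) -> RocResult:
    """AUC as the Mann-Whitney statistic (ties count 1/2), positive class
    coarse Plan I; CI by the Hanley-McNeil normal approximation."""
    if len(scores) != len(gold):
        raise EvaluationInputError(
            f"length mismatch: {len(scores)} scores vs {len(gold)} gold labels"
        )
    y = np.array([g.coarse is CoarsePlan.PLAN_I for g in gold], dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationInputError("AUC undefined: only one class present")

    # average ranks (midranks for ties)
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # 1-based midrank
        i = j + 1
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # curve: sweep distinct thresholds descending
    thresholds = np.unique(s)[::-1]
    curve = [(0.0, 0.0)]
    for t in thresholds:
        called = s >= t
        tpr = float((called & y).sum() / n_pos)
        fpr = float((called & ~y).sum() / n_neg)
        curve.append((fpr, tpr))
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_low=max(0.0, float(auc) - _Z95 * se),
        ci_high=min(1.0, float(auc) + _Z95 * se),
        curve=tuple(curve),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def trapezoidal_auc(curve: Sequence[tuple[float, float]]) -> float:
    """Area under an (FPR, TPR) polyline; used as the cross-check route
    against the rank-based statistic."""
    pts = sorted(curve)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    n: int


def cohens_kappa(
    rater_a: Sequence[TreatmentPlan], rater_b: Sequence[TreatmentPlan]
) -> KappaResult:
    """Chance-corrected agreement on the 3-level plan labels.

    kappa = (p_o - p_e) / (1 - p_e); the CI uses the large-sample standard
    error sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).  Perfect observed agreement
    returns kappa = 1 even in the degenerate p_e = 1 case.
    """
    if len(rater_a) != len(rater_b):
        raise EvaluationInputError(
            f"length mismatch: {len(rater_a)} vs {len(rater_b)} labels"
        )
    if not rater_a:
        raise EvaluationInputError("empty input")
    n = len(rater_a)
    labels = PLAN_ORDER
    idx = {p: i for i, p in enumerate(labels)}
    table = np.zeros((3, 3))
    for a, b in zip(rater_a, rater_b):
        table[idx[a], idx[b]] += 1
    p_o = float(np.trace(table) / n)
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    if p_o == 1.0:
        return KappaResult(1.0, 1.0, 1.0, p_o, p_e, n)
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return KappaResult(
        kappa=kappa,
        ci_low=max(-1.0, kappa - _Z95 * se),
        ci_high=min(1.0, kappa + _Z95 * se),
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )


@dataclass
class MetricsReport:
    n: int
    cm: ConfusionMatrix2
    table3: np.ndarray
    binary: BinaryMetrics
    roc: Optional[RocResult]
    per_plan_accuracy: dict[str, Optional[MetricEstimate]]
    kappa_vs_gold: KappaResult
    kappa_vs_rater2: Optional[KappaResult] = None
    n_dropped: int = 0

    def as_dict(self) -> dict:
        def est(e: Optional[MetricEstimate]):
            return e.as_dict() if e is not None else None

        out = {
            "n": self.n,
            "n_dropped": self.n_dropped,
            "confusion_2x2": {"tp": self.cm.tp, "fp": self.cm.fp,
                              "tn": self.cm.tn, "fn": self.cm.fn},
            "confusion_3x3": {
                "labels": [p.value for p in PLAN_ORDER],
                "rows_gold_cols_predicted": self.table3.tolist(),
            },
            "sensitivity": est(self.binary.sensitivity),
            "specificity": est(self.binary.specificity),
            "accuracy": est(self.binary.accuracy),
            "ppv": est(self.binary.ppv),
            "npv": est(self.binary.npv),
            "per_plan_accuracy": {k: est(v) for k, v in self.per_plan_accuracy.items()},
            "kappa_vs_gold": {
                "point": self.kappa_vs_gold.kappa,
                "ci_low": self.kappa_vs_gold.ci_low,
                "ci_high": self.kappa_vs_gold.ci_high,
                "n": self.kappa_vs_gold.n,
            },
        }
        if self.roc is not None:
            out["auc"] = {"point": self.roc.auc, "ci_low": self.roc.ci_low,
                          "ci_high": self.roc.ci_high, "n": self.n}
        else:
            out["auc"] = None
        if self.kappa_vs_rater2 is not None:
            out["kappa_vs_rater2"] = {
                "point": self.kappa_vs_rater2.kappa,
                "ci_low": self.kappa_vs_rater2.ci_low,
                "ci_high": self.kappa_vs_rater2.ci_high,
                "n": self.kappa_vs_rater2.n,
            }
        return out

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_csv(self, path) -> None:
        d = self.as_dict()
        rows = []
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc"):
            e = d[name]
            if e is None:
                rows.append((name, "undefined", "", "", ""))
            else:
                rows.append((name, e["point"], e["ci_low"], e["ci_high"], e["n"]))
        for plan, e in d["per_plan_accuracy"].items():
            name = f"accuracy_plan_{plan}"
            if e is None:
                rows.append((name, "undefined", "", "", ""))
            else:
                rows.append((name, e["point"], e["ci_low"], e["ci_high"], e["n"]))
        k = d["kappa_vs_gold"]
        rows.append(("kappa_vs_gold", k["point"], k["ci_low"], k["ci_high"], k["n"]))
        if "kappa_vs_rater2" in d:
            k = d["kappa_vs_rater2"]
            rows.append(("kappa_vs_rater2", k["point"], k["ci_low"], k["ci_high"], k["n"]))
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(("metric", "point", "ci_low", "ci_high", "n"))
            writer.writerows(rows)

    def write_confusion_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["gold\\predicted"] + [p.value for p in PLAN_ORDER])
            for i, p in enumerate(PLAN_ORDER):
                writer.writerow([p.value] + list(map(int, self.table3[i])))


def triage_score(weighted_score: float, mandated: bool) -> float:
    """Continuous score fed to the ROC: mandate-fired cases rank above every
    score-based decision (documented adapter; isolated here on purpose)."""
    return 1.0 if mandated else weighted_score


def per_plan_accuracy(
    table3: np.ndarray, ci_method: str = "wald"
) -> dict[str, Optional[MetricEstimate]]:
    """Recall of each plan in the 3x3 table: correct-in-plan / gold-in-plan."""
    out = {}
    for i, plan in enumerate(PLAN_ORDER):
        m = int(table3[i].sum())
        out[plan.value] = _estimate(int(table3[i, i]), m, ci_method)
    return out


def evaluate_run(
    decisions: Sequence[dict],
    gold: Sequence[dict],
    rater2: Optional[Sequence[dict]] = None,
    ci_method: str = "wald",
) -> MetricsReport:
    """Join decision and gold rows on record_id and emit the full report.

    ``decisions`` rows need record_id, plan, and (for the ROC) weighted_score
    and mandated; ``gold`` rows need record_id and gold_plan.  Records missing
    from either side are dropped with a count.
    """
    dec_by_id = {d["record_id"]: d for d in decisions}
    gold_by_id = {g["record_id"]: g for g in gold}
    ids = [rid for rid in dec_by_id if rid in gold_by_id]
    n_dropped = (len(dec_by_id) - len(ids)) + (len(gold_by_id) - len(ids))
    if not ids:
        raise EvaluationInputError("empty join: no record_id present on both sides")

    predicted = [TreatmentPlan(dec_by_id[rid]["plan"]) for rid in ids]
    gold_plans = [TreatmentPlan(gold_by_id[rid]["gold_plan"]) for rid in ids]
    cm, table3 = confusion_counts(predicted, gold_plans)
    binary = binary_metrics(cm, ci_method)

    roc: Optional[RocResult] = None
    if all("weighted_score" in dec_by_id[rid] for rid in ids):
        scores = [
            triage_score(
                float(dec_by_id[rid]["weighted_score"]),
                bool(dec_by_id[rid].get("mandated", False)),
            )
            for rid in ids
        ]
        try:
            roc = roc_auc(scores, gold_plans)
        except EvaluationInputError:
            roc = None  # single-class cohort: AUC undefined

    kappa_gold = cohens_kappa(predicted, gold_plans)
    kappa2 = None
    if rater2 is not None:
        r2_by_id = {r["record_id"]: r for r in rater2}
        both = [rid for rid in ids if rid in r2_by_id]
        if not both:
            raise EvaluationInputError("empty join with second rater")
        kappa2 = cohens_kappa(
            [TreatmentPlan(dec_by_id[rid]["plan"]) for rid in both],
            [TreatmentPlan(r2_by_id[rid]["plan"]) for rid in both],
        )

    return MetricsReport(
        n=len(ids),
        cm=cm,
        table3=table3,
        binary=binary,
        roc=roc,
        per_plan_accuracy=per_plan_accuracy(table3, ci_method),
        kappa_vs_gold=kappa_gold,
        kappa_vs_rater2=kappa2,
        n_dropped=n_dropped,
    )
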