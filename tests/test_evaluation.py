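"""Metric suite: hand-worked examples, independent oracles, CI behaviour."""

import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from ichtriage.case_model import TreatmentPlan
from ichtriage.evaluation import (
    ConfusionMatrix2,
    EvaluationInputError,
    binary_metrics,
    cohens_kappa,
    confusion_counts,
    evaluate_run,
    roc_auc,
    trapezoidal_auc,
    triage_score,
    per_plan_accuracy,
)

I, IIA, IIB = TreatmentPlan.PLAN_I, TreatmentPlan.PLAN_IIA, TreatmentPlan.PLAN_IIB


def brute_force_auc(scores, gold):
    """Pair-enumeration oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, g in zip(scores, gold) if g is I]
    neg = [s for s, g in zip(scores, gold) if g is not I]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        cm, t3 = confusion_counts([I, IIA, IIB], [I, IIA, IIB])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 2, 0, 0)
        assert np.trace(t3) == 3

    def test_single_false_positive(self):
        cm, _ = confusion_counts([I], [IIB])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (0, 1, 0, 0)

    def test_hand_count_with_coarse_mapping(self):
        cm, t3 = confusion_counts([I, I, IIA, IIB], [I, IIA, IIA, I])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)
        # fine-grained: only the IIA/IIA pair is on the diagonal besides I/I
        assert np.trace(t3) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationInputError):
            confusion_counts([I], [I, IIA])


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionMatrix2(tp=50, fp=0, tn=50, fn=0))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(m, name).point == 1.0

    def test_hand_arithmetic(self):
        m = binary_metrics(ConfusionMatrix2(tp=45, fn=5, tn=40, fp=10))
        assert m.sensitivity.point == pytest.approx(0.90)
        assert m.specificity.point == pytest.approx(0.80)
        assert m.accuracy.point == pytest.approx(0.85)
        assert m.ppv.point == pytest.approx(45 / 55)
        assert m.npv.point == pytest.approx(40 / 45)

    def test_wald_interval_formula(self):
        m = binary_metrics(ConfusionMatrix2(tp=45, fn=5, tn=40, fp=10))
        p, n = 0.9, 50
        half = 1.959963984540054 * math.sqrt(p * (1 - p) / n)
        assert m.sensitivity.ci_low == pytest.approx(p - half)
        assert m.sensitivity.ci_high == pytest.approx(min(1.0, p + half))

    def test_zero_denominator_is_undefined_not_zero(self):
        m = binary_metrics(ConfusionMatrix2(tp=0, fn=0, tn=5, fp=5))
        assert m.sensitivity is None
        assert m.specificity is not None

    def test_ci_width_scales_as_inverse_sqrt_n(self):
        small = binary_metrics(ConfusionMatrix2(tp=45, fn=5, tn=40, fp=10))
        big = binary_metrics(ConfusionMatrix2(tp=180, fn=20, tn=160, fp=40))
        for name in ("sensitivity", "specificity", "accuracy"):
            ws = getattr(small, name)
            wb = getattr(big, name)
            ratio = (wb.ci_high - wb.ci_low) / (ws.ci_high - ws.ci_low)
            assert ratio == pytest.approx(0.5, abs=1e-9)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [I, I, IIA, IIB])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([0.5, 0.5, 0.5, 0.5], [I, I, IIB, IIB])
        assert r.auc == 0.5

    def test_worked_example(self):
        r = roc_auc([0.9, 0.7, 0.7, 0.2], [I, I, IIA, IIB])
        assert r.auc == pytest.approx(0.875, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationInputError):
            roc_auc([0.4, 0.6], [I, I])

    def test_curve_endpoints_and_monotonicity(self):
        r = roc_auc([0.9, 0.7, 0.7, 0.2, 0.1], [I, I, IIA, IIB, IIB])
        assert r.curve[0] == (0.0, 0.0) and r.curve[-1] == (1.0, 1.0)
        fprs = [p[0] for p in r.curve]
        tprs = [p[1] for p in r.curve]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pair_count_and_trapezoid_and_sklearn(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(10, 200))
        gold = [I if rng.random() < 0.4 else (IIA if rng.random() < 0.5 else IIB)
                for _ in range(n)]
        if all(g is I for g in gold):
            gold[0] = IIB
        if not any(g is I for g in gold):
            gold[0] = I
        scores = np.round(rng.random(n), 1).tolist()  # coarse grid forces ties
        r = roc_auc(scores, gold)
        assert abs(r.auc - brute_force_auc(scores, gold)) < 1e-12
        assert abs(r.auc - trapezoidal_auc(r.curve)) < 1e-12
        sk = roc_auc_score([1 if g is I else 0 for g in gold], scores)
        assert r.auc == pytest.approx(sk, abs=1e-12)

    def test_hanley_mcneil_se_shrinks_with_n(self):
        scores = [0.9, 0.8, 0.35, 0.4, 0.3, 0.2]  # one positive below a negative
        gold = [I, I, I, IIB, IIB, IIB]
        small = roc_auc(scores, gold)
        big = roc_auc(scores * 4, gold * 4)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)


class TestKappa:
    def test_identical_lists(self):
        assert cohens_kappa([I, IIA, IIB], [I, IIA, IIB]).kappa == 1.0

    def test_degenerate_single_category_perfect_agreement(self):
        # p_e = 1; perfect observed agreement still reports kappa 1
        assert cohens_kappa([I, I, I], [I, I, I]).kappa == 1.0

    def test_hand_arithmetic_2x2(self):
        # agreement table [[20, 5], [10, 15]] over two plans, n = 50
        a = [I] * 25 + [IIB] * 25
        b = [I] * 20 + [IIB] * 5 + [I] * 10 + [IIB] * 15
        r = cohens_kappa(a, b)
        assert r.p_observed == pytest.approx(0.70)
        assert r.p_expected == pytest.approx(0.50)
        assert r.kappa == pytest.approx(0.40)

    def test_cyclic_permutation_gives_negative_kappa(self):
        a = [I, I, IIA, IIA, IIB, IIB]
        cycle = {I: IIA, IIA: IIB, IIB: I}
        b = [cycle[x] for x in a]
        r = cohens_kappa(a, b)
        assert r.kappa == pytest.approx(-0.5)
        assert r.kappa < 0

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(17)
        plans = list(TreatmentPlan)
        a = [plans[i] for i in rng.integers(0, 3, 100)]
        b = [plans[i] for i in rng.integers(0, 3, 100)]
        perm = {I: IIB, IIA: I, IIB: IIA}
        base = cohens_kappa(a, b).kappa
        relabeled = cohens_kappa([perm[x] for x in a], [perm[x] for x in b]).kappa
        assert relabeled == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_sklearn(self, trial):
        rng = np.random.default_rng(900 + trial)
        plans = list(TreatmentPlan)
        a = [plans[i] for i in rng.integers(0, 3, 80)]
        b = [plans[i] for i in rng.integers(0, 3, 80)]
        ours = cohens_kappa(a, b).kappa
        sk = cohen_kappa_score([x.value for x in a], [x.value for x in b])
        assert ours == pytest.approx(sk, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationInputError):
            cohens_kappa([I], [I, I])


class TestEvaluateRun:
    @staticmethod
    def _decisions(pairs):
        return [
            {"record_id": rid, "plan": plan.value, "weighted_score": score,
             "mandated": mandated}
            for rid, plan, score, mandated in pairs
        ]

    @staticmethod
    def _gold(pairs):
        return [{"record_id": rid, "gold_plan": plan.value} for rid, plan in pairs]

    def test_perfect_run(self):
        ids = [f"c{i}" for i in range(10)]
        plans = [I, IIA, IIB, I, IIA, IIB, I, IIA, IIB, I]
        dec = self._decisions([(r, p, 0.9 if p is I else 0.1, False)
                               for r, p in zip(ids, plans)])
        gold = self._gold(list(zip(ids, plans)))
        rep = evaluate_run(dec, gold)
        assert rep.binary.accuracy.point == 1.0
        assert rep.kappa_vs_gold.kappa == 1.0
        assert rep.roc.auc == 1.0

    def test_fine_error_invisible_to_coarse_metrics(self):
        ids = [f"c{i}" for i in range(10)]
        gold_plans = [I, I, IIA, IIA, IIA, IIB, IIB, IIB, IIB, IIB]
        pred_plans = list(gold_plans)
        pred_plans[2] = IIB  # IIA -> IIB: coarse class unchanged
        dec = self._decisions([(r, p, 0.9 if p is I else 0.1, False)
                               for r, p in zip(ids, pred_plans)])
        rep = evaluate_run(dec, self._gold(list(zip(ids, gold_plans))))
        # fine accuracy = trace/n = 0.9; coarse accuracy still 1.0
        assert np.trace(rep.table3) / rep.n == pytest.approx(0.9)
        assert rep.binary.accuracy.point == 1.0

    def test_disjoint_ids_rejected(self):
        dec = self._decisions([("a", I, 1.0, True)])
        gold = self._gold([("b", I)])
        with pytest.raises(EvaluationInputError):
            evaluate_run(dec, gold)

    def test_second_rater_kappa_reported(self):
        ids = [f"c{i}" for i in range(6)]
        plans = [I, IIA, IIB, I, IIA, IIB]
        dec = self._decisions([(r, p, 0.5, False) for r, p in zip(ids, plans)])
        gold = self._gold(list(zip(ids, plans)))
        rep = evaluate_run(dec, gold, rater2=[
            {"record_id": r, "plan": p.value} for r, p in zip(ids, plans)
        ])
        assert rep.kappa_vs_rater2.kappa == 1.0

    def test_per_plan_accuracy_is_recall_of_plan(self):
        table3 = np.array([[8, 2, 0], [1, 6, 3], [0, 0, 10]])
        acc = per_plan_accuracy(table3)
        assert acc["I"].point == pytest.approx(0.8)
        assert acc["IIA"].point == pytest.approx(0.6)
        assert acc["IIB"].point == pytest.approx(1.0)


def test_mandated_cases_outrank_score_based_cases():
    assert triage_score(0.2, True) == 1.0
    assert triage_score(0.2, False) == 0.2
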