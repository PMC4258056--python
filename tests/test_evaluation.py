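"""Confusion metrics, F1, ROC/AUC, max-F1 and E-value sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funrep as fr
from funrep.assignments_io import HitTable
from funrep.prediction import PredictionSet


def brute_force_auc(scores, reference):
    """Average over all positive x negative pairs (ties count half)."""
    pos = [scores.get(f, -np.inf) for f in reference.positives]
    neg = [scores.get(f, -np.inf) for f in reference.negatives]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self, small_reference):
        pred = PredictionSet("p", small_reference.positives)
        m = fr.confusion(pred, small_reference)
        assert (m.tpr, m.fpr, m.ppv, m.f1) == (100.0, 0.0, 100.0, 100.0)
        assert m.specificity == 100.0

    def test_empty_prediction_zero_by_convention(self, small_reference):
        m = fr.confusion(PredictionSet("p", frozenset()), small_reference)
        assert (m.tp, m.fpr, m.tpr) == (0, 0.0, 0.0)
        assert m.ppv == 0.0 and m.f1 == 0.0
        assert not m.ppv_defined

    def test_counts_match_hand_enumeration(self, rng, small_reference):
        universe = sorted(small_reference.universe)
        predicted = frozenset(rng.choice(universe, size=12, replace=False))
        m = fr.confusion(PredictionSet("p", predicted), small_reference)
        tp = len(predicted & small_reference.positives)
        assert m.tp == tp
        assert m.fp == 12 - tp
        assert m.fn == 10 - tp
        assert m.tn == 20 - (12 - tp)
        # partition invariants
        assert m.tp + m.fn == len(small_reference.positives)
        assert m.fp + m.tn == len(small_reference.negatives)
        assert m.specificity == pytest.approx(100.0 - m.fpr)

    def test_prediction_outside_universe_rejected(self, small_reference):
        with pytest.raises(ValueError, match="K99999"):
            fr.confusion(PredictionSet("p", frozenset({"K99999"})), small_reference)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fr.AnnotationReference(frozenset(), frozenset())


class TestF1FromRates:
    @pytest.mark.parametrize(
        "tpr, ppv, expected",
        [
            (94.02, 82.88, 88.10),  # filtered scaled mean-score, UProC
            (93.75, 84.35, 88.80),  # filtered scaled mean-score, RAPSearch
            (95.69, 20.16, 33.30),  # assembly-based sweep, most liberal cutoff
        ],
    )
    def test_published_rate_pairs(self, tpr, ppv, expected):
        assert fr.f1_from_rates(tpr, ppv) == pytest.approx(expected, abs=0.1)

    @settings(max_examples=50)
    @given(st.floats(0.01, 100.0))
    def test_harmonic_mean_of_equal_rates_is_identity(self, x):
        assert fr.f1_from_rates(x, x) == pytest.approx(x)

    def test_both_zero_is_zero_by_convention(self):
        assert fr.f1_from_rates(0.0, 0.0) == 0.0

    def test_rates_outside_percent_range_rejected(self):
        with pytest.raises(ValueError):
            fr.f1_from_rates(101.0, 50.0)


class TestRocAuc:
    def test_perfect_separation(self, small_reference):
        scores = {f: (10.0 if f in small_reference.positives else 1.0)
                  for f in small_reference.universe}
        curve = fr.roc_auc(scores, small_reference)
        assert curve.auc == 1.0
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_all_ties_give_half(self, small_reference):
        scores = {f: 3.0 for f in small_reference.universe}
        assert fr.roc_auc(scores, small_reference).auc == 0.5

    def test_curve_is_monotone(self, rng, small_reference):
        scores = {f: float(rng.integers(0, 5)) for f in small_reference.universe}
        pts = np.array(fr.roc_auc(scores, small_reference).points)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_matches_pairwise_brute_force_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            ids = [f"K{i}" for i in range(n)]
            n_pos = int(rng.integers(1, n))
            reference = fr.AnnotationReference(
                frozenset(ids[:n_pos]), frozenset(ids)
            )
            # integer scores force ties; some functions get no evidence
            scores = {
                f: float(rng.integers(0, 6))
                for f in ids
                if rng.random() < 0.85
            }
            got = fr.roc_auc(scores, reference).auc
            assert got == pytest.approx(brute_force_auc(scores, reference), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng, small_reference):
        scores = {f: float(rng.normal()) for f in small_reference.universe}
        transformed = {f: np.exp(3.0 * v + 1.0) for f, v in scores.items()}
        a = fr.roc_auc(scores, small_reference).auc
        b = fr.roc_auc(transformed, small_reference).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_negated_scores_complement_auc(self, rng, small_reference):
        scores = {f: float(rng.normal()) for f in small_reference.universe}
        a = fr.roc_auc(scores, small_reference).auc
        b = fr.roc_auc({f: -v for f, v in scores.items()}, small_reference).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_reference_rejected(self):
        ids = frozenset({"K1", "K2"})
        all_pos = fr.AnnotationReference(ids, ids)
        with pytest.raises(ValueError, match="AUC undefined"):
            fr.roc_auc({"K1": 1.0, "K2": 2.0}, all_pos)

    def test_mean_auc_aggregation(self, rng, small_reference):
        curves = []
        for _ in range(3):
            scores = {f: float(rng.normal()) for f in small_reference.universe}
            curves.append(fr.roc_auc(scores, small_reference))
        assert fr.mean_auc(curves) == pytest.approx(
            np.mean([c.auc for c in curves])
        )


class TestMaxF1:
    def test_perfect_separation_reaches_100(self, small_reference):
        scores = {f: (10.0 if f in small_reference.positives else 1.0)
                  for f in small_reference.universe}
        assert fr.max_f1(scores, small_reference) == pytest.approx(100.0)

    def test_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(20):
            ids = [f"K{i}" for i in range(12)]
            reference = fr.AnnotationReference(frozenset(ids[:5]), frozenset(ids))
            scores = {f: float(rng.integers(0, 5)) for f in ids if rng.random() < 0.9}
            # brute force: F1 of "value > t" for every distinct score t
            values = {f: scores.get(f, -np.inf) for f in ids}
            best = 0.0
            for t in set(values.values()):
                predicted = frozenset(f for f, v in values.items() if v > t)
                m = fr.confusion(PredictionSet("p", predicted), reference)
                best = max(best, m.f1)
            assert fr.max_f1(scores, reference) == pytest.approx(best, abs=1e-9)

    def test_dominates_any_thresholded_prediction(self, rng, small_reference):
        scores = {f: float(rng.normal(5, 2)) for f in small_reference.universe}
        bound = fr.max_f1(scores, small_reference)
        for t in np.percentile(list(scores.values()), [10, 40, 60, 90]):
            predicted = frozenset(f for f, v in scores.items() if v > t)
            m = fr.confusion(PredictionSet("p", predicted), small_reference)
            assert m.f1 <= bound + 1e-9


class TestEvalueCutoffSweep:
    @staticmethod
    def make_hits(entries):
        frame = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(len(entries))],
                "function_id": [e[0] for e in entries],
                "score": 50.0,
                "e_value": [e[1] for e in entries],
            }
        )
        return HitTable("s1", frame, best_hit_resolved=True)

    def test_metrics_match_hand_enumeration(self):
        ids = [f"K{i}" for i in range(1, 9)]
        reference = fr.AnnotationReference(frozenset(ids[:4]), frozenset(ids))
        hits = self.make_hits(
            [
                ("K1", 1e-30), ("K2", 1e-10), ("K3", 1e-3), ("K4", 5.0),
                ("K5", 1e-20), ("K6", 1e-2), ("K7", 2.0), ("K8", 8.0),
            ]
        )
        sweep = dict(fr.evalue_cutoff_sweep(hits, reference, [1e-15, 1e-5, 10.0]))
        # cutoff 1e-15: K1, K5 predicted -> TP 1, FP 1
        assert (sweep[1e-15].tp, sweep[1e-15].fp) == (1, 1)
        # cutoff 1e-5: adds K2 -> TP 2, FP 1
        assert (sweep[1e-5].tp, sweep[1e-5].fp) == (2, 1)
        # cutoff 10: everything -> TP 4, FP 4
        assert (sweep[10.0].tp, sweep[10.0].fp) == (4, 4)
        assert sweep[10.0].tpr == 100.0 and sweep[10.0].fpr == 100.0

    def test_cutoff_larger_than_all_evalues_predicts_all_hit_functions(self):
        ids = ["K1", "K2", "K3"]
        reference = fr.AnnotationReference(frozenset(ids[:1]), frozenset(ids))
        hits = self.make_hits([("K1", 1e-5), ("K2", 1e-8)])
        ((_, m),) = fr.evalue_cutoff_sweep(hits, reference, [100.0])
        assert m.tp == 1 and m.fp == 1 and m.fn == 0

    def test_cutoff_zero_predicts_nothing(self):
        ids = ["K1", "K2"]
        reference = fr.AnnotationReference(frozenset(ids[:1]), frozenset(ids))
        hits = self.make_hits([("K1", 1e-5), ("K2", 1e-8)])
        ((_, m),) = fr.evalue_cutoff_sweep(hits, reference, [0.0])
        assert m.tp == 0 and m.fp == 0

    def test_sweep_is_antitone_in_cutoff(self, rng):
        ids = [f"K{i}" for i in range(30)]
        reference = fr.AnnotationReference(frozenset(ids[:12]), frozenset(ids))
        hits = self.make_hits(
            [(ids[int(rng.integers(0, 30))], float(10 ** rng.uniform(-30, 1)))
             for _ in range(120)]
        )
        cutoffs = [10.0, 1e-5, 1e-10, 1e-20, 1e-28]
        sweep = fr.evalue_cutoff_sweep(hits, reference, cutoffs)
        tps = [m.tp for _, m in sweep]
        fps = [m.fp for _, m in sweep]
        assert tps == sorted(tps, reverse=True)
        assert fps == sorted(fps, reverse=True)

    def test_missing_evalues_rejected(self):
        frame = pd.DataFrame(
            {"read_id": ["r1"], "function_id": ["K1"], "score": [5.0],
             "e_value": [np.nan]}
        )
        hits = HitTable("s1", frame, best_hit_resolved=True)
        reference = fr.AnnotationReference(frozenset({"K1"}), frozenset({"K1", "K2"}))
        with pytest.raises(ValueError, match="E-value"):
            fr.evalue_cutoff_sweep(hits, reference, [1.0])
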