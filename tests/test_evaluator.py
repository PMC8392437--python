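"""Sensitivity/CI arithmetic, AUC, stage rows, rank tests, audit table."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmacall.classifier import OperatingPoint, ScoreSet, derive_cutoff
from plasmacall.evaluator import (
    EvaluationError,
    evaluate_models,
    false_positive_report,
    rank_tests,
    roc_auc,
    sensitivity_ci,
    stage_breakdown,
)


class TestSensitivityCi:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (20, 25, (80, 64, 96)),
            (17, 27, (63, 45, 81)),
            (20, 30, (67, 50, 84)),
            (13, 43, (30, 16, 44)),
            (111, 260, (43, 37, 49)),
            (18, 29, (62, 44, 80)),
            (28, 66, (42, 30, 54)),
            (7, 43, (16, 5, 27)),
            (21, 29, (72, 56, 88)),
            (0, 10, (0, 0, 0)),
            (10, 10, (100, 100, 100)),
        ],
    )
    def test_wald_on_rounded_percentage(self, k, n, expected):
        assert sensitivity_ci(k, n) == expected

    def test_bounds_contain_sensitivity_and_stay_in_range(self):
        rng = random.Random(3)
        for _ in range(200):
            n = rng.randint(1, 400)
            k = rng.randint(0, n)
            sens, lo, hi = sensitivity_ci(k, n)
            assert 0 <= lo <= sens <= hi <= 100

    def test_exact_proportion_variant_differs_where_expected(self):
        # colorectal 28/66: rounded-percentage convention gives lower bound 30,
        # the exact-proportion Wald gives 31
        assert sensitivity_ci(28, 66)[1] == 30
        assert sensitivity_ci(28, 66, on_rounded=False)[1] == 31

    def test_zero_n_raises(self):
        with pytest.raises(EvaluationError):
            sensitivity_ci(1, 0)


def _labels(cancers, controls, stages=None):
    rows = []
    for i, sid in enumerate(cancers):
        stage = stages[i] if stages else "II"
        rows.append({"sample_id": sid, "label": "cancer", "organ": "lung",
                     "stage": stage, "sex": "male", "batch": "automated"})
    for sid in controls:
        rows.append({"sample_id": sid, "label": "control", "organ": "none",
                     "stage": "not_applicable", "sex": "female", "batch": "automated"})
    return pd.DataFrame(rows).set_index("sample_id")


class TestRocAuc:
    def test_perfect_separation(self):
        scores = ScoreSet(pd.Series({"a": 0.9, "b": 0.8, "x": 0.1, "y": 0.2}))
        labels = _labels(["a", "b"], ["x", "y"])
        assert roc_auc(scores, labels) == 1.0

    def test_identical_scores_give_half(self):
        scores = ScoreSet(pd.Series({"a": 0.5, "b": 0.5, "x": 0.5, "y": 0.5}))
        labels = _labels(["a", "b"], ["x", "y"])
        assert roc_auc(scores, labels) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = random.Random(11)
        for _ in range(100):
            n_pos, n_neg = rng.randint(2, 12), rng.randint(2, 12)
            pos = [round(rng.random(), 1) for _ in range(n_pos)]
            neg = [round(rng.random(), 1) for _ in range(n_neg)]
            ids_p = [f"p{i}" for i in range(n_pos)]
            ids_n = [f"n{i}" for i in range(n_neg)]
            scores = ScoreSet(pd.Series({**dict(zip(ids_p, pos)), **dict(zip(ids_n, neg))}))
            labels = _labels(ids_p, ids_n)
            # brute force over all cancer-control pairs, ties count one half
            wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
            assert math.isclose(roc_auc(scores, labels), wins / (n_pos * n_neg))

    def test_single_class_raises(self):
        scores = ScoreSet(pd.Series({"a": 0.9, "b": 0.8}))
        labels = _labels(["a", "b"], [])
        with pytest.raises(EvaluationError):
            roc_auc(scores, labels)


class TestEvaluateModels:
    def test_row_composition(self):
        cancers = [f"c{i}" for i in range(25)]
        controls = [f"n{i}" for i in range(100)]
        # 20 cancers above the threshold
        scores = {sid: (0.9 if i < 20 else 0.1) for i, sid in enumerate(cancers)}
        scores.update({sid: 0.05 for sid in controls})
        score_set = ScoreSet(pd.Series(scores))
        labels = _labels(cancers, controls)
        op = OperatingPoint(0.95, 0.5, 0.95, 5, 100)
        rows = evaluate_models({"lung": score_set}, labels, {"lung": {0.95: op}})
        cell = rows[0].cells[0.95]
        assert rows[0].n_cancer == 25
        assert (cell.k_detected, cell.sensitivity_pct, cell.ci_low_pct, cell.ci_high_pct) == (
            20, 80, 64, 96,
        )

    def test_higher_specificity_never_detects_more(self):
        rng = np.random.default_rng(4)
        cancers = [f"c{i}" for i in range(30)]
        controls = [f"n{i}" for i in range(120)]
        values = dict(zip(cancers, rng.beta(3, 2, 30)))
        values.update(dict(zip(controls, rng.beta(2, 5, 120))))
        score_set = ScoreSet(pd.Series(values))
        labels = _labels(cancers, controls)
        control_scores = [values[s] for s in controls]
        ops = {t: derive_cutoff(control_scores, t) for t in (0.95, 0.99)}
        rows = evaluate_models({"m": score_set}, labels, {"m": ops})
        assert rows[0].cells[0.99].k_detected <= rows[0].cells[0.95].k_detected


class TestStageBreakdown:
    def test_unknown_stage_never_counted(self):
        cancers = ["a", "b", "c", "d"]
        stages = ["I", "II", "unknown", "II"]
        controls = [f"n{i}" for i in range(30)]
        values = {sid: 0.9 for sid in cancers}
        values.update({sid: 0.1 for sid in controls})
        labels = _labels(cancers, controls, stages)
        op = OperatingPoint(0.95, 0.5, 0.95, 0, 30)
        rows = stage_breakdown(ScoreSet(pd.Series(values)), labels, op)
        assert sum(r.n for r in rows) == 3  # the unknown-stage cancer is absent
        assert all(r.sensitivity_pct == 100 for r in rows)
        assert all(r.auc == 1.0 for r in rows)


class TestRankTests:
    def test_identical_groups_posthoc_p_is_one(self):
        groups = {"a": [1, 2, 3, 4, 5] * 4, "b": [1, 2, 3, 4, 5] * 4,
                  "c": [9, 9, 1, 1, 5] * 4}
        result = rank_tests(groups)
        if result.performed_posthoc:
            assert math.isclose(result.pairwise[("a", "b")], 1.0)

    def test_no_posthoc_without_significant_omnibus(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(0, 1, 15) for g in "abc"}
        result = rank_tests(groups)
        assert result.omnibus_p >= 0.05
        assert result.performed_posthoc is False
        assert result.pairwise == {}

    def test_pairwise_matches_rank_statistic_oracle(self):
        rng = random.Random(21)
        for _ in range(50):
            a = [rng.randint(0, 5) for _ in range(rng.randint(4, 10))]
            b = [rng.randint(0, 5) for _ in range(rng.randint(4, 10))]
            groups = {"a": a, "b": [x + 3 for x in b]}  # shifted so omnibus often fires
            result = rank_tests(groups)
            if not result.performed_posthoc:
                continue
            # independent oracle: direct tie-corrected normal approximation
            combined = np.array(a + [x + 3 for x in b], dtype=float)
            ranks = stats.rankdata(combined)
            n1, n2 = len(a), len(b)
            w = ranks[:n1].sum()
            n = n1 + n2
            _, counts = np.unique(combined, return_counts=True)
            var = n1 * n2 / 12.0 * (n + 1 - ((counts**3 - counts).sum()) / (n * (n - 1)))
            z = (w - n1 * (n + 1) / 2.0) / math.sqrt(var)
            p = 2 * stats.norm.sf(abs(z))
            assert math.isclose(result.pairwise[("a", "b")], p, rel_tol=0, abs_tol=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(EvaluationError):
            rank_tests({"a": [1, 2], "b": []})


class TestFalsePositiveReport:
    def test_count_matches_operating_point(self):
        rng = np.random.default_rng(8)
        controls = [f"n{i}" for i in range(100)]
        values = dict(zip(controls, rng.random(100)))
        cancers = ["c0", "c1"]
        values.update({"c0": 0.99, "c1": 0.98})
        labels = _labels(cancers, controls)
        op = derive_cutoff([values[s] for s in controls], 0.95)
        report = false_positive_report(ScoreSet(pd.Series(values)), labels, op)
        assert len(report) == op.n_control_positive == 5
        assert list(report["score"]) == sorted(report["score"], reverse=True)
        assert (report["margin"] > 0).all()

    def test_empty_when_no_control_above(self):
        controls = [f"n{i}" for i in range(30)]
        values = {sid: 0.1 for sid in controls}
        values["c0"] = 0.9
        labels = _labels(["c0"], controls)
        op = OperatingPoint(0.95, 0.5, 1.0, 0, 30)
        report = false_positive_report(ScoreSet(pd.Series(values)), labels, op)
        assert len(report) == 0
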