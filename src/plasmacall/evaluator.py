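"""Evaluation arithmetic: sensitivity with confidence intervals at fixed
specificity, ROC/AUC, stage stratification, rank-based screens, and the
false-positive audit table.

The confidence-interval convention is a Wald (normal-approximation) interval
with z = 1.96 computed on the *rounded* sensitivity percentage: sensitivity
is first rounded to the nearest integer percent (half away from zero), the
interval is formed on that value, and each bound is again rounded and
clipped to [0, 100]. An exact-proportion Wald variant (interval on k/n
before rounding) is available behind ``on_rounded=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("I", "II", "III", "IV")

Z_95 = 1.96


class EvaluationError(ValueError):
    pass


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sensitivity_ci(k: int, n: int, z: float = Z_95, on_rounded: bool = True) -> tuple[int, int, int]:
    """Sensitivity percent with its Wald 95% CI, all as integers.

    ``on_rounded=True`` (default) forms the interval on the rounded
    percentage p = round(100 k/n)/100; the exact-proportion variant uses
    p = k/n directly. Bounds are rounded to integers and clipped to [0, 100].
    """
    if n <= 0:
        raise EvaluationError("n must be positive")
    if not 0 <= k <= n:
        raise EvaluationError(f"need 0 <= k <= n, got k={k} n={n}")
    sens_pct = _round_half_away(100.0 * k / n)
    p = sens_pct / 100.0 if on_rounded else k / n
    half = z * math.sqrt(p * (1.0 - p) / n) * 100.0
    lo = max(0, min(100, _round_half_away(p * 100.0 - half)))
    hi = max(0, min(100, _round_half_away(p * 100.0 + half)))
    lo = min(lo, sens_pct)
    hi = max(hi, sens_pct)
    return sens_pct, lo, hi


@dataclass(frozen=True)
class PerformanceCell:
    k_detected: int
    sensitivity_pct: int
    ci_low_pct: int
    ci_high_pct: int


@dataclass
class PerformanceRow:
    """One model's sensitivities at each operating point (the Table-2 shape)."""

    model: str
    n_cancer: int
    cells: dict[float, PerformanceCell]  # keyed by target specificity


def evaluate_models(scores_by_model, labels: pd.DataFrame, points_by_model) -> list[PerformanceRow]:
    """Sensitivity rows for every model at every derived operating point.

    A cancer is detected when its score is strictly above the threshold
    anchored on that model's own control scores.
    """
    rows = []
    for model in sorted(scores_by_model):
        scores = scores_by_model[model].scores
        cancer_ids = [s for s in scores.index if labels.loc[s, "label"] == "cancer"]
        if not cancer_ids:
            raise EvaluationError(f"model {model!r} has no cancer samples")
        cells = {}
        for target, op in sorted(points_by_model[model].items()):
            k = sum(1 for s in cancer_ids if op.is_positive(float(scores[s])))
            sens, lo, hi = sensitivity_ci(k, len(cancer_ids))
            cells[target] = PerformanceCell(k, sens, lo, hi)
        rows.append(PerformanceRow(model=model, n_cancer=len(cancer_ids), cells=cells))
    return rows


def roc_auc(scores, labels: pd.DataFrame) -> float:
    """AUC via the Mann-Whitney rank statistic (ties count one half).

    Equals the trapezoidal area under the ROC curve.
    """
    series = scores.scores if hasattr(scores, "scores") else pd.Series(scores)
    y = labels.loc[series.index, "label"]
    pos = series[y == "cancer"].to_numpy()
    neg = series[y == "control"].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both classes required for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels: pd.DataFrame) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) over all distinct score cutoffs."""
    series = scores.scores if hasattr(scores, "scores") else pd.Series(scores)
    y = (labels.loc[series.index, "label"] == "cancer").to_numpy()
    values = series.to_numpy()
    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1]])
    rows = []
    for threshold in thresholds:
        called = values > threshold if np.isfinite(threshold) else np.zeros_like(y, dtype=bool)
        tpr = called[y].mean() if y.any() else 0.0
        fpr = called[~y].mean() if (~y).any() else 0.0
        rows.append({"threshold": threshold, "fpr": float(fpr), "tpr": float(tpr)})
    return pd.DataFrame(rows)


@dataclass
class StageRow:
    stage: str
    n: int
    k: int
    sensitivity_pct: int
    ci_low_pct: int
    ci_high_pct: int
    auc: float


def stage_breakdown(scores, labels: pd.DataFrame, op) -> list[StageRow]:
    """Per-stage sensitivity (at the given operating point) and per-stage AUC.

    Stage AUC compares the stage's cancers against all controls. Cancers of
    unknown stage are excluded from every row.
    """
    series = scores.scores if hasattr(scores, "scores") else pd.Series(scores)
    frame = labels.loc[series.index]
    controls = series[frame["label"] == "control"]
    rows = []
    for stage in STAGES:
        stage_ids = frame[(frame["label"] == "cancer") & (frame["stage"] == stage)].index
        if len(stage_ids) == 0:
            continue
        stage_scores = series[stage_ids]
        k = int(sum(op.is_positive(float(s)) for s in stage_scores))
        sens, lo, hi = sensitivity_ci(k, len(stage_ids))
        merged = pd.concat([stage_scores, controls])
        merged_labels = labels.loc[merged.index]
        auc = roc_auc(pd.Series(merged), merged_labels)
        rows.append(StageRow(stage=stage, n=len(stage_ids), k=k,
                             sensitivity_pct=sens, ci_low_pct=lo, ci_high_pct=hi, auc=auc))
    return rows


# ---------------------------------------------------------------------------
# rank-based screens


@dataclass
class RankTestResult:
    omnibus_p: float
    performed_posthoc: bool
    pairwise: dict = field(default_factory=dict)  # (group_a, group_b) -> p


def _rank_sum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p, normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return float(2.0 * stats.norm.sf(abs(z)))


def rank_tests(groups: dict, alpha: float = 0.05) -> RankTestResult:
    """Kruskal-Wallis omnibus screen with unadjusted pairwise rank-sum post hocs.

    Pairwise Wilcoxon rank-sum tests (normal approximation, tie-corrected,
    no continuity correction, no multiplicity adjustment) run only when the
    omnibus p is below ``alpha``.
    """
    if len(groups) < 2:
        raise EvaluationError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) == 0:
            raise EvaluationError(f"group {name!r} is empty")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    flat = np.concatenate(arrays)
    if np.unique(flat).size == 1:
        omnibus_p = 1.0  # no variation anywhere; KW statistic undefined
    else:
        _, omnibus_p = stats.kruskal(*arrays)
    result = RankTestResult(omnibus_p=float(omnibus_p), performed_posthoc=bool(omnibus_p < alpha))
    if result.performed_posthoc:
        names = list(groups)
        for a, b in combinations(names, 2):
            result.pairwise[(a, b)] = _rank_sum_p(groups[a], groups[b])
    return result


# ---------------------------------------------------------------------------
# false-positive audit


def false_positive_report(scores, labels: pd.DataFrame, op) -> pd.DataFrame:
    """Controls called positive at an operating point, sorted by descending score."""
    series = scores.scores if hasattr(scores, "scores") else pd.Series(scores)
    control_ids = [s for s in series.index if labels.loc[s, "label"] == "control"]
    rows = []
    for sample_id in control_ids:
        score = float(series[sample_id])
        if op.is_positive(score):
            rows.append({"sample_id": sample_id, "score": score,
                         "margin": score - op.threshold})
    frame = pd.DataFrame(rows, columns=["sample_id", "score", "margin"])
    frame = frame.sort_values(["score", "sample_id"], ascending=[False, True], kind="stable")
    frame = frame.reset_index(drop=True)
    if len(frame) != op.n_control_positive and len(control_ids) == op.n_controls:
        raise EvaluationError(
            f"audit count {len(frame)} disagrees with operating point "
            f"({op.n_control_positive})"
        )
    return frame


# ---------------------------------------------------------------------------
# report I/O


def write_performance(rows: list[PerformanceRow], path) -> None:
    targets = sorted({t for row in rows for t in row.cells})
    header = ["model", "n_cancer"]
    for target in targets:
        tag = f"{int(round(target * 100))}"
        header += [f"k_{tag}", f"sensitivity_pct_{tag}", f"ci_low_{tag}", f"ci_high_{tag}"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fields = [row.model, str(row.n_cancer)]
            for target in targets:
                cell = row.cells[target]
                fields += [str(cell.k_detected), str(cell.sensitivity_pct),
                           str(cell.ci_low_pct), str(cell.ci_high_pct)]
            fh.write("\t".join(fields) + "\n")


def format_performance_table(rows: list[PerformanceRow]) -> str:
    """Markdown report with one row per model and one block per operating point."""
    targets = sorted({t for row in rows for t in row.cells})
    head = "| Model | n |"
    rule = "|---|---|"
    for target in targets:
        head += f" k@{target:.0%} | Sens% | 95% CI |"
        rule += "---|---|---|"
    lines = [head, rule]
    for row in rows:
        line = f"| {row.model} | {row.n_cancer} |"
        for target in targets:
            cell = row.cells[target]
            line += (f" {cell.k_detected} | {cell.sensitivity_pct} | "
                     f"{cell.ci_low_pct}, {cell.ci_high_pct} |")
        lines.append(line)
    return "\n".join(lines) + "\n"
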