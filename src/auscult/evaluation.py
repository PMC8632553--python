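"""Group assignment, ROC/AUC separation and classification metrics.

Examinations are crossed into four study groups — asthma diagnosis (A/N) by
presence of physician-verified abnormal sounds (A/N) — and each of the seven
indexes is scored by how well it separates the clinically meaningful pairs
(AA vs AN, AN vs NN, AA vs NA, NA vs NN; cross comparisons are excluded).
AUC is the normalized Mann-Whitney U statistic: concordant pairs get full
credit, ties half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import INDEX_NAMES, DataError

#: Pairwise comparisons reported, in canonical order (positive group first).
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("AA", "AN"),
    ("AN", "NN"),
    ("AA", "NA"),
    ("NA", "NN"),
)


@dataclass(frozen=True)
class ExamGroup:
    exam_id: str
    asthma: bool
    abnormal_sounds: bool
    group: str = field(init=False)

    def __post_init__(self) -> None:
        tag = ("A" if self.asthma else "N") + ("A" if self.abnormal_sounds else "N")
        object.__setattr__(self, "group", tag)


def assign_group(asthma: bool, abnormal_sounds: bool, exam_id: str = "exam") -> ExamGroup:
    """Map (asthma, abnormal sounds) to the AA/AN/NA/NN study group."""
    if asthma is None or abnormal_sounds is None:
        raise DataError("both asthma and abnormal_sounds flags are required")
    return ExamGroup(exam_id, bool(asthma), bool(abnormal_sounds))


def compute_auc(scores_positive, scores_negative) -> float:
    """AUC = P(positive score > negative score) + 0.5 P(tie).

    Computed via midranks, which is exactly the normalized Mann-Whitney U with
    half credit for ties.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass
class ROCAnalysis:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    chosen_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    if uniq.size == 1:
        return uniq  # degenerate: the single score is the only candidate
    return (uniq[:-1] + uniq[1:]) / 2.0


def classification_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with score >= threshold positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise DataError("empty input")
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / scores.size
    return sens, spec, acc


def select_balanced_threshold(scores, binary_labels) -> float:
    """Threshold balancing sensitivity and specificity.

    Candidates are midpoints between adjacent sorted unique scores; the
    returned candidate minimizes |sensitivity - specificity|, ties broken by
    higher Youden's J (sens + spec - 1), then by the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=bool)
    if not labels.any() or labels.all():
        raise DataError("both classes must be present to select a threshold")
    best = None
    for thr in _candidate_thresholds(scores):
        sens, spec, _ = classification_metrics(scores, labels, thr)
        key = (abs(sens - spec), -(sens + spec - 1), thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return float(best[1])


def roc_analysis(scores_positive, scores_negative) -> ROCAnalysis:
    """Full ROC summary for one group pair: AUC, curve, balanced operating point."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    auc = compute_auc(pos, neg)
    thresholds = np.concatenate(
        [[np.inf], np.unique(scores)[::-1]]
    )
    tpr = np.array([np.mean(pos >= t) if pos.size else 0.0 for t in thresholds])
    fpr = np.array([np.mean(neg >= t) if neg.size else 0.0 for t in thresholds])
    thr = select_balanced_threshold(scores, labels)
    sens, spec, acc = classification_metrics(scores, labels, thr)
    return ROCAnalysis(auc, fpr, tpr, thresholds, thr, sens, spec, acc)


# ---------------------------------------------------------------------------
# table-level reports
# ---------------------------------------------------------------------------

def _check_table(index_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INDEX_NAMES if c not in index_table.columns]
    if missing:
        raise DataError(f"index table lacks columns: {missing}")
    if "group" not in index_table.columns:
        if not {"asthma", "abnormal"} <= set(index_table.columns):
            raise DataError("index table needs a 'group' column or asthma/abnormal flags")
        index_table = index_table.copy()
        index_table["group"] = [
            assign_group(a, b).group
            for a, b in zip(index_table["asthma"], index_table["abnormal"])
        ]
    return index_table


def group_statistics(index_table: pd.DataFrame) -> pd.DataFrame:
    """Population mean and SD of each index within each study group.

    Returns a frame indexed by index name with ``<group>_mean`` and
    ``<group>_sd`` columns; empty groups yield NaN cells.
    """
    table = _check_table(index_table)
    out: dict[str, list[float]] = {}
    for group in ("AA", "AN", "NA", "NN"):
        sub = table[table["group"] == group]
        if sub.empty:
            warnings.warn(f"group {group} absent; statistics flagged NaN", stacklevel=2)
            out[f"{group}_mean"] = [np.nan] * len(INDEX_NAMES)
            out[f"{group}_sd"] = [np.nan] * len(INDEX_NAMES)
            continue
        out[f"{group}_mean"] = [float(sub[n].mean()) for n in INDEX_NAMES]
        out[f"{group}_sd"] = [float(sub[n].std(ddof=0)) for n in INDEX_NAMES]
    return pd.DataFrame(out, index=list(INDEX_NAMES))


def pairwise_auc_table(index_table: pd.DataFrame) -> pd.DataFrame:
    """AUC of every index for each of the four group comparisons.

    Rows are index names, columns ``"AA_vs_AN"`` etc.; the first-listed group
    is the positive class, so AUC < 0.5 indicates reversed correlation.
    """
    table = _check_table(index_table)
    out: dict[str, list[float]] = {}
    for g_pos, g_neg in COMPARISONS:
        col = f"{g_pos}_vs_{g_neg}"
        pos = table[table["group"] == g_pos]
        neg = table[table["group"] == g_neg]
        if pos.empty or neg.empty:
            warnings.warn(f"comparison {col} skipped: a group is empty", stacklevel=2)
            out[col] = [np.nan] * len(INDEX_NAMES)
            continue
        out[col] = [compute_auc(pos[n].to_numpy(), neg[n].to_numpy()) for n in INDEX_NAMES]
    return pd.DataFrame(out, index=list(INDEX_NAMES))


def balanced_metrics_table(index_table: pd.DataFrame) -> pd.DataFrame:
    """Balanced-threshold sensitivity/specificity/accuracy per comparison x index."""
    table = _check_table(index_table)
    rows = []
    for g_pos, g_neg in COMPARISONS:
        pos = table[table["group"] == g_pos]
        neg = table[table["group"] == g_neg]
        if pos.empty or neg.empty:
            continue
        for name in INDEX_NAMES:
            analysis = roc_analysis(pos[name].to_numpy(), neg[name].to_numpy())
            rows.append(
                {
                    "comparison": f"{g_pos}_vs_{g_neg}",
                    "index": name,
                    "threshold": analysis.chosen_threshold,
                    "sensitivity": analysis.sensitivity,
                    "specificity": analysis.specificity,
                    "accuracy": analysis.accuracy,
                }
            )
    return pd.DataFrame(rows)


def reproduce_tables(index_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Recompute the three headline reports from a per-examination index table.

    The input schema is the supplementary-data layout: one row per examination
    with the seven index columns plus either a ``group`` column or
    ``asthma``/``abnormal`` flags.
    """
    return {
        "group_statistics": group_statistics(index_table),
        "pairwise_auc": pairwise_auc_table(index_table),
        "balanced_metrics": balanced_metrics_table(index_table),
    }
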