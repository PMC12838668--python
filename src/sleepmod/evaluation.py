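"""Metrics, subject-independent cross-validation and AHI stratification.

Per-stage precision/recall/F1 and the macro-F1 are computed from the 5x5
confusion matrix (rows = true, columns = predicted); Cohen's kappa is
``(p_o - p_e) / (1 - p_e)`` with the chance agreement ``p_e`` from the
marginals.  Cross-validation partitions subjects (never epochs): five test
folds cover all subjects exactly once, and within each fold 15% of the
remaining subjects form an internal validation set for early stopping.
Cohorts follow the clinical AHI severity bands: Normal < 5, Mild 5-15,
Moderate 15-30, Severe >= 30 events/hour (half-open on the right).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .io_formats import STAGES, SubjectTable

COHORTS = ("Normal", "Mild", "Moderate", "Severe")


@dataclasses.dataclass
class MetricsReport:
    """Accuracy, macro-F1, Cohen's kappa and per-class precision/recall/F1."""

    accuracy: float
    macro_f1: float
    kappa: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    confusion: np.ndarray
    included_classes: np.ndarray  # bool: classes entering the macro mean


@dataclasses.dataclass
class FoldPlan:
    """Per-fold subject assignment: disjoint train / validation / test sets."""

    folds: list[dict[str, list[str]]]
    seed: int

    def audit(self) -> dict:
        """Leakage audit: within-fold disjointness and test-set partition."""
        all_test: list[str] = []
        within_ok = True
        for fold in self.folds:
            tr, va, te = set(fold["train"]), set(fold["val"]), set(fold["test"])
            if tr & va or tr & te or va & te:
                within_ok = False
            all_test.extend(fold["test"])
        duplicates = len(all_test) != len(set(all_test))
        return {
            "within_fold_disjoint": within_ok,
            "test_sets_disjoint": not duplicates,
            "test_union_size": len(set(all_test)),
            "n_violations": int(not within_ok) + int(duplicates),
        }


@dataclasses.dataclass(frozen=True)
class CohortLabel:
    subject_id: str
    cohort: str
    ahi: float


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------


def confusion_matrix_indices(
    true_idx: np.ndarray, pred_idx: np.ndarray, n_classes: int = 5
) -> np.ndarray:
    true_idx = np.asarray(true_idx, dtype=np.int64)
    pred_idx = np.asarray(pred_idx, dtype=np.int64)
    if true_idx.size != pred_idx.size:
        raise ValueError("true and predicted label counts differ")
    if true_idx.size == 0:
        raise ValueError("empty label arrays")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true_idx, pred_idx), 1)
    return cm


def confusion_matrix(
    true_labels: Sequence[str], pred_labels: Sequence[str], normalize: bool = False
) -> np.ndarray:
    """5x5 confusion counts; cell (i, j) = true class i predicted as j.

    ``normalize=True`` divides each row by its total (rows with no examples
    stay zero).
    """
    true_idx = np.array([STAGES.index(s) for s in true_labels])
    pred_idx = np.array([STAGES.index(s) for s in pred_labels])
    cm = confusion_matrix_indices(true_idx, pred_idx, n_classes=len(STAGES))
    if normalize:
        totals = cm.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, cm / totals, 0.0)
        return out
    return cm


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy, per-class P/R/F1, macro-F1 and Cohen's kappa from counts.

    Classes with neither true nor predicted instances are excluded from the
    macro mean (their F1 is reported as 0), so small runs that miss a stage
    remain well-defined; with all stages present the macro mean runs over
    all 5.  Degenerate marginals (p_e = 1) yield kappa 0 with a warning.
    """
    cm = np.asarray(cm)
    if np.any(cm < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)  # true counts
    col = cm.sum(axis=0).astype(float)  # predicted counts
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    included = (row > 0) | (col > 0)
    accuracy = float(tp.sum() / total)
    macro_f1 = float(f1[included].mean()) if included.any() else 0.0
    p_o = accuracy
    p_e = float((row * col).sum() / total**2)
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); reporting kappa = 0")
        kappa = 0.0
    else:
        kappa = float((p_o - p_e) / (1.0 - p_e))
    return MetricsReport(
        accuracy=accuracy,
        macro_f1=macro_f1,
        kappa=kappa,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        confusion=cm,
        included_classes=included,
    )


def metrics_from_labels(
    true_labels: Sequence[str], pred_labels: Sequence[str]
) -> MetricsReport:
    return compute_metrics(confusion_matrix(true_labels, pred_labels))


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def subject_folds(
    subjects: Sequence[str],
    k: int = 5,
    val_frac: float = 0.15,
    seed: int = 0,
    cohorts: dict[str, str] | None = None,
) -> FoldPlan:
    """Subject-independent k-fold plan with nested validation split.

    Test sets partition the subjects across folds; within each fold,
    ``val_frac`` of the remaining subjects (at least one) are held out as
    the internal validation set — stratified by cohort when a
    subject -> cohort mapping is provided — and the rest train.
    Deterministic given the seed.
    """
    subjects = list(subjects)
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(subjects, dtype=object)[rng.permutation(len(subjects))])
    fold_tests = [list(order[i::k]) for i in range(k)]
    folds = []
    for i in range(k):
        test = sorted(fold_tests[i])
        rest = [s for s in order if s not in set(test)]
        n_val = max(1, int(round(val_frac * len(rest))))
        if cohorts:
            # round-robin within cohorts for a stratified validation draw
            by_cohort: dict[str, list[str]] = {}
            for s in rest:
                by_cohort.setdefault(cohorts.get(s, "?"), []).append(s)
            val: list[str] = []
            groups = sorted(by_cohort.values(), key=len, reverse=True)
            gi = 0
            while len(val) < n_val and any(groups):
                group = groups[gi % len(groups)]
                if group:
                    val.append(group.pop(0))
                gi += 1
        else:
            val = rest[:n_val]
        val_set = set(val)
        train = [s for s in rest if s not in val_set]
        folds.append({"train": sorted(train), "val": sorted(val), "test": test})
    return FoldPlan(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# AHI stratification
# ---------------------------------------------------------------------------


def cohort_of_ahi(ahi: float) -> str:
    """Severity cohort of an AHI value (events/hour, half-open bands)."""
    if not np.isfinite(ahi) or ahi < 0:
        raise ValueError(f"AHI must be finite and >= 0, got {ahi}")
    if ahi < 5:
        return "Normal"
    if ahi < 15:
        return "Mild"
    if ahi < 30:
        return "Moderate"
    return "Severe"


def stratify_by_ahi(table: SubjectTable) -> list[CohortLabel]:
    """Assign every subject its AHI severity cohort."""
    out = []
    for _, row in table.frame.iterrows():
        ahi = float(row["ahi"])
        out.append(
            CohortLabel(
                subject_id=str(row["subject_id"]),
                cohort=cohort_of_ahi(ahi),
                ahi=ahi,
            )
        )
    return out
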