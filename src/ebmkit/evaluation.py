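"""Evaluation of the reduced feature set and the fitted staging.

Three complementary checks: (1) a gradient-boosted-tree classification
report on the selected features (precision/recall/F1 via 5-fold CV), with an
ordinal accuracy that credits near-miss predictions on ordered outcomes via
the distance-penalty reward R(i,j) = 1 - |i-j|/(K-1); (2) a row-normalized
confusion matrix whose mean diagonal triggers an underperformance warning
below 75%; (3) a chi-squared goodness-of-fit test of stage occupancy against
a uniform null, stratified jointly by subtype and clinical outcome, asking
whether staging separates outcomes beyond chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy import stats
from sklearn.metrics import classification_report as _sk_report
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .readiness import Cohort

__all__ = [
    "EvalReport",
    "reward_matrix",
    "ordinal_accuracy",
    "normalized_confusion",
    "classification_report",
    "chi2_stage_separation",
]

#: mean normalized-confusion diagonal below which a warning fires
CONFUSION_WARNING_THRESHOLD = 0.75


@dataclass
class EvalReport:
    """Bundle of classification and staging diagnostics."""

    report: pd.DataFrame
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    class_order: list[str]
    ordinal_accuracy: float | None
    diagonal_mean: float
    low_accuracy_warning: bool
    chi2: pd.DataFrame | None = None
    warnings_: list[str] = field(default_factory=list)


def reward_matrix(n_classes: int) -> np.ndarray:
    """Distance-penalty reward R(i,j) = 1 - |i-j|/(n_classes-1).

    Exact matches earn 1, the farthest misclassification earns 0, and
    intermediate misses earn fractional credit proportional to ordinal
    closeness.
    """
    if n_classes < 2:
        raise ValueError(f"reward matrix needs at least 2 classes, got {n_classes}")
    idx = np.arange(n_classes)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (n_classes - 1)


def ordinal_accuracy(C: np.ndarray, R: np.ndarray | None = None) -> float:
    """(1/N) * sum_ij R(i,j) * C(i,j) over a raw-count confusion matrix C."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    n = C.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    if R is None:
        R = reward_matrix(C.shape[0])
    return float((R * C).sum() / n)


def normalized_confusion(
    C: np.ndarray,
) -> tuple[np.ndarray, float, bool, list[str]]:
    """Row-normalize a confusion matrix and check the 75% diagonal rule.

    Returns the normalized matrix, the mean diagonal (per-class recall
    averaged over non-empty classes), whether the underperformance warning
    fires (mean diagonal strictly below 0.75), and any notes about empty
    classes.
    """
    C = np.asarray(C, dtype=float)
    row_sums = C.sum(axis=1)
    notes = []
    empty = row_sums == 0
    if empty.any():
        notes.append(
            f"class(es) {list(np.flatnonzero(empty))} have no samples and are "
            "excluded from the diagonal mean"
        )
    norm = np.divide(C, row_sums[:, None], out=np.zeros_like(C),
                     where=row_sums[:, None] > 0)
    diag = np.diag(norm)[~empty]
    diag_mean = float(diag.mean()) if diag.size else float("nan")
    warn = bool(diag_mean < CONFUSION_WARNING_THRESHOLD)
    return norm, diag_mean, warn, notes


def classification_report(
    cohort: Cohort, seed: int = 42, n_folds: int = 5
) -> EvalReport:
    """5-fold CV gradient-boosted-tree report on the (reduced) feature set.

    Out-of-fold predictions feed per-class precision/recall/F1, the ordinal
    accuracy (classes arranged by the cohort's outcome order) and the
    normalized confusion matrix with its 75% mean-diagonal warning.  Fold
    ``i`` seeds its classifier with ``seed + i``.
    """
    X = cohort.X.to_numpy(dtype=float)
    y = cohort.outcomes.to_numpy()
    classes = cohort.ordered_outcomes()
    if len(classes) < 2:
        raise ValueError("classification report needs at least two classes")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = LGBMClassifier(
            n_estimators=200, max_depth=6, random_state=seed + fold,
            n_jobs=1, verbose=-1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[tr], y[tr])
            y_pred[te] = clf.predict(X[te])
    rep = _sk_report(y, y_pred.astype(str), labels=classes,
                     output_dict=True, zero_division=0)
    report_frame = pd.DataFrame(rep).T
    C = confusion_matrix(y, y_pred.astype(str), labels=classes)
    notes: list[str] = []
    ordinal: float | None
    if len(classes) >= 3 and cohort.outcome_order is None:
        ordinal = None
        notes.append(
            "ordinal accuracy skipped: no explicit outcome order was supplied "
            "for a 3+ class cohort"
        )
        warnings.warn(notes[-1], stacklevel=2)
    else:
        ordinal = ordinal_accuracy(C)
    norm, diag_mean, warn, conf_notes = normalized_confusion(C)
    if warn:
        notes.append(
            f"mean per-class classification rate {diag_mean:.3f} is below "
            f"{CONFUSION_WARNING_THRESHOLD:.0%}: classification on the reduced "
            "feature set may be unreliable"
        )
    return EvalReport(
        report=report_frame, confusion=C, confusion_normalized=norm,
        class_order=classes, ordinal_accuracy=ordinal,
        diagonal_mean=diag_mean, low_accuracy_warning=warn,
        warnings_=notes + conf_notes,
    )


def chi2_stage_separation(assignments: pd.DataFrame) -> pd.DataFrame:
    """Chi-squared goodness-of-fit of stage occupancy per (subtype, outcome).

    Within each stratum the null is uniform occupancy over the stages that
    the stratum's subtype occupies anywhere; dof = occupied stages - 1.
    Strata with fewer than two occupied stages are skipped with a note, and
    strata whose expected cell count falls below 1 are flagged unreliable.
    Expects columns ``Subtype``, ``Outcome`` and ``Stage``.
    """
    rows = []
    for subtype, sub_grp in assignments.groupby("Subtype"):
        occupied = np.sort(sub_grp["Stage"].unique())
        for outcome, grp in sub_grp.groupby("Outcome"):
            n = len(grp)
            observed = np.array(
                [(grp["Stage"] == s).sum() for s in occupied], dtype=float
            )
            if len(occupied) < 2:
                rows.append({
                    "Subtype": subtype, "Outcome": outcome, "N": n,
                    "Stages": len(occupied), "Statistic": np.nan,
                    "DoF": 0, "PValue": np.nan,
                    "Note": "skipped: fewer than 2 occupied stages",
                })
                continue
            expected = np.full(len(occupied), n / len(occupied))
            stat, p = stats.chisquare(observed, expected)
            note = "expected count < 1; unreliable" if expected[0] < 1 else ""
            rows.append({
                "Subtype": subtype, "Outcome": outcome, "N": n,
                "Stages": len(occupied), "Statistic": float(stat),
                "DoF": len(occupied) - 1, "PValue": float(p), "Note": note,
            })
    return pd.DataFrame(rows)
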