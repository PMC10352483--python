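"""ROC diagnostics for single-protein and protein-pair EV biomarkers.

Scores are sample-level: normalized expression for single proteins, and for
pairs either the per-sample CPM of the co-expression pair (default — it
uses the assay's own combination statistic) or an in-sample logistic
composite of the two single-protein expressions. AUC is computed as the
tie-corrected Mann-Whitney concordance U/(n1 n2), which equals the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combinations import CombinationTable, combination_frame, pair_key
from .expression import ExpressionSet


@dataclass
class ROCResult:
    marker: str
    scores: pd.Series             # per sample (case-high orientation)
    labels: pd.Series             # sample -> group
    case_label: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    flipped: bool                 # True if scores were negated so AUC >= 0.5


def auc_concordance(case_scores, control_scores) -> float:
    """P(case score > control score) + 0.5 P(tie), by pair counting."""
    x = np.asarray(case_scores, dtype=float)[:, None]
    y = np.asarray(control_scores, dtype=float)[None, :]
    return float(((x > y).sum() + 0.5 * (x == y).sum()) / (x.size * y.size))


def roc_points(scores: np.ndarray, is_case: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC curve over all distinct score thresholds.

    A sample is called positive when score >= threshold. Returns
    (thresholds, sensitivity, specificity) from the all-positive to the
    all-negative end.
    """
    order = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], order])  # inf = all-negative call
    n1 = int(is_case.sum())
    n0 = is_case.size - n1
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called = scores >= t
        sens[i] = (called & is_case).sum() / n1
        spec[i] = (~called & ~is_case).sum() / n0
    return thresholds, sens, spec


def auc_trapezoid(sensitivity: np.ndarray, specificity: np.ndarray) -> float:
    """Area under the ROC polygon by the trapezoidal rule."""
    fpr = 1.0 - specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(sensitivity[order], fpr[order]))


def _roc_from_scores(scores: pd.Series, labels: pd.Series, case_label: str,
                     marker: str) -> ROCResult:
    is_case = (labels.loc[scores.index] == case_label).to_numpy()
    if not is_case.any() or is_case.all():
        raise ValueError("both groups must be nonempty")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        warnings.warn(f"{marker}: constant scores, AUC = 0.5")
    auc = auc_concordance(vals[is_case], vals[~is_case])
    flipped = auc < 0.5
    if flipped:
        vals = -vals
        auc = 1.0 - auc
    thresholds, sens, spec = roc_points(vals, is_case)
    return ROCResult(marker=marker,
                     scores=pd.Series(vals, index=scores.index),
                     labels=labels, case_label=case_label,
                     thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc, flipped=flipped)


def roc_single(expr: ExpressionSet, protein: str,
               case_label: str) -> ROCResult:
    """ROC of one protein's normalized sample expression."""
    scores = expr.normalized.loc[protein]
    return _roc_from_scores(scores, expr.groups, case_label, protein)


def roc_pair(protein_a: str, protein_b: str, case_label: str,
             tables: list[CombinationTable] | None = None,
             expr: ExpressionSet | None = None,
             groups: pd.Series | None = None,
             mode: str = "coexpression") -> ROCResult:
    """ROC of a two-protein marker.

    mode "coexpression": score = the sample's CPM of the (A, B) pair
    (requires ``tables`` and ``groups``). mode "logistic": score = the
    in-sample logistic composite of the two normalized expressions
    (requires ``expr``). Apparent (resubstitution) performance in both
    modes.
    """
    a, b = pair_key(protein_a, protein_b)
    name = f"{a}+{b}"
    if mode == "coexpression":
        if tables is None or groups is None:
            raise ValueError("coexpression mode needs tables and groups")
        frame = combination_frame(tables, use_cpm=True)
        if name not in frame.index:
            raise ValueError(f"pair {name} absent in all samples")
        return _roc_from_scores(frame.loc[name], groups, case_label, name)
    if mode == "logistic":
        if expr is None:
            raise ValueError("logistic mode needs expr")
        from sklearn.linear_model import LogisticRegression
        X = expr.normalized.loc[[a, b]].T.to_numpy()
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0,
                                            X.std(axis=0), 1.0)
        y = (expr.groups.loc[expr.normalized.columns] == case_label
             ).to_numpy(dtype=int)
        clf = LogisticRegression(C=np.inf, max_iter=1000).fit(X, y)
        scores = pd.Series(clf.decision_function(X),
                           index=expr.normalized.columns)
        return _roc_from_scores(scores, expr.groups, case_label,
                                f"{name} (logistic)")
    raise ValueError(f"unknown mode {mode!r}")
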