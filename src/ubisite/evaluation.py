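"""Evaluation protocol for site classifiers.

Confusion-based metrics (precision, recall, F1, accuracy, MCC) at a fixed
decision threshold (0.4 by default, the deployment choice) or at a fixed
false-positive rate (5% is the conventional strict setting), ROC and
precision-recall curves with their areas, the DeLong test for the
difference of two correlated AUROCs, stratified k-fold splitting, and a
seeded random hyperparameter search maximising validation MCC.

Predicted positive means score >= threshold (boundary inclusive); 0/0
metrics report 0 and are flagged degenerate instead of raising, since
threshold sweeps hit empty cells routinely.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold

DEFAULT_DT = 0.4
DEFAULT_FPR = 0.05


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Threshold-dependent metrics plus the threshold-free areas."""

    threshold: float
    confusion: Confusion
    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float
    auroc: float | None = None
    auprc: float | None = None
    degenerate: list[str] = dataclass_field(default_factory=list)


def _check_pair(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel()
    if s.shape != y.shape:
        raise ValueError(f"length mismatch: {s.shape[0]} scores vs "
                         f"{y.shape[0]} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return s, y.astype(np.int64)


def confusion_at(scores, labels, threshold: float) -> Confusion:
    """Confusion counts with the inclusive rule: positive iff score >= t."""
    s, y = _check_pair(scores, labels)
    pred = s >= threshold
    return Confusion(tp=int(np.sum(pred & (y == 1))),
                     fp=int(np.sum(pred & (y == 0))),
                     tn=int(np.sum(~pred & (y == 0))),
                     fn=int(np.sum(~pred & (y == 1))))


def compute_metrics(c: Confusion, threshold: float = DEFAULT_DT
                    ) -> MetricsReport:
    """Standard binary metrics from a confusion; 0/0 cells yield 0, flagged."""
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1")
    accuracy = (c.tp + c.tn) / c.total
    mcc_den_sq = (float(c.tp + c.fp) * (c.tp + c.fn)
                  * (c.tn + c.fp) * (c.tn + c.fn))
    if mcc_den_sq == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(mcc_den_sq)
    return MetricsReport(threshold=threshold, confusion=c,
                         precision=precision, recall=recall, f1=f1,
                         accuracy=accuracy, mcc=float(mcc),
                         degenerate=degenerate)


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr) points at every unique score (ties grouped) and the
    trapezoidal AUROC, which equals the Mann-Whitney estimate."""
    s, y = _check_pair(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, float(roc_auc_score(y, s))


def auroc(scores, labels) -> float:
    return roc_points(scores, labels)[2]


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(recall, precision) points and the step-interpolated area
    (the average-precision convention)."""
    s, y = _check_pair(scores, labels)
    if y.sum() == 0:
        raise ValueError("positives required for a precision-recall curve")
    precision, recall, _ = precision_recall_curve(y, s)
    return recall, precision, float(average_precision_score(y, s))


def auprc(scores, labels) -> float:
    return pr_points(scores, labels)[2]


@dataclass
class ThresholdResult:
    threshold: float
    achieved_fpr: float
    target_fpr: float
    unreachable: bool = False


def threshold_at_fpr(scores, labels, target_fpr: float = DEFAULT_FPR
                     ) -> ThresholdResult:
    """Smallest threshold whose achieved FPR is at most ``target_fpr``.

    Candidate thresholds are the unique scores (positive iff score >=
    threshold).  If even the highest score admits too many false
    positives, a threshold just above the maximum score is returned with
    FPR 0 and flagged unreachable.
    """
    s, y = _check_pair(scores, labels)
    if not 0 < target_fpr < 1:
        raise ValueError("target_fpr must be in (0, 1)")
    neg = s[y == 0]
    if neg.size == 0:
        raise ValueError("negatives required to control the FPR")
    for t in np.unique(s):  # ascending; FPR non-increasing in t
        fpr = float(np.mean(neg >= t))
        if fpr <= target_fpr:
            return ThresholdResult(threshold=float(t), achieved_fpr=fpr,
                                   target_fpr=target_fpr)
    above = float(np.nextafter(s.max(), np.inf))
    return ThresholdResult(threshold=above, achieved_fpr=0.0,
                           target_fpr=target_fpr, unreachable=True)


def evaluate_scores(scores, labels, threshold: float = DEFAULT_DT
                    ) -> MetricsReport:
    """Full report: thresholded metrics plus AUROC/AUPRC."""
    report = compute_metrics(confusion_at(scores, labels, threshold),
                             threshold=threshold)
    s, y = _check_pair(scores, labels)
    if len(np.unique(y)) == 2:
        report.auroc = auroc(s, y)
        report.auprc = auprc(s, y)
    return report


# ---------------------------------------------------------------------------
# DeLong test for paired AUROCs


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks of x (1-based; ties share the average rank)."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=np.float64)
    out[order] = ranks
    return out


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for the AUROC difference of two classifiers
    scored on the same samples, via midrank structural components."""
    sa, y = _check_pair(scores_a, labels)
    sb, y2 = _check_pair(scores_b, labels)
    if not np.array_equal(y, y2):
        raise ValueError("labels mismatch between score vectors")
    m = int(y.sum())
    n = int(y.size - m)
    if m == 0 or n == 0:
        raise ValueError("both classes required")

    aucs = np.empty(2)
    v01 = np.empty((2, m))  # positive-sample structural components
    v10 = np.empty((2, n))  # negative-sample structural components
    for idx, s in enumerate((sa, sb)):
        pos, neg = s[y == 1], s[y == 0]
        tx = _midranks(pos)
        ty = _midranks(neg)
        tz = _midranks(np.concatenate([pos, neg]))
        aucs[idx] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[idx] = (tz[:m] - tx) / n
        v10[idx] = 1.0 - (tz[m:] - ty) / m

    s01 = np.cov(v01) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(v10) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
        return DeLongResult(auc_a=float(aucs[0]), auc_b=float(aucs[1]),
                            delta=delta, z=float(z), p_value=p,
                            degenerate=True)
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a=float(aucs[0]), auc_b=float(aucs[1]),
                        delta=delta, z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter search


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint validation index sets with per-fold class proportions
    within one sample of the global proportions."""
    y = np.asarray(labels).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, "
                         f"fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in splitter.split(np.zeros_like(y), y)]


@dataclass
class Trial:
    params: dict[str, Any]
    value: float | None
    state: str  # "complete" | "failed"
    error: str = ""


class SearchError(RuntimeError):
    """All hyperparameter-search trials failed."""


def _sample_param(spec: Any, rng: np.random.Generator) -> Any:
    if isinstance(spec, (list, tuple)) and not (
            len(spec) == 3 and spec[0] in ("uniform", "loguniform", "int")):
        return spec[int(rng.integers(len(spec)))]
    kind, low, high = spec
    if kind == "uniform":
        return float(rng.uniform(low, high))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(low), np.log(high))))
    if kind == "int":
        return int(rng.integers(low, high + 1))
    raise ValueError(f"unsupported parameter spec {spec!r}")


def hp_search(train_fn: Callable[[dict[str, Any]], float],
              space: dict[str, Any], n_trials: int = 20, seed: int = 0
              ) -> tuple[dict[str, Any], list[Trial]]:
    """Seeded random search maximising the callback's return value.

    The callback receives one sampled parameter dict and returns the score
    to maximise (by convention, mean validation MCC over stratified
    folds).  A parameter is specified as a list of choices or a
    ``(kind, low, high)`` triple with kind "uniform", "loguniform" or
    "int".  Failed trials are logged and skipped; if every trial fails a
    :class:`SearchError` is raised.
    """
    if not space:
        raise ValueError("parameter space is empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    trials: list[Trial] = []
    best: Trial | None = None
    for _ in range(n_trials):
        params = {name: _sample_param(spec, rng)
                  for name, spec in space.items()}
        try:
            value = float(train_fn(params))
        except Exception as exc:  # noqa: BLE001 — failed trials are data
            trials.append(Trial(params=params, value=None, state="failed",
                                error=str(exc)))
            continue
        trial = Trial(params=params, value=value, state="complete")
        trials.append(trial)
        if best is None or value > best.value:
            best = trial
    if best is None:
        raise SearchError("all hyperparameter-search trials failed")
    return best.params, trials
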