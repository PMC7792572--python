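"""Median-IC50 consensus prediction and the benchmark evaluation suite.

Consensus: per peptide, the median of several methods' predicted IC50
values.  A median absorbs a single wildly wrong component, which is the
point — component methods rarely share their outliers.

Evaluation: ROC AUC (midrank ties, with an orientation flag for methods
whose scores decrease with binding), Pearson/Spearman correlations,
accuracy at the optimal classification threshold, an outlier definition
(wrong class AND absolute IC50 error above 500 nM), and a filter that
removes records whose quantitative IC50 contradicts their qualitative
binder label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import EvaluationError, InputError
from .rankic50 import BINDER_CUTOFF_NM, classify

POSITIVE_LABELS = frozenset(
    {"Positive", "Positive-Low", "Positive-Intermediate", "Positive-High"}
)
NEGATIVE_LABELS = frozenset({"Negative"})


@dataclass
class BindingRecord:
    """One benchmark entry: experimental truth plus per-method predictions."""

    allele: str
    peptide: str
    ic50_exp: float | None = None
    qual_label: str | None = None
    predictions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ic50_exp is None and self.qual_label is None:
            raise InputError("evaluation record needs ic50_exp or qual_label")
        if self.qual_label is not None and self.qual_label not in (
            POSITIVE_LABELS | NEGATIVE_LABELS
        ):
            raise InputError(f"unknown qualitative label {self.qual_label!r}")


@dataclass
class EvalReport:
    """Classification and regression metrics for one record set."""

    auc: float
    pcc: float
    srcc: float
    acc_at_ot: float
    ot: float
    fp_rate: float
    tp_rate: float
    n_pos: int
    n_neg: int


def median_consensus(
    predictions: Mapping[str, float], methods: Sequence[str]
) -> float:
    """Median of the selected methods' predicted IC50s (even count: central mean)."""
    if len(methods) < 2:
        raise InputError("consensus needs at least two methods")
    values = []
    for m in methods:
        if m not in predictions:
            raise InputError(f"missing prediction for method {m!r}")
        values.append(predictions[m])
    return float(np.median(values))


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise EvaluationError("both classes must be present")


def auc(
    scores: Sequence[float], labels: Sequence[bool], higher_is_positive: bool = True
) -> float:
    """ROC AUC with midrank tie handling.

    ``higher_is_positive=False`` flips the orientation for methods whose
    scores decrease with binding strength (energies, IC50 predictions).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    if not higher_is_positive:
        scores = -scores
    return float(roc_auc_score(labels, scores))


def correlations(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(Pearson, Spearman) correlation coefficients."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise EvaluationError("need at least 3 paired values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise EvaluationError("correlation undefined for constant input")
    pcc = float(stats.pearsonr(x, y).statistic)
    srcc = float(stats.spearmanr(x, y).statistic)
    return pcc, srcc


def optimal_threshold(
    scores: Sequence[float], labels: Sequence[bool], higher_is_positive: bool = True
) -> tuple[float, float, float, float]:
    """Accuracy-maximising decision threshold.

    Candidate thresholds are midpoints between adjacent distinct sorted
    scores plus sentinels below/above the range; predicted positive
    means score >= threshold (or <= with ``higher_is_positive=False``).
    Ties in accuracy resolve toward the lower threshold.  Returns
    (threshold, accuracy, FP/N, TP/P).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    s = scores if higher_is_positive else -scores
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    best = None
    for thr in candidates:
        pred = s >= thr
        acc = float((pred == labels).mean())
        tp = float((pred & labels).sum() / n_pos)
        fp = float((pred & ~labels).sum() / n_neg)
        key_thr = thr if higher_is_positive else -thr
        if best is None or acc > best[1] + 1e-12 or (
            abs(acc - best[1]) <= 1e-12 and key_thr < best[0]
        ):
            best = (key_thr, acc, fp, tp)
    return best


def find_outliers(
    records: Iterable[BindingRecord], method: str, cutoff: float = BINDER_CUTOFF_NM
) -> list[BindingRecord]:
    """Records where one method is both misclassified and far off.

    An outlier (i) has the wrong binder/non-binder class and (ii) an
    absolute IC50 prediction error above 500 nM.
    """
    out = []
    for rec in records:
        if rec.ic50_exp is None or method not in rec.predictions:
            raise InputError(f"record lacks ic50_exp or prediction for {method!r}")
        pred = rec.predictions[method]
        wrong_class = classify(pred, cutoff) != classify(rec.ic50_exp, cutoff)
        if wrong_class and abs(pred - rec.ic50_exp) > 500.0:
            out.append(rec)
    return out


def filter_contradicting(
    records: Iterable[BindingRecord], cutoff: float = BINDER_CUTOFF_NM
) -> list[BindingRecord]:
    """Keep records whose qualitative label agrees with the quantitative IC50.

    All Positive sublevels count as binder; agreement means
    (label positive) == (IC50 < cutoff).
    """
    kept = []
    for rec in records:
        if rec.ic50_exp is None or rec.qual_label is None:
            raise InputError("record needs both ic50_exp and qual_label")
        labelled_binder = rec.qual_label in POSITIVE_LABELS
        measured_binder = rec.ic50_exp < cutoff
        if labelled_binder == measured_binder:
            kept.append(rec)
    return kept


def evaluate_records(
    records: Sequence[BindingRecord],
    method: str,
    cutoff: float = BINDER_CUTOFF_NM,
    higher_is_positive: bool = False,
) -> EvalReport:
    """Full metric panel for one method's IC50 predictions.

    Binder truth comes from ``ic50_exp < cutoff``; predicted IC50 scores
    are oriented lower-is-binder by default.
    """
    exp = np.array([r.ic50_exp for r in records], dtype=float)
    pred = np.array([r.predictions[method] for r in records], dtype=float)
    labels = exp < cutoff
    a = auc(pred, labels, higher_is_positive=higher_is_positive)
    pcc, srcc = correlations(np.log(exp), np.log(pred))
    ot, acc, fp, tp = optimal_threshold(pred, labels, higher_is_positive=higher_is_positive)
    return EvalReport(
        auc=a, pcc=pcc, srcc=srcc, acc_at_ot=acc, ot=ot, fp_rate=fp, tp_rate=tp,
        n_pos=int(labels.sum()), n_neg=int((~labels).sum()),
    )
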