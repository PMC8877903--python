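"""Multiclass diagnostic metrics for the cascade classifier.

Implements one-vs-rest confusion decomposition (per-class TP/FP/FN/TN via
the standard complement rule), accuracy, sensitivity, specificity, F1,
Bayes-theorem positive predictive value evaluated at a stated prevalence,
Cohen's kappa, and ROC/AUC with Youden-index boundary-threshold selection.

The headline PPV is evaluated at the prevalence of the minority class
(the class with the fewest actual samples), the convention used when a
screening population is dominated by the majority rhythm:

    PPV = Sens * P / (Sens * P + (1 - Sp) * (1 - P)),   P = (TP + FN) / total

Per-class F1 uses the per-class prevalence in its PPV term.  Cohen's kappa
is (po - pe) / (1 - pe) with po the observed agreement (trace / total) and
pe the chance agreement sum_c (row_c / total) * (col_c / total).

All rates are returned as fractions in [0, 1]; undefined ratios (zero
denominators) are NaN, never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "confusion_matrix",
    "per_class_counts",
    "metrics_report",
    "roc_auc_threshold",
    "ppv_bayes",
    "cohen_kappa",
]


@dataclass
class ConfusionMatrix:
    """K x K counts indexed [predicted][actual]."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.labels = tuple(self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, label) -> int:
        return self.labels.index(label)

    def collapse(self, mapping: dict, labels: tuple) -> "ConfusionMatrix":
        """Merge classes; ``mapping`` sends each old label to a new one."""
        k = len(labels)
        out = np.zeros((k, k), dtype=int)
        for i, pl in enumerate(self.labels):
            for j, al in enumerate(self.labels):
                out[labels.index(mapping.get(pl, pl)),
                    labels.index(mapping.get(al, al))] += self.counts[i, j]
        return ConfusionMatrix(out, labels)


def confusion_matrix(y_true, y_pred, labels) -> ConfusionMatrix:
    """Tally counts[p][a] = #{i : pred_i = p, true_i = a}."""
    labels = tuple(labels)
    lut = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            raise ValueError(f"label {t!r}/{p!r} outside {labels}")
        counts[lut[p], lut[t]] += 1
    return ConfusionMatrix(counts, labels)


def per_class_counts(cm: ConfusionMatrix, c) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for class ``c`` by the complement decomposition.

    TP is the diagonal entry; FP the rest of the predicted-c row; FN the
    rest of the actual-c column; TN everything else.
    """
    i = cm.index(c)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum()) - tp
    fn = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def ppv_bayes(sens: float, sp: float, prevalence: float) -> float:
    """Positive predictive value from Bayes' theorem at a given prevalence."""
    den = sens * prevalence + (1.0 - sp) * (1.0 - prevalence)
    return _ratio(sens * prevalence, den)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1) / n   # predicted marginals
    cols = cm.counts.sum(axis=0) / n   # actual marginals
    pe = float(rows @ cols)
    return _ratio(po - pe, 1.0 - pe)


@dataclass
class MetricsReport:
    """Per-class and summary metrics of one confusion matrix.

    ``per_class`` maps label -> dict with keys tp/fp/fn/tn/sens/sp/ppv/f1/
    acc/prevalence.  Macro entries are (mean, sd) pairs over classes, the
    "Mean +/- SD" reporting shape.  All rates are fractions in [0, 1].
    """

    labels: tuple
    per_class: dict
    acc_micro: float
    acc_macro: tuple
    sens_macro: tuple
    sp_macro: tuple
    ppv_macro: tuple
    f1_macro: tuple
    kappa: float
    minority_class: object
    ppv_minority: float
    po: float
    pe: float

    def as_percent(self) -> dict:
        """Summary metrics scaled to percentages."""
        return {
            "acc": 100 * self.acc_micro,
            "acc_macro": 100 * self.acc_macro[0],
            "sens": 100 * self.sens_macro[0],
            "sp": 100 * self.sp_macro[0],
            "ppv": 100 * self.ppv_minority,
            "f1": 100 * self.f1_macro[0],
            "kappa": 100 * self.kappa,
        }


def _macro(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return float("nan"), float("nan")
    return float(v.mean()), float(v.std(ddof=0))


def metrics_report(cm: ConfusionMatrix, minority_class=None) -> MetricsReport:
    """Full metric bundle for a confusion matrix.

    ``minority_class`` defaults to the class with the fewest actual samples;
    the headline PPV is evaluated at its prevalence.
    """
    n = cm.total
    if n == 0:
        raise ValueError("confusion matrix is empty")
    col_totals = cm.counts.sum(axis=0)
    if minority_class is None:
        minority_class = cm.labels[int(np.argmin(col_totals))]

    per_class = {}
    for c in cm.labels:
        tp, fp, fn, tn = per_class_counts(cm, c)
        sens = _ratio(tp, tp + fn)
        sp = _ratio(tn, tn + fp)
        prev = (tp + fn) / n
        ppv_c = ppv_bayes(sens, sp, prev)
        f1 = _ratio(2 * sens * ppv_c, sens + ppv_c)
        per_class[c] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sens": sens, "sp": sp, "ppv": ppv_c, "f1": f1,
            "acc": (tp + tn) / n, "prevalence": prev,
        }

    mc = per_class[minority_class]
    ppv_minority = ppv_bayes(mc["sens"], mc["sp"], mc["prevalence"])
    po = float(np.trace(cm.counts) / n)
    rows = cm.counts.sum(axis=1) / n
    cols = col_totals / n
    pe = float(rows @ cols)
    return MetricsReport(
        labels=cm.labels,
        per_class=per_class,
        acc_micro=po,
        acc_macro=_macro([d["acc"] for d in per_class.values()]),
        sens_macro=_macro([d["sens"] for d in per_class.values()]),
        sp_macro=_macro([d["sp"] for d in per_class.values()]),
        ppv_macro=_macro([d["ppv"] for d in per_class.values()]),
        f1_macro=_macro([d["f1"] for d in per_class.values()]),
        kappa=cohen_kappa(cm),
        minority_class=minority_class,
        ppv_minority=ppv_minority,
        po=po,
        pe=pe,
    )


@dataclass
class RocCurve:
    """Operating points over all score thresholds plus AUC and the
    Youden-index boundary threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    chosen_threshold: float


def roc_auc_threshold(scores, truths) -> RocCurve:
    """ROC over all score thresholds for binary one-vs-rest labels.

    The curve sweeps thresholds from +inf down through every distinct
    score; AUC by the trapezoidal rule; the boundary threshold maximizes
    Youden's J = TPR - FPR (ties broken toward the higher threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truths, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative items")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # cut only between distinct scores
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cuts = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y_sorted)[cuts]
    fp = np.cumsum(~y_sorted)[cuts]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cuts]])
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax takes the first = highest threshold
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                    chosen_threshold=float(thresholds[best]))
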