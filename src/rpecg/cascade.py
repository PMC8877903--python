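"""Two-stage cascade: route windows through stage 1 and, when called
"other", re-segment around the R peak for stage 2.

Stage 1 sees the recurrence-plot image of the raw 2 s window and outputs
{noise, VF, other}.  Windows called "other" get R-peak detection on the
surrounding context (+/-2 s by default); the R-centered 2 s segment is
imaged and classified by stage 2 into {AF, normal, PAC, PVC}.  If no usable
R peak exists, the outcome is the distinct label "other-unresolved" rather
than a forced stage-2 guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ResNetClassifier
from .metrics import ConfusionMatrix, confusion_matrix
from .preprocessing import detect_r_peaks, window_samples
from .recurrence import RecurrencePlotImager
from .signal_io import EcgRecord

__all__ = ["CascadeResult", "TwoStageCascade", "predict_two_stage", "evaluate_overall"]

SIX_CLASSES = ("noise", "VF", "AF", "normal", "PAC", "PVC")
UNRESOLVED = "other-unresolved"
_SUPERCLASS = {"AF": "other", "normal": "other", "PAC": "other", "PVC": "other",
               UNRESOLVED: "other"}


@dataclass
class CascadeResult:
    final_label: str
    stage1_scores: np.ndarray
    stage2_scores: np.ndarray | None = None
    segment_id: object = None


class TwoStageCascade:
    """Cascade of two fitted :class:`ResNetClassifier` models.

    ``fit`` trains stage 1 on all segments (labels collapsed to
    {noise, VF, other}) and stage 2 on the four rhythm classes only;
    ``predict_window`` routes one 2 s window (with optional wider signal
    context for R-peak detection) through both stages.
    """

    def __init__(self, model1: ResNetClassifier, model2: ResNetClassifier,
                 imager1: RecurrencePlotImager | None = None,
                 imager2: RecurrencePlotImager | None = None):
        self.model1 = model1
        self.model2 = model2
        self.imager1 = imager1 or RecurrencePlotImager(size=model1.input_size)
        self.imager2 = imager2 or RecurrencePlotImager(size=model2.input_size)

    def fit(self, segments_by_class: dict, fs: float, seed: int = 0):
        """Train both stages from raw 1-D segments keyed by six-class label."""
        x1, y1, x2, y2 = [], [], [], []
        for label, segs in segments_by_class.items():
            sup = _SUPERCLASS.get(label, label)
            for s in segs:
                x1.append(s)
                y1.append(sup)
                if sup == "other":
                    x2.append(s)
                    y2.append(label)
        self.model1.fit(self.imager1.transform(x1), np.array(y1))
        self.model2.fit(self.imager2.transform(x2), np.array(y2))
        return self

    def predict_window(self, window: np.ndarray, fs: float,
                       context: np.ndarray | None = None,
                       window_offset: int = 0) -> CascadeResult:
        return predict_two_stage(window, fs, self.model1, self.model2,
                                 imager1=self.imager1, imager2=self.imager2,
                                 context=context, window_offset=window_offset)


def predict_two_stage(window: np.ndarray, fs: float,
                      model1: ResNetClassifier, model2: ResNetClassifier,
                      imager1: RecurrencePlotImager | None = None,
                      imager2: RecurrencePlotImager | None = None,
                      context: np.ndarray | None = None,
                      window_offset: int = 0) -> CascadeResult:
    """Route one 2 s window through the cascade.

    ``context`` is a longer excerpt containing the window, with the window
    starting at ``window_offset`` inside it; it is used for R-peak
    detection and for cutting the R-centered stage-2 segment.  Without
    context the window itself is used.
    """
    window = np.asarray(window, dtype=float)
    expect = window_samples(fs, 2.0)
    if len(window) != expect:
        raise ValueError(f"window length {len(window)} != round(2*fs) = {expect}")
    imager1 = imager1 or RecurrencePlotImager(size=model1.input_size)
    imager2 = imager2 or RecurrencePlotImager(size=model2.input_size)

    s1 = model1.predict_proba(imager1.transform([window]))[0]
    label1 = model1.classes_[int(np.argmax(s1))]
    if label1 != "other":
        return CascadeResult(final_label=str(label1), stage1_scores=s1)

    if context is None:
        context, window_offset = window, 0
    ctx_rec = EcgRecord(record_id="window", signal=context, fs=fs)
    peaks = detect_r_peaks(ctx_rec)
    one_s = round(fs)
    # prefer the peak nearest the window center with 1 s context either side
    center = window_offset + expect // 2
    usable = [p for p in peaks if p - one_s >= 0 and p + one_s <= len(context)]
    if not usable:
        return CascadeResult(final_label=UNRESOLVED, stage1_scores=s1)
    peak = min(usable, key=lambda p: abs(p - center))
    seg = context[peak - one_s:peak + one_s]
    s2 = model2.predict_proba(imager2.transform([seg]))[0]
    label2 = model2.classes_[int(np.argmax(s2))]
    return CascadeResult(final_label=str(label2), stage1_scores=s1, stage2_scores=s2)


def evaluate_overall(segments, labels, model1, model2,
                     fs: float, contexts=None, offsets=None,
                     imager1=None, imager2=None):
    """Run every labeled test segment through the cascade and tally the
    six-class confusion matrix.

    "other-unresolved" predictions are tallied as a seventh predicted
    outcome; against any truth they are misclassifications (the matrix
    keeps them in a dedicated row so they remain visible).

    Returns (ConfusionMatrix over six classes + unresolved row, results).
    """
    labels = list(labels)
    present = [c for c in SIX_CLASSES if c in set(labels)]
    if len(present) < len(SIX_CLASSES):
        import warnings
        missing = sorted(set(SIX_CLASSES) - set(present))
        warnings.warn(f"classes absent from the test set: {missing}")
    results = []
    for i, seg in enumerate(segments):
        ctx = contexts[i] if contexts is not None else None
        off = offsets[i] if offsets is not None else 0
        results.append(predict_two_stage(seg, fs, model1, model2,
                                         imager1=imager1, imager2=imager2,
                                         context=ctx, window_offset=off))
    preds = [r.final_label for r in results]
    observed = set(labels) | set(preds)
    all_labels = tuple(
        [l for l in SIX_CLASSES if l in observed]
        + sorted(observed - set(SIX_CLASSES) - {UNRESOLVED})
        + ([UNRESOLVED] if UNRESOLVED in observed else [])
    )
    cm = confusion_matrix(labels, preds, labels=all_labels)
    return cm, results


def superclass_matrix(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse {AF, normal, PAC, PVC, other-unresolved} -> other."""
    keep = tuple(dict.fromkeys(_SUPERCLASS.get(l, l) for l in cm.labels))
    return cm.collapse(_SUPERCLASS, keep)
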