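"""Desk-scale benchmark experiments on fully synthetic data.

These harnesses reproduce the pipeline's behavior at CPU-friendly problem
sizes: six synthetic classes, recurrence-plot images at 96x96, a standard
ResNet-18 for stage 1 and a width-reduced (base 16) ResNet-18 for stage 2,
trained for a handful of epochs.  They are used by the acceptance script
and the acceptance test suite, and are importable for interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import SIX_CLASSES, UNRESOLVED, evaluate_overall, superclass_matrix
from .estimators import ResNetClassifier
from .metrics import metrics_report
from .preprocessing import detect_r_peaks, segment_stage1, segment_stage2, window_samples
from .recurrence import RecurrencePlotImager
from .synthetic_ecg import SynthConfig, generate_record
from .training import split_data

__all__ = ["make_windows", "rpeak_benchmark", "run_cascade_experiment", "CascadeOutcome"]


def make_windows(n_per_class: int, fs: float = 250.0, seed: int = 0,
                 classes=SIX_CLASSES, context_s: float = 2.0,
                 record_duration_s: float = 14.0):
    """Build labeled 2 s windows with surrounding signal context.

    noise and VF windows tile their records (stage-1 segmentation); the
    four rhythm classes are R-peak-centered segments produced by the
    package's own detector and central-beat labeling rule, keeping only
    segments whose central beat carries the class of interest (a PAC
    record also yields normal segments, which are discarded here so every
    class bucket is pure).

    Returns dict label -> list of (window, context, offset_in_context);
    the context extends ``context_s`` seconds beyond the window on each
    side (clipped at record edges) for downstream R-peak work.
    """
    out = {}
    win = window_samples(fs, 2.0)
    ctx = round(context_s * fs)
    for ci, label in enumerate(classes):
        items = []
        rec_seed = 1_000_003 * (seed + 1) + 10_000 * ci  # distinct per class
        while len(items) < n_per_class:
            rec = generate_record(SynthConfig(
                class_label=label, duration_s=record_duration_s, fs=fs,
                mean_hr_bpm=70.0, seed=rec_seed % (2**31),
            ))
            rec_seed += 1
            if label in ("noise", "VF"):
                segs = segment_stage1(rec)
            else:
                segs = [s for s in segment_stage2(rec, detect_r_peaks(rec))
                        if s.label == label]
            x = rec.lead
            for s in segs:
                lo = max(0, s.start_sample - ctx)
                hi = min(len(x), s.start_sample + win + ctx)
                items.append((s.samples, x[lo:hi], s.start_sample - lo))
                if len(items) >= n_per_class:
                    break
        out[label] = items
    return out


def rpeak_benchmark(n_records: int = 20, fs: float = 250.0, noise_sd: float = 0.05,
                    seed: int = 0, tol_s: float = 0.040):
    """Pooled R-peak detection sensitivity and positive predictivity on
    annotated synthetic records of the beat-bearing classes."""
    tp = fn = fp = 0
    classes = ("normal", "AF", "PAC", "PVC")
    for i in range(n_records):
        label = classes[i % len(classes)]
        rec = generate_record(SynthConfig(
            class_label=label, duration_s=30.0, fs=fs, mean_hr_bpm=70.0,
            noise_sd=noise_sd, seed=(7_919 * (seed + 1) + i) % (2**31),
        ))
        det = np.asarray(detect_r_peaks(rec))
        truth = np.asarray([s for s, _ in rec.beat_annotations])
        tol = round(tol_s * fs)
        for t in truth:
            if len(det) and np.min(np.abs(det - t)) <= tol:
                tp += 1
            else:
                fn += 1
        for d in det:
            if not (len(truth) and np.min(np.abs(truth - d)) <= tol):
                fp += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return {"sensitivity": sens, "ppv": ppv, "n_beats": tp + fn}


_SUPER = {"AF": "other", "normal": "other", "PAC": "other", "PVC": "other"}


@dataclass
class CascadeOutcome:
    """Results of one scaled-down end-to-end run."""

    six_class_cm: object
    super_cm: object
    report: object
    macro_f1: float
    six_class_accuracy: float
    superclass_accuracy: float
    stage1_history: dict
    stage2_history: dict
    n_train: int
    n_test: int


def run_cascade_experiment(seed: int = 0, n_per_class: int = 200,
                           fs: float = 250.0, image_size: int = 96,
                           epochs1: int = 5, epochs2: int = 10,
                           batch_size: int = 32,
                           stage2_base_width: int = 16) -> CascadeOutcome:
    """Train the two-stage cascade on synthetic data and evaluate it on the
    held-out test split.

    Splits each class 70/15/15 into train/validation/test.  Stage 1 trains
    on all training windows with superclass labels {noise, VF, other};
    stage 2 trains on R-peak-centered 2 s segments cut from the training
    windows of the four rhythm classes.  Evaluation routes raw test
    windows through the full cascade (stage-1 image, R-peak detection on
    context, stage-2 image).
    """
    data = make_windows(n_per_class, fs=fs, seed=seed)
    imager = RecurrencePlotImager(size=image_size)
    # linear lr-batch scaling of the protocol's 0.1-at-256 learning rate
    lr = 0.1 * batch_size / 256.0

    splits = {label: split_data(range(len(items)), seed=seed + 101 * ci)
              for ci, (label, items) in enumerate(data.items())}

    def collect(part):
        segs, ctxs, offs, labels = [], [], [], []
        for label, items in data.items():
            for i in getattr(splits[label], part):
                w, c, o = items[i]
                segs.append(w)
                ctxs.append(c)
                offs.append(o)
                labels.append(label)
        return segs, ctxs, offs, labels

    tr_segs, tr_ctxs, tr_offs, tr_labels = collect("train_ids")
    va_segs, _, _, va_labels = collect("val_ids")
    te_segs, te_ctxs, te_offs, te_labels = collect("test_ids")

    # ---- stage 1: superclass labels on raw windows
    y1_tr = np.array([_SUPER.get(l, l) for l in tr_labels])
    y1_va = np.array([_SUPER.get(l, l) for l in va_labels])
    model1 = ResNetClassifier(depth=18, input_size=image_size, epochs=epochs1,
                              batch_size=batch_size, lr=lr, augment=False, seed=seed)
    model1.fit(imager.transform(tr_segs), y1_tr,
               X_val=imager.transform(va_segs), y_val=y1_va)

    # ---- stage 2: the rhythm-class training windows are R-peak-centered
    # segments labeled by their central beat, exactly what stage 2 consumes
    x2_tr = [w for w, l in zip(tr_segs, tr_labels) if l in _SUPER]
    y2_tr = np.array([l for l in tr_labels if l in _SUPER])
    x2_va = [w for w, l in zip(va_segs, va_labels) if l in _SUPER]
    y2_va = np.array([l for l in va_labels if l in _SUPER])
    model2 = ResNetClassifier(depth=18, base_width=stage2_base_width,
                              input_size=image_size, epochs=epochs2,
                              batch_size=batch_size, lr=lr, augment=False,
                              seed=seed + 1)
    model2.fit(imager.transform(x2_tr), y2_tr,
               X_val=imager.transform(x2_va), y_val=y2_va)

    # ---- overall six-class evaluation through the cascade
    cm, _ = evaluate_overall(te_segs, te_labels, model1, model2, fs=fs,
                             contexts=te_ctxs, offsets=te_offs,
                             imager1=imager, imager2=imager)
    report = metrics_report(cm, minority_class=None)
    six_labels = [l for l in cm.labels if l != UNRESOLVED]
    f1s = [report.per_class[l]["f1"] for l in six_labels]
    macro_f1 = float(np.nanmean(f1s))
    super_cm = superclass_matrix(cm)
    six_acc = float(np.trace(cm.counts) / cm.total)
    super_acc = float(np.trace(super_cm.counts) / super_cm.total)
    return CascadeOutcome(
        six_class_cm=cm, super_cm=super_cm, report=report, macro_f1=macro_f1,
        six_class_accuracy=six_acc, superclass_accuracy=super_acc,
        stage1_history=model1.history_, stage2_history=model2.history_,
        n_train=len(tr_segs), n_test=len(te_segs),
    )
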