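# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rpecg`. Empirical figures quoted here are the ones the test
suite and `scripts/acceptance.py` themselves compute; nothing else is
claimed.

## Recurrence-plot transform

Segments are mapped to N×N matrices of pairwise state distances
D_ij = ‖x_i − x_j‖ (unthresholded RP). Delay embedding is available
(dimension `m`, lag `tau`, both default 1, i.e. raw samples as states):
the pipeline operates directly on 2 s segments, and with m = 1 the RP of a
one-dimensional trace already captures the rhythm and morphology cues the
classifier needs. The thresholded variant Θ(ε − D) uses the convention
Θ(0) = 1, so the identity diagonal is always recurrent.

Rendering choices, each deliberate and configurable:

* **Normalization** — per-matrix min–max to [0, 1]; a constant matrix maps
  to 0. Per-matrix scope makes rendering invariant to amplitude scaling of
  the segment (tested property), which removes inter-record gain
  differences; a fixed global range is available when absolute amplitude
  matters.
* **Colormap** — a piecewise-linear rainbow with anchors at
  0 → (0, 0, 0.5), 0.125 → (0, 0, 1), 0.375 → (0, 1, 1), 0.625 → (1, 1, 0),
  0.875 → (1, 0, 0), 1 → (0.5, 0, 0) (the classic "jet" breakpoints),
  implemented directly so no plotting library is involved and pixel output
  is bit-reproducible.
* **Resize** — bilinear, to 224×224 by default (96×96 in the desk-scale
  experiments). Bilinear is smooth, deterministic and cheap; no
  anti-aliasing filter is applied before downscaling.
* **Orientation** — row 0 is rendered at the bottom, so the identity
  diagonal runs lower-left → upper-right.

## Synthetic ECG generator

The generator exists so that every downstream stage has annotated ground
truth without clinical data. It is morphological, not dynamical: each beat
is a sum of five Gaussian bumps (P, Q, R, S, T) with fixed relative
amplitudes and offsets; a record is a beat train plus band-limited noise.

Class semantics and defaults (all overridable):

| class  | construction | key defaults |
|--------|--------------|--------------|
| normal | full P-QRS-T, RR ~ Normal, cv 0.03 | hr 70 bpm |
| AF     | P suppressed, RR i.i.d. cv 0.25 | |
| PAC    | premature (RR×0.6) narrow beats at `ectopic_rate`, then a 1.3×RR pause | rate 0.15 |
| PVC    | as PAC but QRS ≥ 2× wider, no P, deeper S | rate 0.15 |
| VF     | sinusoid with random-walk frequency in 4–7 Hz, amplitude-modulated; no beats | |
| noise  | band-limited Gaussian noise + sinusoidal baseline wander; artifact annotation covers the record | sd 0.45 mV |

Additive sensor noise defaults to 0.02 mV (0.05 mV in the detector
benchmark). RR draws are truncated to [0.3, 2.0]× the mean so annotations
stay physiological. One `numpy` Generator seeded from `seed` drives every
draw, giving bit-exact reproducibility.

What the generator does **not** emulate: multi-lead morphology, baseline
wander during beats, muscle artifact bursts inside otherwise-clean rhythm,
P-wave variability, fusion beats, atrial flutter, paced rhythms, or
realistic VF onset/offset transitions. Passing tests on this data shows the
pipeline's machinery is correct and that the six idealized classes are
separable in RP space; it does not certify clinical performance.

## Segmentation and labeling

* 2 s windows: `round(fs × 2)` samples — 720 at 360 Hz, 500 at 250 Hz.
* Stage 1 tiles records without overlap (stride = window; both
  configurable) and labels a window only when one category (VF from rhythm
  intervals, noise from artifact intervals, otherwise "other") covers at
  least 2/3 of its samples; windows with no two-thirds majority are
  discarded rather than labeled by plurality.
* Stage 2 cuts `[peak − fs, peak + fs)` around each detected R peak with at
  least 1 s of context on both sides, and labels by the beat annotation
  nearest the central peak within ±75 ms (a standard beat-matching window).
  An AF rhythm interval overrides beat symbols, because AF labels are
  rhythm-level in the source databases. Labels map N/L/R → normal,
  A/a/S → PAC, V → PVC; anything else is the sentinel `unmapped` and the
  segment is dropped.

## R-peak detection

Pan–Tompkins-style: Butterworth band-pass 5–15 Hz (order 2, zero-phase) →
derivative → squaring → 150 ms moving-window integration → adaptive
threshold at noise + 0.25·(signal − noise) with exponentially updated
signal/noise levels and a 200 ms refractory period; detections are refined
to the local absolute maximum of the raw trace within ±50 ms. The threshold
is a fraction of a running amplitude estimate, so detection is invariant to
positive rescaling of the input (tested). On the synthetic benchmark (20
records, four beat-bearing classes, noise 0.05 mV) pooled sensitivity and
positive predictivity both exceed 0.99 at ±40 ms tolerance; the wide-QRS
PVC morphology is the hardest case since its energy sits at the lower edge
of the 5–15 Hz band (the band is a parameter).

## Residual networks and training

The network family is canonical: 7×7/64 stride-2 stem (padding 3), BN,
ReLU, 3×3 stride-2 max pool (padding 1), four residual stages with
stride-2 downsampling entering stages 2–4, global average pooling, and a
softmax head sized by `num_classes`. Depths 18/34 use two-3×3 basic
blocks; 50/101/152 use 1×1–3×3–1×1 bottlenecks with 4× expansion. Batch
normalization follows every convolution, before the activation. Paddings
are the ones that reproduce the 112/56/28/14/7/1 output-size schedule for
a 224×224 input. Shortcuts across shape changes default to 1×1 projection
convolutions (the standard choice for networks trained from scratch);
subsampled zero-padded identity shortcuts are selectable. `base_width`
scales all stage widths (width 16 gives the cheap stage-2 network of the
desk-scale experiments). The constructed ResNet-18 with a 3-class head has
11,178,051 trainable parameters and ResNet-50 with a 4-class head
23,516,228, counting convolution weights, fully connected weights and
biases, and BN scale/shift.

Training is SGD with momentum 0.9 and weight decay 1e-4, initial learning
rate 0.1 divided by 10 when the validation error fails to improve for
`plateau_patience` (default 5) epochs; an alternative mode divides the
rate every `lr_step_iters` iterations instead. Batch size defaults to 128
(256 selectable; the desk-scale runs use 32 so that small datasets still
produce enough updates per epoch). No dropout. Weights are He
fan-in-scaled Gaussians. Images are centered by subtracting the per-pixel
training-set mean (per-channel centering is obtainable by averaging that
mean). Augmentation: horizontal flips (p = 1/2), integer translations up
to ±16 px with edge replication, and per-channel Gaussian RGB intensity
jitter (sd 0.05), clipped back to [0, 1].

Because the engine is plain numpy, one implementation detail matters: after
short training runs the exponentially weighted BN running statistics lag
the batch statistics badly, so `train_model` re-estimates them each epoch
with a streaming pass over (up to 256 of) the training images before
computing validation error. Without this, inference-mode predictions after
a few epochs are near-random even when training accuracy is high.

Two further stabilizers for short runs: `train_model` keeps a snapshot of
the weights (and BN statistics) from the best-validation epoch and
restores it at the end (`restore_best`, on by default) — SGD at high
learning rates can reach a good solution and then diverge away from it
within a 10-epoch budget; and the desk-scale experiments scale the
learning rate by the linear lr-batch rule (0.1 × batch/256, i.e. 0.0125
at batch 32), since the protocol's 0.1 is calibrated to batch-256
gradients and is unstable at small batches.

Class imbalance is left as-is by default (the "other" superclass dominates
stage 1); inverse-frequency class weighting is intentionally not applied
anywhere, matching the plain cross-entropy protocol.

## Cascade and evaluation

Stage 1 sees the RP image of the raw window. If it answers noise or VF the
cascade stops; otherwise R peaks are detected in ±2 s of surrounding
context, the peak nearest the window center with 1 s margin on both sides
is chosen, and the beat-centered RP image goes to stage 2. When no usable
peak exists the outcome is the distinct label `other-unresolved` — a
deliberate reported category, never a forced stage-2 guess; in the overall
confusion matrix it appears as its own predicted row and counts as a
misclassification against every truth.

The metric bundle: per-class counts by the complement decomposition
(TP = diagonal; FP = rest of predicted row; FN = rest of actual column;
TN = remainder); Sens = TP/(TP+FN); Sp = TN/(TN+FP); per-class PPV from
Bayes' theorem at that class's prevalence; headline PPV at the
minority-class prevalence; F1 as the harmonic mean of Sens and PPV; micro
accuracy (trace/N) and macro averages reported as mean ± sd over classes;
Cohen's kappa with p_e = Σ_c (row_c/N)(col_c/N). Zero-denominator rates
are NaN, never silently 0. ROC curves sweep all distinct score thresholds;
AUC is trapezoidal; the boundary threshold maximizes Youden's J = TPR −
FPR with ties resolved toward the higher threshold. All of this is checked
against brute-force recomputation from regenerated label vectors on random
confusion matrices (K = 2…6) at 1e-12, and kappa/AUC additionally against
scikit-learn.

A structural invariant is asserted on every evaluation: collapsing the
four rhythm classes (and `other-unresolved`) to "other" can only merge
errors into agreements, so six-class accuracy never exceeds the collapsed
three-superclass accuracy.

## Desk-scale experiment sizes

The end-to-end benchmark trains on 200 segments per class at 250 Hz
(70/15/15 train/validation/test per class), 96×96 RP images, a standard
ResNet-18 for stage 1 (5 epochs) and a base-width-16 ResNet-18 for stage 2
(10 epochs), batch 32 with the linearly scaled learning rate, no
augmentation (the synthetic classes are cleanly separable without it). These sizes were chosen so the whole experiment
runs in minutes on one CPU while leaving the pipeline's every stage
exercised: with them the held-out six-class macro-F1 exceeds 0.9 and the
collapse invariant holds (recomputed by `scripts/acceptance.py` and the
acceptance tests). Rhythm-class windows are R-peak-centered segments
labeled by their central beat, so every class bucket is pure; noise and VF
windows come from stage-1 tiling.

## Numerical choices and degenerate inputs

* All network arithmetic is float32; gradient-check tests run the same
  layers in float64 against central finite differences.
* Argmax ties (class scores) resolve to the lowest class index.
* Max-pool gradient routes to the first maximal element of each window.
* A constant/flat signal yields an empty R-peak list; a record shorter
  than one window yields an empty segment list; an empty confusion matrix
  or single-class truth vector raises instead of returning NaN bundles.
* WFDB IO quantizes signals at 200 adu/mV (format 16), so round trips are
  exact to 1/400 mV; annotation indices and order are preserved bitwise.

## Known limitations

* The numpy CNN engine is single-device and unaccelerated; it is meant for
  desk-scale experiments and reference semantics, not production training.
* The WFDB layer implements the subset of the format the pipeline needs
  (format 16, single segment, one annotation file); compressed or
  multi-segment records are out of scope.
* Synthetic data limitations listed above bound what the green test suite
  demonstrates about clinical recordings.
* Cross-validation utilities split by segment id, not by patient/record;
  on real data a record-aware split would be required to avoid leakage.
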