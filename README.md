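# rpecg — two-stage ECG arrhythmia classification from recurrence plots

`rpecg` classifies short (2 s) ECG segments into six rhythm categories —
normal sinus rhythm, atrial fibrillation (AF), premature atrial contraction
(PAC), premature ventricular contraction (PVC), ventricular fibrillation
(VF), and noise/artifact — by converting each segment into an unthresholded
recurrence-plot image and routing it through a cascade of two residual CNNs.
It is aimed at biomedical-signal researchers who want a fully inspectable,
CPU-only reference implementation of this pipeline, complete with a
synthetic ECG generator so every stage is testable without access to
clinical databases.

## The method

A recurrence plot (RP) compares every pair of delay-embedded states of a
time series x. The thresholded variant binarizes through a Heaviside step
at a cutoff ε,

    R_ij = Θ(ε − ‖x_i − x_j‖),

while the unthresholded variant used here keeps the raw distance matrix
D_ij = ‖x_i − x_j‖, which is min–max normalized, mapped through a rainbow
colormap, and rendered as a fixed-size RGB image. Rhythm structure becomes
texture: regular rhythms give periodic lattices, AF gives an irregular
block pattern, VF a smooth wandering oscillation, noise an unstructured
field.

Classification is a two-stage cascade. Stage 1 (ResNet-18) separates
{noise, VF, other} from the raw 2 s window — VF and noise lack usable R
peaks, so they must be caught before any beat-based processing. Windows
called "other" get Pan–Tompkins-style R-peak detection; one second of
signal on each side of the peak forms a beat-centered segment whose RP
image goes to stage 2 (ResNet-50 by default; any supported depth/width),
which outputs {AF, normal, PAC, PVC}.

Evaluation follows a strict multiclass formulary: per-class one-vs-rest
TP/FP/FN/TN decomposition; sensitivity, specificity; PPV via Bayes'
theorem evaluated at the minority-class prevalence P = (TP+FN)/N,

    PPV = Sens·P / (Sens·P + (1−Sp)(1−P));

F1 as the harmonic mean of sensitivity and PPV; Cohen's kappa
(p_o − p_e)/(1 − p_e); and one-vs-rest ROC/AUC with Youden-index boundary
thresholds.

## Worked example

```python
import numpy as np
from rpecg import SynthConfig, generate_record, detect_r_peaks, segment_stage2
from rpecg import RecurrencePlotImager, ResNetClassifier

# a 10 s synthetic record with ventricular ectopy and known annotations
rec = generate_record(SynthConfig("PVC", duration_s=10, fs=250,
                                  mean_hr_bpm=70, ectopic_rate=0.3, seed=0))
peaks = detect_r_peaks(rec)
segs = segment_stage2(rec, peaks)
print(len(peaks), [s.label for s in segs])
```

prints

```
11 ['normal', 'PVC', 'normal', 'PVC', 'normal', 'normal', 'normal', 'normal', 'normal']
```

— eleven detected R peaks, of which nine have the one-second context
needed on both sides; the two beats annotated `V` by the generator map to
`PVC`, the rest to `normal`. Each segment can then be imaged and classified:

```python
imager = RecurrencePlotImager(size=96)
images = imager.transform([s.samples for s in segs])   # (8, 96, 96, 3)
clf = ResNetClassifier(depth=18, base_width=16, input_size=96, epochs=10)
# clf.fit(train_images, train_labels); clf.predict(images)
```

The command-line interface mirrors the library
(`rpecg synth / segment / rp / train / cv / predict / evaluate`); run
`rpecg --help` for the pipeline plumbing.

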