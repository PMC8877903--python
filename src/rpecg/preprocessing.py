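"""Record-to-segment preprocessing for the two classification stages.

Stage 1 tiles a record with fixed 2 s windows and labels each window by the
two-thirds rule: a window gets a category label (VF from rhythm intervals,
noise from artifact intervals, otherwise "other") only if that category
covers at least 2/3 of its samples; windows with no 2/3 majority are
discarded.

Stage 2 detects R peaks (Pan-Tompkins-style) and cuts one second of signal
on each side of every peak; the segment is labeled by the beat annotation at
its central R peak (AF rhythm intervals override beat symbols).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import EcgRecord

__all__ = [
    "Segment",
    "window_samples",
    "segment_stage1",
    "segment_stage2",
    "detect_r_peaks",
    "map_annotation_label",
]

TWO_THIRDS = 2.0 / 3.0
BEAT_MATCH_TOL_S = 0.075   # beat-to-peak matching window, standard practice

_BEAT_MAP = {"N": "normal", "L": "normal", "R": "normal",
             "A": "PAC", "a": "PAC", "S": "PAC",
             "V": "PVC"}
_VF_RHYTHMS = {"VF", "VFL"}
UNMAPPED = "unmapped"


@dataclass
class Segment:
    """A fixed-duration 1-D ECG excerpt with its class label."""

    samples: np.ndarray          # mV, length round(2*fs)
    fs: float
    label: str
    stage: int                   # 1 or 2
    record_id: str
    start_sample: int
    center_r_sample: int | None = None  # absolute index, stage 2 only

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        expect = window_samples(self.fs, 2.0)
        if len(self.samples) != expect:
            raise ValueError(f"segment length {len(self.samples)} != round(2*fs) = {expect}")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


def window_samples(fs: float, duration_s: float = 2.0) -> int:
    """Number of samples in a window: round(fs * duration_s).

    2 s is 720 samples at 360 Hz and 500 samples at 250 Hz.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    return round(fs * duration_s)


def _strip_paren(label: str) -> str:
    return label[1:] if label.startswith("(") else label


def map_annotation_label(beat_symbol: str | None, rhythm_label: str | None,
                         in_artifact: bool = False) -> str:
    """Map WFDB beat symbol + rhythm context to a pipeline class label.

    Priority: artifact interval -> noise; VF rhythm -> VF; AFIB rhythm -> AF
    (rhythm overrides the beat symbol, since some databases carry rhythm-only
    labels); else the beat symbol (N/L/R -> normal, A/a/S -> PAC, V -> PVC);
    anything else -> the sentinel "unmapped".
    """
    if in_artifact:
        return "noise"
    rhythm = _strip_paren(rhythm_label) if rhythm_label else None
    if rhythm in _VF_RHYTHMS:
        return "VF"
    if rhythm == "AFIB":
        return "AF"
    if beat_symbol in _BEAT_MAP:
        return _BEAT_MAP[beat_symbol]
    return UNMAPPED


def _coverage_masks(record: EcgRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample boolean masks (vf, noise) from annotations."""
    n = record.n_samples
    vf = np.zeros(n, dtype=bool)
    rhythms = record.rhythm_annotations
    for k, (start, label) in enumerate(rhythms):
        end = rhythms[k + 1][0] if k + 1 < len(rhythms) else n
        if _strip_paren(label) in _VF_RHYTHMS:
            vf[start:end] = True
    noise = np.zeros(n, dtype=bool)
    for s, e in record.artifact_annotations:
        noise[s:e] = True
    return vf, noise


def segment_stage1(record: EcgRecord, window_s: float = 2.0,
                   stride_s: float | None = None) -> list[Segment]:
    """Tile the record and label windows by the two-thirds rule.

    Categories are noise (artifact intervals), VF (VF rhythm intervals) and
    other (everything else).  A window is labeled if one category covers at
    least 2/3 of its samples and discarded otherwise.  Default stride equals
    the window (non-overlapping tiling).
    """
    if stride_s is None:
        stride_s = window_s
    win = window_samples(record.fs, window_s)
    stride = window_samples(record.fs, stride_s)
    x = record.lead
    n = len(x)
    if n < win:
        return []
    vf, noise = _coverage_masks(record)
    vf_cum = np.concatenate([[0], np.cumsum(vf)])
    nz_cum = np.concatenate([[0], np.cumsum(noise)])

    out = []
    for start in range(0, n - win + 1, stride):
        end = start + win
        f_vf = (vf_cum[end] - vf_cum[start]) / win
        f_noise = (nz_cum[end] - nz_cum[start]) / win
        f_other = 1.0 - f_vf - f_noise
        fractions = {"VF": f_vf, "noise": f_noise, "other": f_other}
        label = max(fractions, key=fractions.get)
        if fractions[label] < TWO_THIRDS:
            continue
        out.append(Segment(
            samples=x[start:end], fs=record.fs, label=label, stage=1,
            record_id=record.record_id, start_sample=start,
        ))
    return out


def detect_r_peaks(record: EcgRecord, band: tuple = (5.0, 15.0)) -> list[int]:
    """Pan-Tompkins-style QRS detector.

    Band-pass 5-15 Hz -> differentiate -> square -> 150 ms moving-window
    integration -> adaptive threshold with a 200 ms refractory period.  Each
    detection is refined to the local absolute maximum of the raw signal
    within +/-50 ms.  The adaptive threshold is a fraction of a running
    amplitude estimate, so detections are invariant to a positive rescaling
    of the signal.
    """
    fs = record.fs
    if fs < 100:
        raise ValueError("detect_r_peaks requires fs >= 100 Hz")
    x = np.asarray(record.lead, dtype=float)
    if len(x) < round(0.5 * fs) or np.allclose(x, x[0]):
        return []

    nyq = fs / 2.0
    b, a = sps.butter(2, [band[0] / nyq, band[1] / nyq], btype="band")
    filt = sps.filtfilt(b, a, x)
    deriv = np.gradient(filt)
    sq = deriv ** 2
    win = max(1, round(0.150 * fs))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = round(0.200 * fs)
    # candidate local maxima of the integrated energy
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        return []

    # adaptive threshold: running signal/noise level estimates (scale-free)
    spk = float(np.percentile(integ[cand], 90))
    npk = float(np.percentile(integ, 10))
    peaks = []
    for c in cand:
        thr = npk + 0.25 * (spk - npk)
        if integ[c] >= thr:
            peaks.append(c)
            spk = 0.125 * integ[c] + 0.875 * spk
        else:
            npk = 0.125 * integ[c] + 0.875 * npk

    # refine to raw-signal absolute maximum within +/-50 ms
    half = round(0.050 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    # dedupe and enforce the refractory period on the refined indices
    out: list[int] = []
    for p in sorted(set(refined)):
        if out and p - out[-1] < refractory:
            if np.abs(x[p]) > np.abs(x[out[-1]]):
                out[-1] = p
        else:
            out.append(p)
    return out


def _rhythm_at(record: EcgRecord, sample: int) -> str | None:
    label = None
    for start, lab in record.rhythm_annotations:
        if start <= sample:
            label = lab
        else:
            break
    return label


def _in_artifact(record: EcgRecord, sample: int) -> bool:
    return any(s <= sample < e for s, e in record.artifact_annotations)


def segment_stage2(record: EcgRecord, r_peaks: list[int]) -> list[Segment]:
    """Cut one second before and after each R peak and label by the central
    beat annotation.

    Peaks closer than 1 s to either record edge are skipped, as are peaks
    with no beat annotation within +/-75 ms (unless an AF rhythm interval
    covers the peak, which labels the segment AF outright) and peaks whose
    label maps outside {AF, normal, PAC, PVC}.
    """
    if any(b <= a for a, b in zip(r_peaks, r_peaks[1:])):
        raise ValueError("r_peaks must be strictly increasing")
    fs = record.fs
    one_s = round(fs)
    x = record.lead
    n = len(x)
    tol = round(BEAT_MATCH_TOL_S * fs)
    beat_idx = np.array([s for s, _ in record.beat_annotations], dtype=int)
    beat_sym = [sym for _, sym in record.beat_annotations]

    out = []
    for peak in r_peaks:
        if peak < one_s or peak + one_s > n:
            continue
        rhythm = _rhythm_at(record, peak)
        symbol = None
        if len(beat_idx):
            j = int(np.argmin(np.abs(beat_idx - peak)))
            if abs(int(beat_idx[j]) - peak) <= tol:
                symbol = beat_sym[j]
        if symbol is None and not (rhythm and _strip_paren(rhythm) == "AFIB"):
            continue
        label = map_annotation_label(symbol, rhythm, _in_artifact(record, peak))
        if label not in ("AF", "normal", "PAC", "PVC"):
            continue
        start = peak - one_s
        out.append(Segment(
            samples=x[start:start + 2 * one_s], fs=fs, label=label, stage=2,
            record_id=record.record_id, start_sample=start, center_r_sample=peak,
        ))
    return out
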