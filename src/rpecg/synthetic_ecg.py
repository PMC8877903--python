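"""Synthetic annotated ECG generator for the six rhythm classes.

Emulates normal sinus rhythm, atrial fibrillation (AF), premature atrial
contraction (PAC), premature ventricular contraction (PVC), ventricular
fibrillation (VF) and noise/artifact, each with ground-truth beat and rhythm
annotations, so the whole pipeline is testable without PhysioNet downloads.

Morphology is a sum of five Gaussian bumps per beat (P, Q, R, S, T) rather
than a dynamical heart model: the goal is that the six classes are cleanly
separable in recurrence-plot space under full parametric control, not
physiological fidelity.

Class semantics:

* normal — regular RR (cv ~ 0.03), full P-QRS-T morphology;
* AF     — P wave suppressed, RR i.i.d. with large cv (~0.25);
* PAC    — normal rhythm with premature (RR x 0.6) narrow beats at
  ``ectopic_rate``, followed by a compensatory-ish pause;
* PVC    — as PAC but the premature beat is wide (QRS >= 2x) with no P wave;
* VF     — sinusoid whose frequency random-walks in 4-7 Hz: quasi-periodic
  oscillation without R peaks, no beat annotations;
* noise  — band-limited Gaussian noise plus baseline wander, artifact
  annotations covering the record, no beat annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import EcgRecord

__all__ = ["SynthConfig", "make_beat_template", "generate_record", "CLASSES"]

CLASSES = ("normal", "AF", "PAC", "PVC", "VF", "noise")

_RHYTHM_LABEL = {"normal": "(N", "AF": "(AFIB", "PAC": "(N", "PVC": "(N", "VF": "(VF"}


@dataclass
class SynthConfig:
    """Parameters of one synthetic record.

    ``rr_cv`` defaults depend on the class (0.03 normal-like, 0.25 AF); pass
    a value to override.  ``ectopic_rate`` only applies to PAC/PVC.
    """

    class_label: str = "normal"
    duration_s: float = 10.0
    fs: float = 250.0
    mean_hr_bpm: float = 70.0
    rr_cv: float | None = None
    ectopic_rate: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}; expected one of {CLASSES}")
        if self.duration_s <= 4:
            raise ValueError("duration_s must exceed 4 s (one 2 s window with context)")
        if not 0 <= self.ectopic_rate <= 0.5:
            raise ValueError("ectopic_rate must lie in [0, 0.5]")
        if self.rr_cv is not None and self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.fs <= 0 or self.mean_hr_bpm <= 0 or self.noise_sd < 0:
            raise ValueError("fs, mean_hr_bpm must be positive and noise_sd >= 0")

    @property
    def effective_rr_cv(self) -> float:
        if self.rr_cv is not None:
            return self.rr_cv
        return 0.25 if self.class_label == "AF" else 0.03


# Gaussian bump parameters per wave: (time offset s, width s, amplitude mV)
_WAVES = {
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.15),
    "R": (0.0, 0.014, 1.0),
    "S": (0.035, 0.010, -0.25),
    "T": (0.30, 0.060, 0.35),
}


def make_beat_template(fs: float, width_scale: float = 1.0, wide: bool = False,
                       gain: float = 1.0, p_wave: bool = True):
    """One P-QRS-T complex as a sum of five Gaussian bumps.

    Parameters
    ----------
    fs : sampling rate, Hz.
    width_scale : multiplies all wave widths (and QRS offsets).
    wide : ventricular morphology — QRS at least doubled in width, P wave
        suppressed, deeper S wave.
    gain : linear amplitude scale.
    p_wave : set False to suppress the P wave (AF morphology).

    Returns
    -------
    template : ndarray, samples spanning [-0.35 s, +0.45 s) around the R peak
    r_offset : int, sample index of the R peak inside the template
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.arange(round(-0.35 * fs), round(0.45 * fs)) / fs
    r_offset = -round(-0.35 * fs)
    y = np.zeros_like(t)
    qrs_widen = 2.6 if wide else 1.0
    for name, (mu, sd, amp) in _WAVES.items():
        if name == "P" and (wide or not p_wave):
            continue
        if name in ("Q", "R", "S"):
            sd = sd * qrs_widen * width_scale
            mu = mu * qrs_widen * width_scale
            if wide:
                amp = {"Q": -0.1, "R": 1.1, "S": -0.45}[name]
        else:
            sd = sd * width_scale
        y += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return gain * y, r_offset


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float = 0.5, hi: float = 40.0) -> np.ndarray:
    white = rng.standard_normal(n)
    hi = min(hi, 0.45 * fs)
    b, a = sps.butter(3, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    x = sps.lfilter(b, a, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_rr(rng: np.random.Generator, mean_rr: float, cv: float) -> float:
    # truncated so RR stays physiological and positive
    return float(np.clip(rng.normal(mean_rr, cv * mean_rr), 0.3 * mean_rr, 2.0 * mean_rr))


def _beat_train(cfg: SynthConfig, rng: np.random.Generator, n: int):
    """Place beats; returns (signal, beat_annotations)."""
    fs, mean_rr = cfg.fs, 60.0 / cfg.mean_hr_bpm
    cv = cfg.effective_rr_cv
    suppress_p = cfg.class_label == "AF"
    normal_tpl, normal_off = make_beat_template(fs, p_wave=not suppress_p)
    pac_tpl, pac_off = make_beat_template(fs, width_scale=0.9, p_wave=True)
    pvc_tpl, pvc_off = make_beat_template(fs, wide=True)

    y = np.zeros(n)
    beats = []
    t = 0.5 * mean_rr + 0.2  # first beat well inside the record
    is_ectopic = False       # whether the beat being placed arrived early
    while True:
        r_sample = round(t * fs)
        if r_sample >= n - round(0.45 * fs):
            break
        if is_ectopic and cfg.class_label == "PAC":
            symbol, tpl, off = "A", pac_tpl, pac_off
        elif is_ectopic:
            symbol, tpl, off = "V", pvc_tpl, pvc_off
        else:
            symbol, tpl, off = "N", normal_tpl, normal_off
        start = r_sample - off
        stop = start + len(tpl)
        lo, hi = max(start, 0), min(stop, n)
        if hi > lo:
            y[lo:hi] += tpl[lo - start:hi - start]
        beats.append((r_sample, symbol))
        if is_ectopic:
            rr = 1.3 * mean_rr  # post-extrasystolic pause
            is_ectopic = False
        elif cfg.class_label in ("PAC", "PVC") and rng.random() < cfg.ectopic_rate:
            rr = 0.6 * mean_rr  # the next beat is premature
            is_ectopic = True
        else:
            rr = _draw_rr(rng, mean_rr, cv)
        t += rr
    return y, beats


def _vf_signal(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Chaotic quasi-periodic oscillation: sinusoid with random-walking
    instantaneous frequency in 4-7 Hz and slowly varying amplitude."""
    fs = cfg.fs
    f = np.empty(n)
    f[0] = rng.uniform(4.0, 7.0)
    steps = rng.normal(0, 0.8 / np.sqrt(fs), size=n - 1)
    f[1:] = f[0] + np.cumsum(steps)
    # reflect the walk back into [4, 7]
    f = 4.0 + np.abs((f - 4.0) % 6.0 - 3.0)
    phase = 2 * np.pi * np.cumsum(f) / fs
    amp = 0.5 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * np.arange(n) / fs
                             + rng.uniform(0, 2 * np.pi))
    return amp * np.sin(phase)


def _noise_signal(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    fs = cfg.fs
    wander_f = rng.uniform(0.15, 0.4)
    wander = 0.6 * np.sin(2 * np.pi * wander_f * np.arange(n) / fs + rng.uniform(0, 2 * np.pi))
    return 0.45 * _band_limited_noise(rng, n, fs, lo=0.5, hi=40.0) + wander


def generate_record(config: SynthConfig) -> EcgRecord:
    """Generate one annotated record; all randomness flows from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration_s * cfg.fs)

    beats: list = []
    artifacts: list = []
    if cfg.class_label == "VF":
        y = _vf_signal(cfg, rng, n)
        rhythms = [(0, "(VF")]
    elif cfg.class_label == "noise":
        y = _noise_signal(cfg, rng, n)
        rhythms = [(0, "(N")]
        artifacts = [(0, n)]
    else:
        y, beats = _beat_train(cfg, rng, n)
        rhythms = [(0, _RHYTHM_LABEL[cfg.class_label])]

    if cfg.noise_sd > 0:
        y = y + cfg.noise_sd * _band_limited_noise(rng, n, cfg.fs, lo=0.5, hi=45.0)

    return EcgRecord(
        record_id=f"synth-{cfg.class_label}-{cfg.seed}",
        signal=y,
        fs=cfg.fs,
        beat_annotations=beats,
        rhythm_annotations=rhythms,
        artifact_annotations=artifacts,
    )
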