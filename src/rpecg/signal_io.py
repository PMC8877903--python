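"""Reading and writing ECG records in the WFDB file conventions.

A record consists of a text header (``<record>.hea``), a binary signal file
(format 16: little-endian int16, channels interleaved), and an annotation
file (``<record>.atr``) in the MIT annotation format carrying beat symbols,
rhythm-change aux strings (``"(N"``, ``"(AFIB"``, ``"(VF"`` ...) and
signal-quality markers used here to delimit artifact (noise) intervals.

Only the subset of the conventions needed for single-segment arrhythmia
records is implemented: one or more channels, format 16, annotation times as
cumulative sample intervals.  Sample indices are 0-based and intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EcgRecord",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_manifest",
    "write_manifest",
    "ManifestError",
]

# MIT annotation-code <-> symbol tables (subset).
_BEAT_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_BEAT_SYMBOL_TO_CODE = {v: k for k, v in _BEAT_CODE_TO_SYMBOL.items()}
_RHYTHM = 28          # '+' rhythm change, aux holds the rhythm string
_QUALITY = 14         # signal-quality change, used for artifact intervals
_SKIP = 59
_AUX = 63

_NOISE_ON = "noise-on"
_NOISE_OFF = "noise-off"

STAGE1_LABELS = ("noise", "VF", "other")
STAGE2_LABELS = ("AF", "normal", "PAC", "PVC")


@dataclass
class EcgRecord:
    """A sampled ECG trace with beat/rhythm/artifact annotations.

    Attributes
    ----------
    record_id : str
        Record name (file stem on disk).
    signal : ndarray
        Voltage samples in mV.  Multichannel records are stored as
        (n_samples, n_channels); ``channel`` selects the working lead.
    fs : float
        Sampling rate in Hz, > 0.
    beat_annotations : list of (int, str)
        (sample_index, beat_symbol), strictly increasing indices.
    rhythm_annotations : list of (int, str)
        (sample_index, rhythm_label) rhythm-change points; labels keep the
        WFDB leading "(" (e.g. ``"(AFIB"``).
    artifact_annotations : list of (int, int)
        Half-open [start, end) noise intervals.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    beat_annotations: list = field(default_factory=list)
    rhythm_annotations: list = field(default_factory=list)
    artifact_annotations: list = field(default_factory=list)
    channel: int = 0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.signal)
        for name in ("beat_annotations", "rhythm_annotations"):
            ann = getattr(self, name)
            idx = [int(i) for i, _ in ann]
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"{name}: sample index out of [0, {n})")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"{name}: indices must be strictly increasing")
        for s, e in self.artifact_annotations:
            if not (0 <= s <= e <= n):
                raise ValueError("artifact interval outside the record")

    @property
    def lead(self) -> np.ndarray:
        """Working single-channel signal (``channel``, default 0)."""
        if self.signal.ndim == 1:
            return self.signal
        return self.signal[:, self.channel]

    @property
    def n_samples(self) -> int:
        return len(self.signal)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_channel(self, channel: int) -> "EcgRecord":
        return replace(self, channel=channel)


# --------------------------------------------------------------------------
# WFDB record IO


def _fs_repr(fs: float) -> str:
    return repr(int(fs)) if float(fs).is_integer() else repr(float(fs))


def write_wfdb_record(record: EcgRecord, path: str) -> None:
    """Write ``record`` as ``<path>/<record_id>.{hea,dat,atr}``.

    Physical samples are quantized with a gain of 200 adu/mV (the common
    MIT-BIH value), so a round trip preserves voltages to 1/400 mV.
    """
    os.makedirs(path, exist_ok=True)
    name = record.record_id
    sig = record.signal
    if sig.ndim == 1:
        sig = sig[:, None]
    n_samples, n_sig = sig.shape
    gain, baseline = 200.0, 0
    adc = np.clip(np.rint(sig * gain) + baseline, -32768, 32767).astype("<i2")

    lines = [f"{name} {n_sig} {_fs_repr(record.fs)} {n_samples}"]
    for ch in range(n_sig):
        first = int(adc[0, ch]) if n_samples else 0
        lines.append(f"{name}.dat 16 {int(gain)}({baseline})/mV 16 0 {first} 0 0 ch{ch}")
    with open(os.path.join(path, name + ".hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    adc.reshape(-1).tofile(os.path.join(path, name + ".dat"))
    _write_annotations(record, os.path.join(path, name + ".atr"))


def _ann_stream(record: EcgRecord):
    """Merge beat/rhythm/artifact annotations into one time-ordered stream."""
    events = []  # (sample, priority, code, aux)
    for s, sym in record.beat_annotations:
        code = _BEAT_SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unsupported beat symbol {sym!r}")
        events.append((int(s), 1, code, None))
    for s, lab in record.rhythm_annotations:
        events.append((int(s), 0, _RHYTHM, lab))
    for s, e in record.artifact_annotations:
        events.append((int(s), 2, _QUALITY, _NOISE_ON))
        events.append((int(e), 2, _QUALITY, _NOISE_OFF))
    events.sort(key=lambda t: (t[0], t[1]))
    return events


def _write_annotations(record: EcgRecord, path: str) -> None:
    out = bytearray()
    prev = 0
    for sample, _prio, code, aux in _ann_stream(record):
        dt = sample - prev
        if not 0 <= dt < 1024:
            # SKIP atom: 4-byte absolute interval, then the event at dt=0
            out += int((_SKIP << 10)).to_bytes(2, "little")
            out += ((dt >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (dt & 0xFFFF).to_bytes(2, "little")
            dt = 0
        out += ((code << 10) | dt).to_bytes(2, "little")
        if aux is not None:
            data = aux.encode()
            out += ((_AUX << 10) | len(data)).to_bytes(2, "little")
            out += data
            if len(data) % 2:
                out += b"\x00"
        prev = sample
    out += b"\x00\x00"  # EOF
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def _read_annotations(path: str):
    with open(path, "rb") as fh:
        buf = fh.read()
    beats, rhythms, quality = [], [], []
    pos, t = 0, 0
    pending = None  # (code, sample) awaiting a possible AUX atom
    while pos + 1 < len(buf):
        word = int.from_bytes(buf[pos:pos + 2], "little")
        pos += 2
        code, payload = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi = int.from_bytes(buf[pos:pos + 2], "little")
            lo = int.from_bytes(buf[pos + 2:pos + 4], "little")
            pos += 4
            t += (hi << 16) | lo
            pending = None
            continue
        if code == _AUX:
            aux = buf[pos:pos + payload].decode()
            pos += payload + (payload % 2)
            if pending is not None:
                pcode, psample = pending
                if pcode == _RHYTHM:
                    rhythms.append((psample, aux))
                elif pcode == _QUALITY:
                    quality.append((psample, aux))
                pending = None
            continue
        t += payload
        if code in _BEAT_CODE_TO_SYMBOL:
            beats.append((t, _BEAT_CODE_TO_SYMBOL[code]))
            pending = None
        elif code in (_RHYTHM, _QUALITY):
            pending = (code, t)
        else:
            pending = None
    artifacts = []
    start = None
    for s, aux in quality:
        if aux == _NOISE_ON:
            start = s
        elif aux == _NOISE_OFF and start is not None:
            artifacts.append((start, s))
            start = None
    return beats, rhythms, artifacts


def read_wfdb_record(path: str, channel: int = 0) -> EcgRecord:
    """Read a WFDB record.

    ``path`` is the record path without extension (``dir/100``) or the
    directory containing exactly one ``.hea`` file.
    """
    if os.path.isdir(path):
        heads = sorted(f for f in os.listdir(path) if f.endswith(".hea"))
        if not heads:
            raise FileNotFoundError(f"no .hea header file in {path!r}")
        path = os.path.join(path, heads[0][:-4])
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing header file {hea!r}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    rec_line = lines[0].split()
    name, n_sig = rec_line[0], int(rec_line[1])
    fs = float(rec_line[2]) if len(rec_line) > 2 else 250.0
    n_samples = int(rec_line[3]) if len(rec_line) > 3 else -1

    gains, baselines, fmts, dat_name = [], [], [], None
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        dat_name = parts[0]
        fmts.append(parts[1])
        gspec = parts[2] if len(parts) > 2 else "200"
        g = gspec.split("/")[0]
        if "(" in g:
            g, b = g.split("(")
            baselines.append(int(b.rstrip(")")))
        else:
            baselines.append(0)
        gains.append(float(g) if float(g) != 0 else 200.0)
    if any(f.split("+")[0] != "16" for f in fmts):
        raise ValueError(f"unsupported signal format(s) {fmts}; only format 16 is handled")

    dat = os.path.join(os.path.dirname(path), dat_name)
    if not os.path.exists(dat):
        raise FileNotFoundError(f"missing signal file {dat!r}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples >= 0 and len(raw) != n_samples * n_sig:
        raise ValueError(
            f"signal length mismatch: header promises {n_samples}x{n_sig} "
            f"samples, file holds {len(raw)}"
        )
    adc = raw.reshape(-1, n_sig)
    sig = (adc - np.asarray(baselines)) / np.asarray(gains)
    if n_sig == 1:
        sig = sig[:, 0]

    atr = path + ".atr"
    beats, rhythms, artifacts = _read_annotations(atr) if os.path.exists(atr) else ([], [], [])
    return EcgRecord(
        record_id=name,
        signal=sig,
        fs=fs,
        beat_annotations=beats,
        rhythm_annotations=rhythms,
        artifact_annotations=artifacts,
        channel=channel,
    )


# --------------------------------------------------------------------------
# Segment manifests


class ManifestError(ValueError):
    pass


_MANIFEST_COLUMNS = [
    "segment_id", "record_id", "start_sample", "end_sample", "fs",
    "stage", "label", "image_path",
]


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    """Write a segment manifest as a UTF-8 CSV with a header row."""
    df = manifest.loc[:, _MANIFEST_COLUMNS]
    _validate_manifest(df)
    df.to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_path": "string", "label": "string",
                                  "segment_id": "string", "record_id": "string"})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    _validate_manifest(df)
    return df.loc[:, _MANIFEST_COLUMNS]


def _validate_manifest(df: pd.DataFrame) -> None:
    for i, row in enumerate(df.itertuples(index=False)):
        stage = int(row.stage)
        if stage not in (1, 2):
            raise ManifestError(f"row {i}: stage must be 1 or 2, got {row.stage}")
        allowed = STAGE1_LABELS if stage == 1 else STAGE2_LABELS
        if row.label not in allowed:
            raise ManifestError(f"row {i}: label {row.label!r} not valid for stage {stage}")
        expect = round(2 * float(row.fs))
        if int(row.end_sample) - int(row.start_sample) != expect:
            raise ManifestError(
                f"row {i}: segment length {int(row.end_sample) - int(row.start_sample)} "
                f"!= round(2*fs) = {expect}"
            )
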