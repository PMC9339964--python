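"""Readers and writers: CSV signals, JSON annotations, WFDB records.

WFDB support is a minimal single-channel implementation of the classic
header + format-16 (little-endian 16-bit) signal file pair, enough to
round-trip simulated records and to read simple PhysioNet-style PPG
records.  Signals at other sampling rates are resampled to 100 Hz.
"""

from __future__ import annotations

import json
import os
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from ppgdetect.ppg_sim import PPGSignal

TARGET_FS = 100.0


def _resample(x: np.ndarray, fs: float, target: float = TARGET_FS) -> np.ndarray:
    if fs == target:
        return x
    frac = Fraction(target / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def read_annotations(path: str) -> list[tuple[float, float, str]]:
    with open(path) as fh:
        raw = json.load(fh)
    return [(float(d["start_s"]), float(d["end_s"]), str(d["rhythm"])) for d in raw]


def write_annotations(annotations, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"start_s": s, "end_s": e, "rhythm": r} for s, e, r in annotations],
            fh, indent=1,
        )


def _sidecar(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".ann.json"


def read_ppg(path: str, format: str = "csv", fs: float = TARGET_FS) -> PPGSignal:
    """Load a PPG record, resampled to 100 Hz.

    ``csv``: one numeric column (header ``value`` or first column), sampled
    at ``fs``.  ``wfdb``: path to the ``.hea`` header (or its basename) of
    a format-16 record; the first channel is used.  Annotations are loaded
    from ``<base>.ann.json`` when present.
    """
    if not os.path.exists(path) and format != "wfdb":
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        col = "value" if "value" in df.columns else df.columns[0]
        x = df[col].to_numpy(dtype=float)
    elif format == "wfdb":
        x, fs = _read_wfdb(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    x = _resample(x, fs)
    ann_path = _sidecar(path if not path.endswith(".hea") else path[:-4] + ".x")
    annotations = read_annotations(ann_path) if os.path.exists(ann_path) else []
    return PPGSignal(x, TARGET_FS, annotations)


# ------------------------------------------------------------------ WFDB

def _read_wfdb(path: str) -> tuple[np.ndarray, float]:
    hea = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else None
    if n_sig < 1:
        raise ValueError("record has no signal channels")
    sig = lines[1].split()
    dat_file, fmt = sig[0], sig[1].split("x")[0]
    if fmt != "16":
        raise ValueError(f"only format 16 is supported, got {fmt}")
    gain, baseline = 200.0, 0
    if len(sig) > 2:
        gspec = sig[2]
        if "/" in gspec:
            gspec = gspec.split("/")[0]
        if "(" in gspec:
            g, b = gspec.split("(")
            gain, baseline = float(g), int(b.rstrip(")"))
        else:
            gain = float(gspec)
    if gain == 0:
        gain = 200.0
    raw = np.fromfile(os.path.join(os.path.dirname(hea), dat_file), dtype="<i2")
    if n_sig > 1:
        raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samples is not None:
        raw = raw[:n_samples]
    return (raw.astype(float) - baseline) / gain, fs


def write_wfdb(ppg: PPGSignal, basename: str, units: str = "adu") -> None:
    """Write a single-channel format-16 record (+ annotation sidecar)."""
    x = ppg.samples
    span = float(np.max(np.abs(x))) if len(x) else 1.0
    gain = 30000.0 / span if span > 0 else 200.0
    adc = np.clip(np.round(x * gain), -32768, 32767).astype("<i2")
    rec = os.path.basename(basename)
    with open(basename + ".hea", "w") as fh:
        fh.write(f"{rec} 1 {ppg.fs:g} {len(x)}\n")
        fh.write(f"{rec}.dat 16 {gain:.6f}(0)/{units} 16 0 {int(adc[0]) if len(adc) else 0} 0 0 PPG\n")
    adc.tofile(basename + ".dat")
    if ppg.annotations:
        write_annotations(ppg.annotations, basename + ".ann.json")


def write_labels_csv(labels, path: str) -> None:
    pd.DataFrame({"segment": np.arange(len(labels)), "label": labels}).to_csv(path, index=False)


def read_labels_csv(path: str) -> np.ndarray:
    df = pd.read_csv(path)
    col = "label" if "label" in df.columns else df.columns[-1]
    return df[col].astype(str).to_numpy()
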