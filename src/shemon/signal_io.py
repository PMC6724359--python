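"""Reading, writing, resampling and windowing of single-lead ECG and 6-axis IMU data.

The working sampling rate for all ECG models is 250 Hz; records acquired at
other rates (e.g. 1000 Hz or 257 Hz) are brought to 250 Hz with
:func:`resample` before windowing.  Windows are 8 s (2000 samples at 250 Hz)
with a per-sample class-label sequence built by :func:`expand_labels`.
"""

from __future__ import annotations

import csv as _csv
import struct
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as _sig

__all__ = [
    "EcgRecord",
    "LabeledWindow",
    "ImuRecord",
    "CLASS_NAMES",
    "DEFAULT_CLASS_SCHEME",
    "read_record",
    "write_record",
    "read_imu_csv",
    "write_imu_csv",
    "resample",
    "make_windows",
    "expand_labels",
    "save_dataset",
    "load_dataset",
]

#: Nine output classes.  Index 0 is background / normal sinus rhythm; 1-3 are
#: record-level diagnosis classes, 4-6 beat-level ectopy classes.  The last two
#: slots are implementation-assigned (paced beats and unknown/noise).
CLASS_NAMES = (
    "normal",
    "MI",
    "HF",
    "AR",
    "FB",
    "SVEB",
    "VEB",
    "paced",
    "unknown",
)

#: Annotation symbol -> class index.  Beat symbols follow the MIT/PhysioNet
#: convention; record-level rhythm strings map to the diagnosis classes.
DEFAULT_CLASS_SCHEME: dict[str, int] = {
    "N": 0,
    "L": 0,
    "R": 0,
    "MI": 1,
    "HF": 2,
    "AR": 3,
    "F": 4,
    "FB": 4,
    "A": 5,
    "a": 5,
    "S": 5,
    "J": 5,
    "j": 5,
    "SVEB": 5,
    "V": 6,
    "E": 6,
    "VEB": 6,
    "/": 7,
    "f": 7,
    "paced": 7,
    "Q": 8,
    "unknown": 8,
}

#: Radius (seconds) of the neighborhood painted around each annotated R-peak.
#: 300 ms covers one QRST complex without swallowing neighbors at <= 100 bpm.
BEAT_PAINT_RADIUS_S = 0.3

WORKING_FS = 250.0


@dataclass
class EcgRecord:
    """Uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling rate in Hz; must be positive.
    lead : str
        Lead label, e.g. ``"V2"`` or ``"MLV2"``.
    beat_labels : list of (int, str)
        Optional per-beat annotations as (sample index, symbol), strictly
        increasing in index.
    rhythm_label : str or None
        Optional record-level diagnosis class (e.g. ``"MI"``).
    """

    samples: np.ndarray
    fs: float
    lead: str = "MLV2"
    beat_labels: list[tuple[int, str]] = field(default_factory=list)
    rhythm_label: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        idx = [i for i, _ in self.beat_labels]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("beat indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("beat indices must lie inside the record")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class LabeledWindow:
    """Fixed-length signal segment with a per-sample class-label sequence."""

    x: np.ndarray
    y: np.ndarray
    start: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")


@dataclass
class ImuRecord:
    """6-channel inertial stream: 3-axis acceleration and 3-axis gyro."""

    acc: np.ndarray  # (n, 3), m s^-2
    gyro: np.ndarray  # (n, 3), deg s^-1
    fs: float
    activity: str | None = None

    def __post_init__(self):
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.acc.shape != self.gyro.shape or self.acc.shape[1] != 3:
            raise ValueError("acc and gyro must both be (n, 3)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def channels(self) -> np.ndarray:
        """(n, 6) array: ax ay az gx gy gz."""
        return np.hstack([self.acc, self.gyro])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv_record(path: Path) -> EcgRecord:
    t, v = [], []
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        header = next(reader)
        if header and header[0].strip().lower() not in ("time_s", "t"):
            # no header: treat first row as data
            t.append(float(header[0]))
            v.append(float(header[1]))
        for row in reader:
            if not row:
                continue
            t.append(float(row[0]))
            v.append(float(row[1]))
    if len(t) < 2:
        raise IOError(f"CSV record too short: {path}")
    fs = 1.0 / float(np.median(np.diff(t)))
    beat_labels = []
    sidecar = path.with_suffix(".labels.csv")
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            reader = _csv.reader(fh)
            next(reader)  # header
            for row in reader:
                if row:
                    beat_labels.append((int(row[0]), row[1].strip()))
    return EcgRecord(np.asarray(v), fs=round(fs, 6), beat_labels=beat_labels)


def _write_csv_record(rec: EcgRecord, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["time_s", "voltage_mV"])
        for i, v in enumerate(rec.samples):
            w.writerow([f"{i / rec.fs:.6f}", repr(float(v))])
    if rec.beat_labels:
        with open(path.with_suffix(".labels.csv"), "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["sample_index", "symbol"])
            for i, sym in rec.beat_labels:
                w.writerow([i, sym])


# ---------------------------------------------------------------------------
# Minimal WFDB I/O (header + .dat formats 16 and 212 + MIT .atr annotations)
# ---------------------------------------------------------------------------

# MIT annotation code -> symbol, common beat codes only.
_ATR_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 38: "f",
}
_SYMBOL_TO_ATR_CODE = {v: k for k, v in _ATR_CODE_TO_SYMBOL.items()}


def _parse_hea(path: Path):
    lines = [ln.split("#")[0].strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fname = tok[0]
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2]
            if "(" in g:
                baseline = int(g[g.index("(") + 1 : g.index(")")])
            g = g.split("(")[0].split("/")[0]
            if g:
                gain = float(g) or 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append(dict(fname=fname, fmt=fmt, gain=gain, baseline=baseline,
                         desc=desc))
    return name, nsig, fs, nsamp, sigs


def _read_dat(path: Path, fmt: str, nsig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == "16":
        adc = np.frombuffer(raw, dtype="<i2")
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        adc = np.empty(2 * len(b), dtype=np.int32)
        adc[0::2], adc[1::2] = s0, s1
    else:
        raise IOError(f"unsupported WFDB signal format {fmt!r}")
    n = (len(adc) // nsig) * nsig
    return adc[:n].reshape(-1, nsig)


def _read_atr(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == 59:  # SKIP: next 4 bytes hold a long interval
            if i + 3 < len(raw):
                t += struct.unpack("<i", bytes([raw[i + 2], raw[i + 3],
                                                raw[i], raw[i + 1]]))[0]
                i += 4
        elif code in (60, 61, 62):  # NUM / SUB / CHN: modifier, no time
            continue
        elif code == 63:  # AUX: skip payload (padded to even length)
            i += interval + (interval & 1)
        else:
            t += interval
            sym = _ATR_CODE_TO_SYMBOL.get(code)
            if sym is None:
                warnings.warn(f"unknown annotation code {code}; recorded as 'unknown'")
                sym = "unknown"
            out.append((t, sym))
    return out


def _read_wfdb(path: Path, lead: str | None = None) -> EcgRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header {hea}")
    name, nsig, fs, nsamp, sigs = _parse_hea(hea)
    dat = hea.parent / sigs[0]["fname"]
    fmt = sigs[0]["fmt"]
    adc = _read_dat(dat, fmt, nsig)
    if lead is not None:
        descs = [s["desc"] for s in sigs]
        if lead not in descs:
            raise IOError(f"lead {lead!r} not in record (has {descs})")
        ch = descs.index(lead)
    else:
        ch = 0
    s = sigs[ch]
    volts = (adc[:, ch].astype(float) - s["baseline"]) / s["gain"]
    beat_labels = []
    atr = hea.with_suffix(".atr")
    if atr.exists():
        beat_labels = [(i, sym) for i, sym in _read_atr(atr) if i < len(volts)]
    return EcgRecord(volts, fs=fs, lead=s["desc"], beat_labels=beat_labels)


def write_wfdb(rec: EcgRecord, directory, name: str, gain: float = 200.0) -> Path:
    """Write a single-channel WFDB record (format 16) plus .atr annotations.

    Returns the path of the header file.  ADC values are rounded; use a gain
    large enough for the desired amplitude resolution.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(rec.samples * gain).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    hea = directory / f"{name}.hea"
    fs = int(rec.fs) if float(rec.fs).is_integer() else rec.fs
    hea.write_text(
        f"{name} 1 {fs} {len(adc)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if len(adc) else 0} 0 0 {rec.lead}\n"
    )
    if rec.beat_labels:
        buf = bytearray()
        prev = 0
        for idx, sym in rec.beat_labels:
            code = _SYMBOL_TO_ATR_CODE.get(sym, 13)
            dt = idx - prev
            if dt >= 1024:
                buf += struct.pack("<H", 59 << 10)
                buf += struct.pack("<i", dt)[2:4] + struct.pack("<i", dt)[0:2]
                dt = 0
            buf += struct.pack("<H", (code << 10) | dt)
            prev = idx
        buf += b"\x00\x00"
        (directory / f"{name}.atr").write_bytes(bytes(buf))
    return hea


def read_record(path, format: str | None = None, lead: str | None = None) -> EcgRecord:
    """Read an ECG record from CSV or WFDB.

    ``format`` is ``"csv"`` or ``"wfdb"``; when omitted it is inferred from
    the file extension.  The native sampling rate is preserved (no silent
    resampling); WFDB annotations, when present, become ``beat_labels``.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat", ".atr", "") else "csv"
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb(path, lead=lead)
    raise ValueError(f"unknown format {format!r}")


def write_record(rec: EcgRecord, path) -> None:
    """Write a record as CSV (``time_s,voltage_mV`` + label sidecar)."""
    _write_csv_record(rec, Path(path))


def read_imu_csv(path, fs: float | None = None) -> ImuRecord:
    """Read an IMU stream from CSV with columns ``t,ax,ay,az,gx,gy,gz``."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = data["t"]
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    acc = np.column_stack([data["ax"], data["ay"], data["az"]])
    gyro = np.column_stack([data["gx"], data["gy"], data["gz"]])
    return ImuRecord(acc, gyro, fs=round(fs, 6))


def write_imu_csv(imu: ImuRecord, path) -> None:
    n = len(imu.acc)
    t = np.arange(n) / imu.fs
    arr = np.column_stack([t, imu.acc, imu.gyro])
    header = "t,ax,ay,az,gx,gy,gz"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")


# ---------------------------------------------------------------------------
# Resampling, label expansion and windowing
# ---------------------------------------------------------------------------

def resample(rec: EcgRecord, fs_target: float) -> EcgRecord:
    """Resample to ``fs_target`` with a polyphase anti-aliasing filter.

    Beat-label indices are rescaled by the same ratio.  The output length is
    ``round(len * fs_target / fs)`` within one sample.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if len(rec.samples) == 0:
        raise ValueError("cannot resample an empty record")
    if fs_target == rec.fs:
        return replace(rec)
    ratio = Fraction(fs_target / rec.fs).limit_denominator(10000)
    x = _sig.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    scale = fs_target / rec.fs
    labels = [(min(int(round(i * scale)), len(x) - 1), sym)
              for i, sym in rec.beat_labels]
    # rounding can merge adjacent labels at extreme downsampling; keep order strict
    out_labels: list[tuple[int, str]] = []
    for i, sym in labels:
        if out_labels and i <= out_labels[-1][0]:
            i = out_labels[-1][0] + 1
        if i < len(x):
            out_labels.append((i, sym))
    return EcgRecord(x, fs=fs_target, lead=rec.lead, beat_labels=out_labels,
                     rhythm_label=rec.rhythm_label)


def expand_labels(rec: EcgRecord, class_scheme: dict[str, int] | None = None,
                  radius_s: float = BEAT_PAINT_RADIUS_S) -> np.ndarray:
    """Build the per-sample class vector for a record.

    Each annotated beat paints a symmetric neighborhood of ``radius_s`` around
    its R-peak with its beat class; a record-level rhythm class fills every
    sample not claimed by a non-background beat class; everything else is
    background (class 0).  Precedence: beat class > rhythm class > background.

    Raises ``KeyError`` listing any annotation symbol missing from the scheme.
    """
    scheme = DEFAULT_CLASS_SCHEME if class_scheme is None else class_scheme
    missing = sorted({sym for _, sym in rec.beat_labels if sym not in scheme})
    if rec.rhythm_label is not None and rec.rhythm_label not in scheme:
        missing.append(rec.rhythm_label)
    if missing:
        raise KeyError(f"unmapped annotation symbols: {missing}")
    n = len(rec.samples)
    y = np.zeros(n, dtype=np.int64)
    if rec.rhythm_label is not None:
        y[:] = scheme[rec.rhythm_label]
    r = int(round(radius_s * rec.fs))
    for idx, sym in rec.beat_labels:
        cls = scheme[sym]
        if cls == 0:
            continue  # normal beats stay background; only ectopy claims samples
        y[max(0, idx - r): min(n, idx + r + 1)] = cls
    return y


def make_windows(rec: EcgRecord, win_s: float = 8.0, stride_s: float | None = None,
                 class_scheme: dict[str, int] | None = None) -> list[LabeledWindow]:
    """Cut a record into fixed-length labeled windows.

    Windows are non-overlapping by default (stride = window).  The trailing
    partial window is dropped.  The record must already be at the working rate
    (250 Hz by default elsewhere); no resampling happens here.
    """
    if stride_s is None:
        stride_s = win_s
    L = int(round(win_s * rec.fs))
    step = int(round(stride_s * rec.fs))
    n = len(rec.samples)
    if n < L:
        warnings.warn(f"record of {n} samples shorter than one {L}-sample window")
        return []
    y_full = expand_labels(rec, class_scheme)
    out = []
    for start in range(0, n - L + 1, step):
        out.append(LabeledWindow(rec.samples[start:start + L],
                                 y_full[start:start + L], start=start))
    return out


# ---------------------------------------------------------------------------
# HDF5 dataset cache
# ---------------------------------------------------------------------------

def save_dataset(path, X: np.ndarray, Y: np.ndarray, fs: float = WORKING_FS,
                 class_names=CLASS_NAMES) -> None:
    """Cache a window set as HDF5: datasets /x (n,L) float32, /y (n,L) int8."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=np.asarray(X, dtype=np.float32))
        f.create_dataset("y", data=np.asarray(Y, dtype=np.int8))
        f.attrs["fs"] = fs
        f.attrs["class_names"] = list(class_names)


def load_dataset(path):
    import h5py

    with h5py.File(path, "r") as f:
        X = f["x"][...].astype(float)
        Y = f["y"][...].astype(np.int64)
        fs = float(f.attrs["fs"])
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["class_names"]]
    return X, Y, fs, names
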