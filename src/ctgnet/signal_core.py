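"""CTG trace data model, validity accounting, resampling, windowing and file I/O.

A cardiotocogram (CTG) couples a fetal heart rate (FHR, beats per minute)
channel with a uterine contraction (UC, dimensionless tocodynamometer units)
channel. Clinical monitors record both at 4 Hz; the classification models in
this package consume 1 Hz, 30-minute windows (1800 samples). Transducer
displacement produces runs of missing signal ("signal loss"), which clinical
practice encodes as zeros; here invalid samples are carried explicitly in a
per-sample validity mask and stored as NaN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CTGTrace",
    "WindowSpec",
    "FHR_MIN_BPM",
    "FHR_MAX_BPM",
    "compute_signal_loss",
    "passes_quality",
    "extract_last_window",
    "downsample",
    "interpolate_invalid",
    "read_ctg_csv",
    "write_ctg_csv",
    "read_wfdb_record",
    "write_wfdb_record",
]

#: Physiologically plausible FHR range; samples outside it count as signal loss.
FHR_MIN_BPM = 50.0
FHR_MAX_BPM = 210.0


def _fhr_validity(fhr: np.ndarray) -> np.ndarray:
    """Valid FHR samples are finite, nonzero and inside [50, 210] bpm."""
    with np.errstate(invalid="ignore"):
        return np.isfinite(fhr) & (fhr != 0.0) & (fhr >= FHR_MIN_BPM) & (fhr <= FHR_MAX_BPM)


@dataclass
class CTGTrace:
    """Two-channel sampled CTG signal with per-sample validity masks.

    Parameters
    ----------
    fhr, uc
        Sample arrays of equal length (bpm and arbitrary units). Invalid
        samples may be NaN or 0; masks are derived on construction when not
        given.
    fs
        Sampling rate in Hz (> 0). Clinical input is 4 Hz; model input 1 Hz.
    valid_fhr, valid_uc
        Boolean masks; where omitted they are inferred (FHR: finite, nonzero,
        in [50, 210]; UC: finite).
    meta
        Free-form record identifiers.
    """

    fhr: np.ndarray
    uc: np.ndarray
    fs: float
    valid_fhr: np.ndarray | None = None
    valid_uc: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.ndim != 1 or self.uc.ndim != 1:
            raise ValueError("fhr and uc must be one-dimensional")
        if len(self.fhr) != len(self.uc):
            raise ValueError(
                f"channel length mismatch: fhr has {len(self.fhr)}, uc has {len(self.uc)}"
            )
        if len(self.fhr) < 1:
            raise ValueError("trace must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.valid_fhr is None:
            self.valid_fhr = _fhr_validity(self.fhr)
        else:
            self.valid_fhr = np.asarray(self.valid_fhr, dtype=bool)
        if self.valid_uc is None:
            self.valid_uc = np.isfinite(self.uc)
        else:
            self.valid_uc = np.asarray(self.valid_uc, dtype=bool)
        for name, mask in (("valid_fhr", self.valid_fhr), ("valid_uc", self.valid_uc)):
            if len(mask) != len(self.fhr):
                raise ValueError(f"{name} length does not match the signal length")

    def __len__(self) -> int:
        return len(self.fhr)

    @property
    def duration_s(self) -> float:
        return len(self.fhr) / self.fs

    def slice(self, start: int, stop: int) -> "CTGTrace":
        return CTGTrace(
            fhr=self.fhr[start:stop],
            uc=self.uc[start:stop],
            fs=self.fs,
            valid_fhr=self.valid_fhr[start:stop],
            valid_uc=self.valid_uc[start:stop],
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class WindowSpec:
    """End-of-record analysis window (default: the last 30 minutes)."""

    duration_s: float = 1800.0
    anchor: str = "end"

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("window duration must be positive")
        if self.anchor != "end":
            raise ValueError("only end-of-record anchoring is supported")


def compute_signal_loss(trace: CTGTrace) -> float:
    """Fraction of samples with invalid FHR, in [0, 1].

    The exclusion criterion (loss above 16%) is defined on the FHR channel,
    the signal being classified; UC validity is available separately through
    ``trace.valid_uc``.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("cannot compute signal loss of an empty trace")
    return float(np.count_nonzero(~trace.valid_fhr)) / n


def passes_quality(trace: CTGTrace, min_duration_s: float = 1800.0, max_loss: float = 0.16) -> bool:
    """Record-quality gate: duration >= ``min_duration_s`` and loss <= ``max_loss``.

    Both boundaries are inclusive — exclusion is strictly "shorter than" the
    duration floor and strictly "more than" the loss ceiling.
    """
    return trace.duration_s >= min_duration_s and compute_signal_loss(trace) <= max_loss


def extract_last_window(trace: CTGTrace, spec: WindowSpec = WindowSpec()) -> CTGTrace:
    """Extract the final ``spec.duration_s`` seconds, trimming trailing zero FHR.

    Monitors keep writing zeros after the transducer is removed; the window is
    anchored at the last nonzero (and finite) FHR sample, and trailing zeros
    are discarded before windowing.
    """
    nonzero = np.isfinite(trace.fhr) & (trace.fhr != 0.0)
    if not nonzero.any():
        raise ValueError("trace contains no nonzero FHR samples")
    last = int(np.nonzero(nonzero)[0][-1])
    trimmed = trace.slice(0, last + 1)
    n_window = int(round(spec.duration_s * trace.fs))
    if len(trimmed) < n_window:
        raise ValueError(
            f"record too short for window: {len(trimmed) / trace.fs:.0f} s available "
            f"after trailing-zero removal, {spec.duration_s:.0f} s required"
        )
    return trimmed.slice(len(trimmed) - n_window, len(trimmed))


def downsample(trace: CTGTrace, target_fs: float) -> CTGTrace:
    """Downsample by per-bin mean of valid samples.

    ``trace.fs`` must be an integer multiple of ``target_fs``. Each output
    sample is the mean of the valid input samples in its bin; bins with no
    valid sample yield NaN flagged invalid. Output length is
    ``floor(n * target_fs / fs)``.
    """
    ratio = trace.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sampling rate {trace.fs} Hz is not an integer multiple of target {target_fs} Hz"
        )
    r = int(round(ratio))
    n_out = len(trace) // r
    if n_out == 0:
        raise ValueError("trace shorter than one output bin")

    def _bin(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = values[: n_out * r].reshape(n_out, r)
        m = valid[: n_out * r].reshape(n_out, r)
        counts = m.sum(axis=1)
        sums = np.where(m, v, 0.0).sum(axis=1)
        out = np.full(n_out, np.nan)
        ok = counts > 0
        out[ok] = sums[ok] / counts[ok]
        return out, ok

    fhr, vf = _bin(trace.fhr, trace.valid_fhr)
    uc, vu = _bin(trace.uc, trace.valid_uc)
    return CTGTrace(fhr=fhr, uc=uc, fs=target_fs, valid_fhr=vf, valid_uc=vu, meta=dict(trace.meta))


def interpolate_invalid(trace: CTGTrace) -> CTGTrace:
    """Linearly interpolate invalid samples in both channels.

    Models without a mask channel need gap-free input. Interior gaps are
    linearly interpolated between the nearest valid samples; leading/trailing
    gaps take the nearest valid value. A channel with no valid sample at all
    is filled with a neutral constant (FHR 120 bpm, UC 0).
    """

    def _fill(values: np.ndarray, valid: np.ndarray, fallback: float) -> np.ndarray:
        if valid.all():
            return values.copy()
        if not valid.any():
            return np.full_like(values, fallback)
        idx = np.arange(len(values))
        return np.interp(idx, idx[valid], values[valid])

    fhr = _fill(trace.fhr, trace.valid_fhr, 120.0)
    uc = _fill(trace.uc, trace.valid_uc, 0.0)
    return CTGTrace(
        fhr=fhr,
        uc=uc,
        fs=trace.fs,
        valid_fhr=np.ones(len(trace), bool),
        valid_uc=np.ones(len(trace), bool),
        meta=dict(trace.meta),
    )


# ---------------------------------------------------------------------------
# CSV I/O — dialect: header `time_s,fhr_bpm,uc_units`, '.' decimal, UTF-8.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["time_s", "fhr_bpm", "uc_units"]


def read_ctg_csv(path: str | Path) -> CTGTrace:
    """Read a trace from CSV; sampling rate is the reciprocal median time step."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer the sampling rate")
    steps = np.diff(t)
    bad = np.nonzero(steps <= 0)[0]
    if len(bad):
        raise ValueError(f"{path}: non-monotone time at row {int(bad[0]) + 2}")
    fs = 1.0 / float(np.median(steps))
    fhr = df["fhr_bpm"].to_numpy(dtype=float)  # empty cells -> NaN -> invalid
    uc = df["uc_units"].to_numpy(dtype=float)
    return CTGTrace(fhr=fhr, uc=uc, fs=float(round(fs, 6)), meta={"source": str(path)})


def write_ctg_csv(trace: CTGTrace, path: str | Path) -> None:
    t = np.arange(len(trace)) / trace.fs
    fhr = np.where(trace.valid_fhr, trace.fhr, np.nan)
    uc = np.where(trace.valid_uc, trace.uc, np.nan)
    pd.DataFrame({"time_s": t, "fhr_bpm": fhr, "uc_units": uc}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal WFDB reader/writer (CTU-UHB dialect: format-16 int16 signal file).
# Channels are matched by description containing "FHR"/"UC", case-insensitive.
# ---------------------------------------------------------------------------


def _parse_wfdb_header(header_path: Path):
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        file_name, fmt = parts[0], parts[1]
        gain = 200.0
        baseline = 0
        m = re.match(r"([0-9.eE+-]+)(?:\(([-0-9]+)\))?", parts[2]) if len(parts) > 2 else None
        if m:
            gain = float(m.group(1)) or 200.0
            if m.group(2) is not None:
                baseline = int(m.group(2))
        description = parts[-1] if len(parts) > 3 else file_name
        signals.append(
            {"file": file_name, "fmt": fmt, "gain": gain, "baseline": baseline, "desc": description}
        )
    return record_name, n_sig, fs, n_samples, signals


def read_wfdb_record(path: str | Path) -> CTGTrace:
    """Read a CTG record in WFDB format (header + format-16 signal file).

    ``path`` is the record path without extension (or the ``.hea`` file).
    FHR and UC channels are located by description; zero FHR samples are
    flagged invalid per the CTU-UHB dropout convention.
    """
    path = Path(path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(f"WFDB header not found: {header}")
    record_name, n_sig, fs, n_samples, signals = _parse_wfdb_header(header)
    for sig in signals:
        if sig["fmt"] not in ("16", "16+0"):
            raise ValueError(f"unsupported WFDB signal format {sig['fmt']!r} (only 16 supported)")
    data_file = header.parent / signals[0]["file"]
    raw = np.fromfile(data_file, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    frames = raw.reshape(-1, n_sig)

    def _channel(keyword: str) -> int:
        for i, sig in enumerate(signals):
            if keyword.lower() in sig["desc"].lower():
                return i
        available = [s["desc"] for s in signals]
        raise ValueError(f"no channel matching {keyword!r}; available channels: {available}")

    i_fhr = _channel("FHR")
    i_uc = _channel("UC")
    fhr = (frames[:, i_fhr].astype(float) - signals[i_fhr]["baseline"]) / signals[i_fhr]["gain"]
    uc = (frames[:, i_uc].astype(float) - signals[i_uc]["baseline"]) / signals[i_uc]["gain"]
    return CTGTrace(fhr=fhr, uc=uc, fs=fs, meta={"record": record_name, "source": str(header)})


def write_wfdb_record(trace: CTGTrace, path: str | Path, gain: float = 100.0) -> None:
    """Write a trace as a two-channel WFDB format-16 record (test fixtures)."""
    path = Path(path)
    name = path.name
    n = len(trace)
    header = [f"{name} 2 {trace.fs:g} {n}"]
    for desc in ("FHR", "UC"):
        header.append(f"{name}.dat 16 {gain:g}(0)/unit 16 0 0 0 0 {desc}")
    path.with_suffix(".hea").write_text("\n".join(header) + "\n")
    fhr = np.where(trace.valid_fhr, trace.fhr, 0.0)
    uc = np.where(trace.valid_uc, trace.uc, 0.0)
    frames = np.empty((n, 2), dtype="<i2")
    frames[:, 0] = np.round(fhr * gain).astype("<i2")
    frames[:, 1] = np.round(uc * gain).astype("<i2")
    frames.tofile(path.with_suffix(".dat"))
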