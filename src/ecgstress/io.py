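"""Record containers, file formats, resampling and z-score normalization.

Two on-disk formats are supported:

* a minimal waveform-database layout — ``<name>.hea`` text header plus a
  16-bit little-endian ``<name>.dat`` signal file (gain in adu/mV) — for
  records such as the ambulatory driving corpus;
* a plain text format, one sample (mV) per line, with a ``.meta.json``
  sidecar carrying the sampling rate.

Both formats use a ``<name>.markers.csv`` sidecar with rows
``condition,start_s,end_s``; records without markers are rejected at load
time, mirroring the exclusion of unmarked subjects from the corpus.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

VALID_CONDITIONS = ("rest", "stress_city", "stress_highway", "stress_task")

#: marker condition -> binary class; anything driven/task-induced is stress
CONDITION_LABELS = {"rest": 0, "stress_city": 1, "stress_highway": 1,
                    "stress_task": 1}


class EcgLoadError(IOError):
    pass


@dataclass(frozen=True)
class Marker:
    condition: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.end_s > self.start_s >= 0:
            raise ValueError(
                f"bad marker interval [{self.start_s}, {self.end_s}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def label(self) -> int:
        return CONDITION_LABELS[self.condition]


@dataclass
class EcgRecord:
    """One subject's continuous ECG with labeled segment markers."""

    subject_id: str
    samples: np.ndarray           # mV
    fs: float                     # Hz
    markers: list[Marker]
    stressor: str                 # {driving, mental_arithmetic}

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.stressor not in ("driving", "mental_arithmetic"):
            raise ValueError(f"unknown stressor {self.stressor!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.subject_id}: non-finite samples")
        total = len(self.samples) / self.fs
        prev_end = 0.0
        for m in sorted(self.markers, key=lambda m: m.start_s):
            if m.start_s < prev_end - 1e-9:
                raise ValueError(
                    f"record {self.subject_id}: overlapping markers")
            if m.end_s > total + 1e-6:
                raise ValueError(
                    f"record {self.subject_id}: marker past end of signal")
            prev_end = m.end_s

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


# -- writers ---------------------------------------------------------------


def _write_markers(path: Path, markers: list[Marker]) -> None:
    lines = ["condition,start_s,end_s"]
    lines += [f"{m.condition},{m.start_s:.6f},{m.end_s:.6f}" for m in markers]
    path.write_text("\n".join(lines) + "\n")


def _read_markers(path: Path) -> list[Marker]:
    markers = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        cond, start, end = line.split(",")
        markers.append(Marker(cond, float(start), float(end)))
    return markers


def write_record(record: EcgRecord, directory, format: str = "text",
                 gain: float = 1000.0) -> Path:
    """Write a record; returns the primary file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.subject_id
    _write_markers(directory / f"{name}.markers.csv", record.markers)
    if format == "text":
        sig_path = directory / f"{name}.txt"
        np.savetxt(sig_path, record.samples, fmt="%.17g")
        (directory / f"{name}.meta.json").write_text(json.dumps(
            {"subject_id": name, "fs": record.fs,
             "stressor": record.stressor, "units": "mV"}, indent=1))
        return sig_path
    if format == "wfdb":
        adc = np.clip(np.round(record.samples * gain), -32768, 32767)
        adc = adc.astype("<i2")
        (directory / f"{name}.dat").write_bytes(adc.tobytes())
        checksum = int(adc.astype(np.int64).sum() % 65536)
        init = int(adc[0]) if adc.size else 0
        header = (
            f"{name} 1 {record.fs:g} {len(adc)}\n"
            f"{name}.dat 16 {gain:g}/mV 16 0 {init} {checksum} 0 ECG\n"
            f"# stressor: {record.stressor}\n")
        hea_path = directory / f"{name}.hea"
        hea_path.write_text(header)
        return hea_path
    raise ValueError(f"unknown format {format!r}")


# -- readers ---------------------------------------------------------------


def _markers_for(directory: Path, name: str) -> list[Marker]:
    marker_path = directory / f"{name}.markers.csv"
    if not marker_path.exists():
        raise EcgLoadError(
            f"record {name!r} excluded: no condition marker file "
            f"({marker_path})")
    return _read_markers(marker_path)


def _read_wfdb(path: Path) -> EcgRecord:
    directory, name = path.parent, path.stem
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    rec_name, n_sig, fs, n_samples = lines[0].split()[:4]
    sig_lines = [ln for ln in lines[1:] if not ln.startswith("#")]
    ecg_line = None
    for ln in sig_lines:
        fields = ln.split()
        if fields[-1].upper() == "ECG":
            ecg_line = fields
            break
    if ecg_line is None:
        raise EcgLoadError(f"record {name!r}: no ECG channel in header")
    fmt = ecg_line[1]
    if fmt != "16":
        raise EcgLoadError(f"record {name!r}: unsupported format {fmt}")
    gain = float(ecg_line[2].split("/")[0])
    dat_path = directory / ecg_line[0]
    adc = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    stressor = "driving"
    for ln in lines:
        if ln.startswith("# stressor:"):
            stressor = ln.split(":", 1)[1].strip()
    return EcgRecord(subject_id=rec_name, samples=adc / gain, fs=float(fs),
                     markers=_markers_for(directory, name), stressor=stressor)


def _read_text(path: Path) -> EcgRecord:
    directory, name = path.parent, path.stem
    meta_path = directory / f"{name}.meta.json"
    if not meta_path.exists():
        raise EcgLoadError(f"record {name!r}: missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    samples = np.loadtxt(path, ndmin=1)
    return EcgRecord(subject_id=meta.get("subject_id", name), samples=samples,
                     fs=float(meta["fs"]),
                     markers=_markers_for(directory, name),
                     stressor=meta.get("stressor", "mental_arithmetic"))


def read_record(path, format: str | None = None) -> EcgRecord:
    """Load a record from a ``.hea`` (wfdb) or ``.txt`` (text) file."""
    path = Path(path)
    if not path.exists():
        raise EcgLoadError(f"no such record: {path}")
    if format is None:
        format = "wfdb" if path.suffix == ".hea" else "text"
    if format == "wfdb":
        return _read_wfdb(path)
    if format == "text":
        return _read_text(path)
    raise ValueError(f"unknown format {format!r}")


def read_directory(directory) -> list[EcgRecord]:
    """Load every record in a directory, sorted by subject id."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.hea")) + sorted(directory.glob("*.txt"))
    if not paths:
        raise EcgLoadError(f"no records found in {directory}")
    return [read_record(p) for p in paths]


# -- resampling ------------------------------------------------------------


def resample(record: EcgRecord, target_fs: float = 256.0) -> EcgRecord:
    """Anti-aliased polyphase resampling; markers keep their seconds."""
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    if target_fs == record.fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(record.samples, up, down)
    n_target = int(round(len(record.samples) * target_fs / record.fs))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)), mode="edge")
    return replace(record, samples=out, fs=float(target_fs))


# -- normalization ---------------------------------------------------------


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled mean/SD of all samples of one stressor's records."""

    mu_s: float
    sigma_s: float
    stressor: str

    def __post_init__(self):
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")


def fit_norm_stats(records: list[EcgRecord]) -> NormalizationStats:
    """Pooled mean and population SD over every sample of the records."""
    if not records:
        raise ValueError("need at least one record")
    stressors = {r.stressor for r in records}
    if len(stressors) != 1:
        raise ValueError(f"records span multiple stressors: {stressors}")
    pooled = np.concatenate([r.samples for r in records])
    if pooled.size < 2:
        raise ValueError("need >= 2 pooled samples")
    sigma = float(pooled.std())  # population SD (divisor n)
    if sigma == 0:
        raise ValueError("constant signal: pooled SD is zero")
    return NormalizationStats(mu_s=float(pooled.mean()), sigma_s=sigma,
                              stressor=stressors.pop())


def apply_norm(record: EcgRecord, stats: NormalizationStats) -> EcgRecord:
    return replace(record,
                   samples=(record.samples - stats.mu_s) / stats.sigma_s)
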