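"""Fixed-width window extraction from labeled records.

Windows are non-overlapping, anchored at each labeled segment's start,
never cross a segment boundary, and remainder samples are dropped —
``floor(duration_s / window_s)`` windows per segment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .io import EcgRecord

WINDOW_CHOICES = (10, 30, 60)


@dataclass
class WindowedDataset:
    """Rank-3 window collection ``[n, w, 1]`` with labels and subject ids."""

    windows: np.ndarray          # [n, w, 1] float32
    labels: np.ndarray           # [n] int (0 rest, 1 stress)
    subject_ids: np.ndarray      # [n] str
    window_s: int
    fs: int = 256
    stressor: str | None = None
    norm_stats: tuple[float, float] | None = None  # (mu, sigma) if applied

    def __post_init__(self):
        self.windows = np.asarray(self.windows, np.float32)
        self.labels = np.asarray(self.labels, np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        w = self.window_s * self.fs
        if self.windows.ndim != 3 or self.windows.shape[2] != 1 \
                or (self.windows.shape[0] and self.windows.shape[1] != w):
            raise ValueError(
                f"windows must have shape [n, {w}, 1], "
                f"got {self.windows.shape}")
        if not (len(self.labels) == len(self.windows)
                == len(self.subject_ids)):
            raise ValueError("windows/labels/subject_ids length mismatch")
        if self.labels.size and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def width(self) -> int:
        return self.window_s * self.fs

    def subjects(self) -> list[str]:
        return sorted(set(self.subject_ids.tolist()))

    def subset(self, subject_ids) -> "WindowedDataset":
        mask = np.isin(self.subject_ids, list(subject_ids))
        return WindowedDataset(self.windows[mask], self.labels[mask],
                               self.subject_ids[mask], self.window_s,
                               self.fs, self.stressor, self.norm_stats)

    def normalized(self, mu: float, sigma: float) -> "WindowedDataset":
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return WindowedDataset((self.windows - mu) / sigma, self.labels,
                               self.subject_ids, self.window_s, self.fs,
                               self.stressor, (float(mu), float(sigma)))

    def content_hash(self) -> str:
        """Deterministic digest of windows, labels and subject ids."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.windows).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update(",".join(map(str, self.subject_ids.tolist())).encode())
        h.update(json.dumps([self.window_s, self.fs, self.stressor,
                             self.norm_stats]).encode())
        return h.hexdigest()

    def save(self, path) -> None:
        np.savez(path, windows=self.windows, labels=self.labels,
                 subject_ids=self.subject_ids.astype(str),
                 meta=np.frombuffer(json.dumps(
                     {"window_s": self.window_s, "fs": self.fs,
                      "stressor": self.stressor,
                      "norm_stats": self.norm_stats}).encode(), np.uint8))

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            norm = meta.get("norm_stats")
            return cls(data["windows"], data["labels"], data["subject_ids"],
                       meta["window_s"], meta["fs"], meta.get("stressor"),
                       tuple(norm) if norm else None)


def slice_windows(records: list[EcgRecord], window_s: int,
                  fs: int = 256) -> WindowedDataset:
    """Slice every labeled segment of every record into windows.

    Records must already be at the common sampling rate ``fs``.  Segments
    shorter than the window contribute zero windows.
    """
    if window_s not in WINDOW_CHOICES:
        raise ValueError(f"window_s must be one of {WINDOW_CHOICES}")
    w = window_s * fs
    windows, labels, subjects = [], [], []
    stressors = set()
    for rec in records:
        if rec.fs != fs:
            raise ValueError(
                f"record {rec.subject_id} is at {rec.fs} Hz; resample to "
                f"{fs} Hz before slicing")
        stressors.add(rec.stressor)
        for m in rec.markers:
            start = int(round(m.start_s * fs))
            n_win = int(m.duration_s // window_s)
            for j in range(n_win):
                lo = start + j * w
                windows.append(rec.samples[lo:lo + w])
                labels.append(m.label)
                subjects.append(rec.subject_id)
    arr = (np.stack(windows)[..., None] if windows
           else np.zeros((0, w, 1), np.float32))
    stressor = stressors.pop() if len(stressors) == 1 else None
    return WindowedDataset(arr, np.array(labels, np.int64),
                           np.array(subjects, dtype=str), window_s, fs,
                           stressor)


def label_distribution(ds: WindowedDataset) -> tuple[int, int, int]:
    """(n_rest, n_stress, n_total)."""
    n_stress = int(ds.labels.sum())
    n_total = len(ds)
    return n_total - n_stress, n_stress, n_total
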