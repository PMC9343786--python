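"""Read/write multi-channel physiological recordings, reference traces and annotations.

The on-disk session container is a plain-text columnar format: a directory
holding a ``meta.json`` manifest plus one CSV per modality (``biopotential.csv``,
``acoustic.csv``, ``motion.csv``), channels as columns. Annotations are CSV
(columns ``onset_s, offset_s, peak_time_s, peak_value, source``) or JSON;
reference traces are two-column CSV (``time_s, value``).

The reader never resamples or filters: sample counts equal the manifest
declarations, and decimation from 1000 to the canonical 250 samples/s is the
job of :mod:`cabum.preprocess`. Annotation times are seconds from recording
start and intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "ReferenceTrace",
    "ContractionAnnotations",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_reference",
    "write_reference",
]

#: decimal places written to the columnar container; the round-trip
#: quantization error is bounded by half of one unit in the last place.
_CSV_DECIMALS = 6

# label prefixes mapping channels to modalities; configurable because no
# container standard encodes modality
BIO_PREFIX = "BIO"
ACU_PREFIX = "ACU"
MOT_PREFIX = "MOT"


@dataclass
class RawRecording:
    """Multi-channel abdominal recording with sampling metadata.

    ``biopotential`` is channels x samples in microvolts (8 channels by
    default: seven sensing plus one reference electrode), ``acoustic`` is
    channels x samples in arbitrary analog units (4 channels by default),
    ``motion`` is 6 x samples (3-axis accelerometer then 3-axis gyroscope).
    """

    biopotential: np.ndarray
    acoustic: np.ndarray
    fs_signal: float = 1000.0
    motion: np.ndarray | None = None
    fs_motion: float = 50.0
    channel_labels: list[str] = field(default_factory=list)
    start_time: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.biopotential = np.atleast_2d(np.asarray(self.biopotential, dtype=float))
        self.acoustic = np.atleast_2d(np.asarray(self.acoustic, dtype=float))
        if self.motion is not None:
            self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        if self.fs_signal <= 0:
            raise ValueError("fs_signal must be positive")
        if self.biopotential.size and self.acoustic.size:
            if self.biopotential.shape[1] != self.acoustic.shape[1]:
                raise ValueError(
                    "biopotential and acoustic must share one sample count; got "
                    f"{self.biopotential.shape[1]} vs {self.acoustic.shape[1]}"
                )
        if not self.channel_labels:
            self.channel_labels = [
                f"{BIO_PREFIX}{i+1}" for i in range(self.n_biopotential)
            ] + [f"{ACU_PREFIX}{i+1}" for i in range(self.n_acoustic)]

    @property
    def n_biopotential(self) -> int:
        return 0 if self.biopotential.size == 0 else self.biopotential.shape[0]

    @property
    def n_acoustic(self) -> int:
        return 0 if self.acoustic.size == 0 else self.acoustic.shape[0]

    @property
    def n_samples(self) -> int:
        if self.biopotential.size:
            return self.biopotential.shape[1]
        if self.acoustic.size:
            return self.acoustic.shape[1]
        return 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_signal


@dataclass
class ReferenceTrace:
    """Uniform reference uterine-activity trace.

    ``kind`` is one of IUPC / TOCO (mmHg), INVU (unitless) or synthetic.
    """

    values: np.ndarray
    fs: float
    kind: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class ContractionAnnotations:
    """Sorted list of contraction intervals, half-open [onset, offset) seconds."""

    intervals: list[tuple[float, float, float, float]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        clean = []
        for i, iv in enumerate(self.intervals):
            onset, offset = float(iv[0]), float(iv[1])
            peak_t = float(iv[2]) if len(iv) > 2 and iv[2] == iv[2] else 0.5 * (onset + offset)
            peak_v = float(iv[3]) if len(iv) > 3 and iv[3] == iv[3] else float("nan")
            if onset >= offset:
                raise ValueError(f"row {i}: onset {onset} >= offset {offset}")
            if onset < 0:
                raise ValueError(f"row {i}: negative onset {onset}")
            clean.append((onset, offset, peak_t, peak_v))
        self.intervals = sorted(clean, key=lambda iv: iv[0])

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([iv[0] for iv in self.intervals])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([iv[1] for iv in self.intervals])

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets


def _fmt(a: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(np.round(np.asarray(a, dtype=float).T, _CSV_DECIMALS))


def write_recording(rec: RawRecording, path: str | Path, format_hint: str = "columnar") -> Path:
    """Write a recording to the columnar session directory format."""
    if format_hint not in ("columnar",):
        raise ValueError(f"unsupported container format: {format_hint!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "cabum-columnar-v1",
        "fs_signal": rec.fs_signal,
        "fs_motion": rec.fs_motion,
        "n_biopotential": rec.n_biopotential,
        "n_acoustic": rec.n_acoustic,
        "n_samples": rec.n_samples,
        "channel_labels": rec.channel_labels,
        "start_time": rec.start_time,
        "subject_id": rec.subject_id,
        "has_motion": rec.motion is not None,
        "csv_decimals": _CSV_DECIMALS,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.n_biopotential:
        bio_labels = [l for l in rec.channel_labels if l.startswith(BIO_PREFIX)]
        df = _fmt(rec.biopotential)
        df.columns = bio_labels[: df.shape[1]] or df.columns
        df.to_csv(path / "biopotential.csv", index=False)
    if rec.n_acoustic:
        acu_labels = [l for l in rec.channel_labels if l.startswith(ACU_PREFIX)]
        df = _fmt(rec.acoustic)
        df.columns = acu_labels[: df.shape[1]] or df.columns
        df.to_csv(path / "acoustic.csv", index=False)
    if rec.motion is not None:
        df = _fmt(rec.motion)
        df.columns = [f"{MOT_PREFIX}{i+1}" for i in range(df.shape[1])]
        df.to_csv(path / "motion.csv", index=False)
    return path


def read_recording(path: str | Path, format_hint: str = "columnar") -> RawRecording:
    """Read a recording from the columnar session directory format.

    Loading never resamples: ``fs_signal`` is taken from the manifest and
    sample counts must equal the manifest declaration.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a session directory (no meta.json): {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"unreadable session manifest: {e}") from e

    def _load(name: str) -> np.ndarray:
        f = path / name
        if not f.exists():
            return np.empty((0, 0))
        return pd.read_csv(f).to_numpy(dtype=float).T

    bio = _load("biopotential.csv")
    acu = _load("acoustic.csv")
    motion = _load("motion.csv") if meta.get("has_motion") else None
    if motion is not None and motion.size == 0:
        motion = None
    for name, arr, key in (("biopotential", bio, "n_biopotential"), ("acoustic", acu, "n_acoustic")):
        n_declared = int(meta.get(key, arr.shape[0]))
        if arr.shape[0] != n_declared:
            raise ValueError(
                f"{name}: {arr.shape[0]} channels on disk, manifest declares {n_declared}"
            )
        if arr.size and arr.shape[1] != int(meta["n_samples"]):
            raise ValueError(
                f"{name}: {arr.shape[1]} samples on disk, manifest declares {meta['n_samples']}"
            )
    if bio.size and bio.shape[0] != 8:
        warnings.warn(f"expected 8 biopotential channels, found {bio.shape[0]}", stacklevel=2)
    return RawRecording(
        biopotential=bio,
        acoustic=acu,
        fs_signal=float(meta["fs_signal"]),
        motion=motion,
        fs_motion=float(meta.get("fs_motion", 50.0)),
        channel_labels=list(meta.get("channel_labels", [])),
        start_time=meta.get("start_time", ""),
        subject_id=meta.get("subject_id", ""),
    )


_ANN_COLS = ["onset_s", "offset_s", "peak_time_s", "peak_value", "source"]


def write_annotations(ann: ContractionAnnotations, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"onset_s": a, "offset_s": b, "peak_time_s": c, "peak_value": d, "source": ann.source}
        for a, b, c, d in ann.intervals
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> ContractionAnnotations:
    """Read contraction intervals from CSV or JSON; rows are sorted on load."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text() or "[]")
        df = pd.DataFrame(rows)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=_ANN_COLS)
    if df.empty:
        return ContractionAnnotations([], source="")
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing required column {col!r}")
    intervals = []
    for i, row in df.iterrows():
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if onset >= offset:
            raise ValueError(f"row {i}: onset {onset} >= offset {offset}")
        intervals.append(
            (
                onset,
                offset,
                float(row.get("peak_time_s", np.nan)),
                float(row.get("peak_value", np.nan)),
            )
        )
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else ""
    return ContractionAnnotations(intervals, source=source)


def write_reference(ref: ReferenceTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": ref.times, "value": ref.values}).to_csv(path, index=False)
    return path


def read_reference(path: str | Path, kind: str = "synthetic") -> ReferenceTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("reference trace is not uniformly sampled")
        fs = 1.0 / dt[0]
    else:
        fs = 1.0
    return ReferenceTrace(df["value"].to_numpy(dtype=float), fs=fs, kind=kind)
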