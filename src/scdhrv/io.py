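"""Record containers and file I/O.

The package works with three on-disk artifacts:

* ECG records — either WFDB records (if the ``wfdb`` package is importable)
  or a minimal CSV dialect: one header line ``fs=<Hz>`` followed by one
  sample value (mV) per line.
* RR-interval series — two-column CSV (beat time in s, RR in ms).
* Feature tables — CSV with id/label columns plus the 13 named HRV features.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ordered names of the 13-feature combinational HRV vector.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_nn",
    "sdnn",
    "rmssd",
    "pnn50",
    "vlf",
    "hf",
    "lf_hf",
    "sd1",
    "sd1_sd2",
    "alpha_dfa",
    "difw_tf",
    "stdw_tf",
    "wdif_tf",
)

ID_COLUMNS = ("subject_id", "channel_id", "interval_index", "label")


class FormatError(ValueError):
    """Malformed input file (missing header, bad schema...)."""


class ParseError(ValueError):
    """Non-numeric or otherwise unparsable content; carries a line number."""


@dataclass(frozen=True)
class EcgRecord:
    """A sampled ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz.
    channel_id, subject_id : str
        Identifiers carried through the pipeline.
    event_time : float or None
        Seconds from record start to the event (VF/SCD onset), if known.
    truth_beats : ndarray or None
        Ground-truth R-peak times in seconds (synthetic records only).
    """

    samples: np.ndarray
    fs: float
    channel_id: str = "0"
    subject_id: str = ""
    event_time: float | None = None
    truth_beats: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise ValueError("an ECG record needs at least 2 samples")
        if self.event_time is not None and not 0 <= self.event_time <= self.duration:
            raise ValueError(
                f"event_time {self.event_time} outside record [0, {self.duration}]"
            )
        if self.truth_beats is not None:
            tb = np.asarray(self.truth_beats, dtype=float)
            if tb.size > 1 and np.any(np.diff(tb) <= 0):
                raise ValueError("truth_beats must be strictly increasing")
            object.__setattr__(self, "truth_beats", tb)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of the record with new sample values (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class RrSeries:
    """Beat times (s) and the RR/NN tachogram (ms).

    ``rr[i] = 1000 * (beat_times[i+1] - beat_times[i])`` by construction.
    """

    beat_times: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if rr.size != bt.size - 1:
            raise ValueError("len(rr) must equal len(beat_times) - 1")
        if np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr", rr)

    @classmethod
    def from_rr(cls, rr: Sequence[float], t0: float = 0.0) -> "RrSeries":
        """Build a series from RR intervals alone (beat times by cumulation)."""
        rr = np.asarray(rr, dtype=float)
        beat_times = t0 + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
        return cls(beat_times=beat_times, rr=rr)

    def __len__(self) -> int:
        return self.rr.size


@dataclass
class FeatureRow:
    subject_id: str
    channel_id: str
    interval_index: int  # 1..4 backward from the event; 0 for normal subjects
    features: dict[str, float]
    label: str  # "normal" | "scd"


@dataclass
class FeatureTable:
    """Rows of named HRV features with binary labels."""

    rows: list[FeatureRow] = field(default_factory=list)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        for row in self.rows:
            missing = set(self.feature_names) - set(row.features)
            if missing:
                raise ValueError(f"row {row.subject_id} missing features {missing}")
            if row.label not in ("normal", "scd"):
                raise ValueError(f"label must be normal/scd, got {row.label!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[FeatureRow]:
        return iter(self.rows)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with y coded 0 = normal, 1 = scd (positive class)."""
        X = np.array(
            [[r.features[name] for name in self.feature_names] for r in self.rows]
        )
        y = np.array([1 if r.label == "scd" else 0 for r in self.rows])
        return X, y

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = {
                "subject_id": r.subject_id,
                "channel_id": r.channel_id,
                "interval_index": r.interval_index,
            }
            d.update({name: r.features[name] for name in self.feature_names})
            d["label"] = r.label
            recs.append(d)
        return pd.DataFrame(recs)

    def subset(self, feature_names: Sequence[str]) -> "FeatureTable":
        names = tuple(feature_names)
        rows = [
            FeatureRow(
                r.subject_id,
                r.channel_id,
                r.interval_index,
                {n: r.features[n] for n in names},
                r.label,
            )
            for r in self.rows
        ]
        return FeatureTable(rows=rows, feature_names=names)


# ---------------------------------------------------------------------------
# ECG reading/writing


def read_ecg(path: str | Path, format: str = "csv") -> EcgRecord | list[EcgRecord]:
    """Read an ECG record from disk.

    ``format="csv"`` expects the dialect written by :func:`write_csv`:
    a ``fs=<Hz>`` header line then one mV sample per line.  ``format="wfdb"``
    requires the optional ``wfdb`` package and returns one record per signal
    channel (multi-channel Holter records contribute one observation per
    channel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> EcgRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise FormatError(f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable sampling rate {header!r}") from exc
        samples = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from exc
    return EcgRecord(samples=np.array(samples), fs=fs, subject_id=path.stem)


def write_csv(record: EcgRecord, path: str | Path) -> None:
    """Write the CSV dialect read back by :func:`read_ecg` (lossless)."""
    with open(path, "w") as fh:
        fh.write(f"fs={record.fs:g}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def _read_wfdb(path: Path) -> list[EcgRecord]:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "WFDB reading needs the optional 'wfdb' package; "
            "use the CSV dialect otherwise"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    return [  # pragma: no cover
        EcgRecord(
            samples=rec.p_signal[:, ch],
            fs=float(rec.fs),
            channel_id=str(ch),
            subject_id=rec.record_name,
        )
        for ch in range(rec.n_sig)
    ]


# ---------------------------------------------------------------------------
# Pre-event windows


def extract_pre_event_windows(record: EcgRecord, k_minutes: int) -> list[EcgRecord]:
    """Cut the ``k`` one-minute windows immediately preceding the event.

    Window ``i`` (1-based) covers ``[event_time - 60*i, event_time - 60*(i-1))``
    seconds, half-open, so window 1 is the minute closest to the event.  The
    interval index counts *backward* from the event.
    """
    if record.event_time is None:
        raise ValueError("record has no event_time; cannot cut pre-event windows")
    if record.event_time < 60.0 * k_minutes:
        raise ValueError(
            f"need {60 * k_minutes:.0f}s before the event, "
            f"record has only {record.event_time:.0f}s"
        )
    n_win = round(60.0 * record.fs)
    end_sample = round(record.event_time * record.fs)
    windows = []
    for i in range(1, k_minutes + 1):
        lo = end_sample - n_win * i
        hi = end_sample - n_win * (i - 1)
        tb = None
        if record.truth_beats is not None:
            t_lo, t_hi = lo / record.fs, hi / record.fs
            mask = (record.truth_beats >= t_lo) & (record.truth_beats < t_hi)
            tb = record.truth_beats[mask] - t_lo
        windows.append(
            EcgRecord(
                samples=record.samples[lo:hi],
                fs=record.fs,
                channel_id=record.channel_id,
                subject_id=record.subject_id,
                truth_beats=tb,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# RR series I/O


def write_rr(rr: RrSeries, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["beat_time_s", "rr_ms"])
        w.writerow([repr(float(rr.beat_times[0])), ""])
        for t, v in zip(rr.beat_times[1:], rr.rr):
            w.writerow([repr(float(t)), repr(float(v))])


def read_rr(path: str | Path) -> RrSeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["beat_time_s", "rr_ms"]:
        raise FormatError(f"{path}: expected columns beat_time_s, rr_ms")
    beat_times = df["beat_time_s"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)[1:]
    return RrSeries(beat_times=beat_times, rr=rr)


# ---------------------------------------------------------------------------
# Feature table I/O


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a stable column order."""
    _warn_duplicates(table)
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    expected = list(ID_COLUMNS[:3]) + list(FEATURE_NAMES) + ["label"]
    unknown = set(df.columns) - set(expected)
    if unknown:
        raise FormatError(f"{path}: unknown feature columns {sorted(unknown)}")
    missing = set(expected) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows = [
        FeatureRow(
            subject_id=str(rec["subject_id"]),
            channel_id=str(rec["channel_id"]),
            interval_index=int(rec["interval_index"]),
            features={name: float(rec[name]) for name in FEATURE_NAMES},
            label=str(rec["label"]),
        )
        for rec in df.to_dict("records")
    ]
    table = FeatureTable(rows=rows)
    _warn_duplicates(table)
    return table


def _warn_duplicates(table: FeatureTable) -> None:
    seen: set[tuple] = set()
    for r in table.rows:
        key = (r.subject_id, r.channel_id, r.interval_index)
        if key in seen:
            warnings.warn(f"duplicate observation {key}; keeping both")
            logger.warning("duplicate observation %s; keeping both", key)
        seen.add(key)
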