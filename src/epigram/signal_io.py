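"""Reading and writing recordings, seizure annotations, pattern-count tables
and the packaged patient manifest.

The native recording format is a small self-describing delimited text file:
``#``-prefixed header lines carry ``sampling_rate``, ``bit_depth``,
``channel_labels`` and ``start_time``; every following line is one channel,
comma-separated sample values.  Integer recordings round-trip bit-exactly.
EDF files are read through :mod:`mne` when it is installed; without it the
delimited format is the only recording backend.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelRecording",
    "SeizureAnnotation",
    "PatientManifest",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "load_manifest",
    "read_pattern_counts",
    "write_pattern_counts",
    "RecordingFormatError",
    "AnnotationError",
    "ManifestError",
]


class RecordingFormatError(ValueError):
    """Raised when a recording file cannot be parsed or is inconsistent."""


class AnnotationError(ValueError):
    """Raised for invalid seizure annotations (inverted or overlapping)."""


class ManifestError(ValueError):
    """Raised when a patient manifest is missing required columns."""


@dataclass
class MultichannelRecording:
    """A sampled multichannel signal.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array.  Integer dtype for raw amplitude
        codes, floating dtype for filtered signals.
    sampling_rate
        Samples per second, strictly positive.
    channel_labels
        One label per channel.
    bit_depth
        Source quantization depth in bits; integer samples must fit in the
        signed range of this depth.
    start_time
        Offset of the first sample, in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ()
    bit_depth: int = 16
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.samples.ndim != 2:
            raise RecordingFormatError("samples must be a channels x time matrix")
        if self.sampling_rate <= 0:
            raise RecordingFormatError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i}" for i in range(self.samples.shape[0])
            )
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise RecordingFormatError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if np.issubdtype(self.samples.dtype, np.integer):
            lo, hi = self.code_range
            if self.samples.size and (
                self.samples.min() < lo or self.samples.max() > hi
            ):
                raise RecordingFormatError(
                    f"integer samples exceed {self.bit_depth}-bit range "
                    f"[{lo}, {hi}]"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def code_range(self) -> tuple[int, int]:
        half = 1 << (self.bit_depth - 1)
        return -half, half - 1

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector for a named channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.samples[idx]


@dataclass(frozen=True, order=True)
class SeizureAnnotation:
    """A single annotated seizure, half-open interval ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise AnnotationError(
                f"onset {self.onset_s} must precede offset {self.offset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, start: float, stop: float) -> bool:
        """True if ``[start, stop)`` intersects this seizure."""
        return start < self.offset_s and stop > self.onset_s


def validate_annotations(
    annotations: Iterable[SeizureAnnotation],
) -> tuple[SeizureAnnotation, ...]:
    """Sort annotations by onset and reject overlapping events."""
    ordered = tuple(sorted(annotations, key=lambda a: a.onset_s))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.onset_s < prev.offset_s:
            raise AnnotationError(
                f"annotations overlap: [{prev.onset_s}, {prev.offset_s}) and "
                f"[{cur.onset_s}, {cur.offset_s})"
            )
    return ordered


# ---------------------------------------------------------------------------
# recording files


def write_recording(path: str | Path, recording: MultichannelRecording) -> None:
    """Write a recording in the delimited-matrix dialect."""
    path = Path(path)
    is_int = np.issubdtype(recording.samples.dtype, np.integer)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate: {recording.sampling_rate!r}\n")
        fh.write(f"# bit_depth: {recording.bit_depth}\n")
        fh.write(f"# channel_labels: {','.join(recording.channel_labels)}\n")
        fh.write(f"# start_time: {recording.start_time!r}\n")
        for row in recording.samples:
            if is_int:
                fh.write(",".join(str(int(v)) for v in row))
            else:
                fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_delimited(path: Path) -> MultichannelRecording:
    header: dict[str, str] = {}
    rows: list[np.ndarray] = []
    is_float = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise RecordingFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
                continue
            try:
                fields = line.split(",")
                if any("." in f or "e" in f or "E" in f for f in fields):
                    is_float = True
                    rows.append(np.array([float(f) for f in fields]))
                else:
                    rows.append(np.array([int(f) for f in fields], dtype=np.int64))
            except ValueError as exc:
                raise RecordingFormatError(
                    f"{path}:{lineno}: cannot parse sample row: {exc}"
                ) from None
    if not rows:
        raise RecordingFormatError(f"{path}: no sample rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise RecordingFormatError(
            f"{path}: channels have unequal lengths {sorted(lengths)}"
        )
    if "sampling_rate" not in header:
        raise RecordingFormatError(f"{path}: missing sampling_rate header")
    samples = np.vstack(
        [r.astype(np.float64) for r in rows] if is_float else rows
    )
    labels = tuple(
        s for s in header.get("channel_labels", "").split(",") if s
    )
    return MultichannelRecording(
        samples=samples,
        sampling_rate=float(header["sampling_rate"]),
        channel_labels=labels,
        bit_depth=int(header.get("bit_depth", 16)),
        start_time=float(header.get("start_time", 0.0)),
    )


def _read_edf(path: Path) -> MultichannelRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise RecordingFormatError(
            "EDF support requires the optional 'mne' backend; "
            "install it or use the delimited format"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelRecording(
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        bit_depth=16,
    )


def read_recording(
    path: str | Path, format_id: str = "auto"
) -> MultichannelRecording:
    """Read a recording.

    ``format_id`` is ``"delimited-matrix"``, ``"EDF"`` or ``"auto"``
    (suffix-based: ``.edf`` selects EDF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_id == "auto":
        format_id = "EDF" if path.suffix.lower() == ".edf" else "delimited-matrix"
    if format_id.lower() in {"edf"}:
        return _read_edf(path)
    if format_id == "delimited-matrix":
        return _read_delimited(path)
    raise ValueError(f"unknown recording format {format_id!r}")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> tuple[SeizureAnnotation, ...]:
    """Read a seizure annotation CSV with columns onset_s, offset_s[, label]."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return ()
    if df.empty and "onset_s" not in df.columns:
        return ()
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise AnnotationError(f"{path}: missing column {col!r}")
    labels = df["label"] if "label" in df.columns else ["seizure"] * len(df)
    annotations = [
        SeizureAnnotation(float(on), float(off), str(lab))
        for on, off, lab in zip(df["onset_s"], df["offset_s"], labels)
    ]
    return validate_annotations(annotations)


def write_annotations(
    path: str | Path, annotations: Iterable[SeizureAnnotation]
) -> None:
    ordered = validate_annotations(annotations)
    df = pd.DataFrame(
        {
            "onset_s": [a.onset_s for a in ordered],
            "offset_s": [a.offset_s for a in ordered],
            "label": [a.label for a in ordered],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# patient manifest

_MANIFEST_COLUMNS = (
    "patient_id",
    "n_seizures",
    "preictal_hours",
    "origin",
    "electrodes",
    "interictal_hours",
)


@dataclass
class PatientManifest:
    """Per-patient bookkeeping of the study cohort.

    Wraps a table with one row per patient: seizure count, hours of
    preictal and interictal data, seizure-origin code (F/T/O/P) and
    electrode codes (g/s/d).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ManifestError(f"manifest missing columns {missing}")
        if (self.table["n_seizures"] < 1).any():
            raise ManifestError("every patient must have at least one seizure")
        if (self.table["preictal_hours"] < 0).any() or (
            self.table["interictal_hours"] < 0
        ).any():
            raise ManifestError("hours must be non-negative")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_seizures(self) -> int:
        return int(self.table["n_seizures"].sum())

    @property
    def total_hours(self) -> float:
        """Total recorded hours (preictal + interictal) before rounding."""
        return float(
            self.table["preictal_hours"].sum()
            + self.table["interictal_hours"].sum()
        )

    @property
    def total_hours_rounded(self) -> int:
        return int(round(self.total_hours))

    def by_origin(self) -> pd.DataFrame:
        """Aggregate seizure counts and hours by seizure-origin code."""
        return self.table.groupby("origin")[
            ["n_seizures", "preictal_hours", "interictal_hours"]
        ].sum()


def load_manifest(path: str | Path | None = None) -> PatientManifest:
    """Load a patient manifest CSV; default is the packaged cohort table."""
    if path is None:
        ref = resources.files("epigram.data").joinpath("patient_manifest.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return PatientManifest(df)


# ---------------------------------------------------------------------------
# pattern-count tables


def write_pattern_counts(path: str | Path, rows: Iterable[dict]) -> None:
    """Write a pattern-count TSV.

    Each row is a mapping with keys ``window_index``, ``pattern_length``,
    ``representative_pattern_hex`` and ``count``.
    """
    df = pd.DataFrame(list(rows))
    cols = ["window_index", "pattern_length", "representative_pattern_hex", "count"]
    df = df[cols]
    df.to_csv(path, sep="\t", index=False)


def read_pattern_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["representative_pattern_hex"] = df["representative_pattern_hex"].astype(str)
    return df
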