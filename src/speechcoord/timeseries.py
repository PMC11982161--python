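"""Interval annotations and 1 Hz binary speech/silence series.

The raw material of the analysis is a pair of voice-activity annotations,
one per conversation partner, each a list of labelled intervals in seconds
(e.g., Praat's silence-annotation output with ``sounding``/``silent``
labels).  These are binarized into 1-second bins (1 = speech, 0 = silence)
and aligned within the dyad so that every downstream recurrence measure
operates on two equal-length binary series.

Conventions
-----------
* Bins are half-open ``[t, t+1)`` seconds; a partial trailing bin (< 1 s)
  is dropped, never padded.
* Under the default ``majority`` rule a bin is speech iff at least 0.5 s of
  it is covered by speech-labelled intervals (ties count as speech); the
  ``any_speech`` rule marks a bin as speech on any positive overlap.
* Recognised conversation tasks are ``introduction``, ``self_disclosure``
  and ``argumentative``.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError

TASKS = ("introduction", "self_disclosure", "argumentative")

#: Praat silence-annotation labels; anything else must come via ``label_map``.
DEFAULT_LABEL_MAP: Mapping[str, int] = {"sounding": 1, "silent": 0, "": 0}


@dataclass(frozen=True)
class IntervalAnnotation:
    """Ordered, non-overlapping labelled intervals for one participant.

    Attributes
    ----------
    intervals : tuple of (onset, offset, label)
        Times in seconds; onsets strictly increasing, offsets > onsets,
        no overlap between consecutive intervals.
    total_duration : float
        Recording length in seconds; at least the last offset.
    source_id : str
        Provenance identifier (file name, tier name, participant code).
    label_map : mapping str -> {0, 1}
        How labels binarize; stored here so :func:`binarize` needs no
        extra context.
    """

    intervals: tuple[tuple[float, float, str], ...]
    total_duration: float
    source_id: str = ""
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        prev_onset = -math.inf
        prev_offset = -math.inf
        prev = None
        for iv in self.intervals:
            onset, offset, _ = iv
            if not onset > prev_onset:
                raise FormatError(f"onsets must be strictly increasing: {prev} then {iv}")
            if not offset > onset:
                raise FormatError(f"interval offset must exceed onset: {iv}")
            if onset < prev_offset:
                raise FormatError(f"overlapping intervals: {prev} and {iv}")
            prev_onset, prev_offset, prev = onset, offset, iv
        if self.intervals and self.total_duration < self.intervals[-1][1]:
            raise FormatError(
                f"total_duration {self.total_duration} shorter than last offset "
                f"{self.intervals[-1][1]}"
            )


@dataclass(frozen=True)
class SpeechSeries:
    """One partner's 1 Hz binary speech(1)/silence(0) series."""

    values: np.ndarray
    dyad_id: str
    participant_id: str
    task: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 1:
            raise FormatError("SpeechSeries needs a non-empty 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            raise FormatError("SpeechSeries values must all be 0 or 1")
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}; expected one of {TASKS}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def speech_seconds(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class DyadSeries:
    """Two aligned partners of the same dyad and task."""

    series_a: SpeechSeries
    series_b: SpeechSeries

    def __post_init__(self) -> None:
        a, b = self.series_a, self.series_b
        if a.dyad_id != b.dyad_id or a.task != b.task:
            raise FormatError(
                f"partners disagree on dyad/task: ({a.dyad_id}, {a.task}) vs "
                f"({b.dyad_id}, {b.task})"
            )
        if a.participant_id == b.participant_id:
            raise FormatError("partners must have distinct participant_id")
        if len(a) != len(b):
            raise FormatError(f"partners must have equal length ({len(a)} vs {len(b)})")

    @property
    def n(self) -> int:
        return len(self.series_a)

    @property
    def dyad_id(self) -> str:
        return self.series_a.dyad_id

    @property
    def task(self) -> str:
        return self.series_a.task


# ---------------------------------------------------------------------------
# Reading annotations


def read_annotation(
    path: str | Path,
    tier_or_columns: str | Sequence[str] | None = None,
    label_map: Mapping[str, int] | None = None,
) -> IntervalAnnotation:
    """Read a Praat TextGrid interval tier or an interval CSV.

    Parameters
    ----------
    path
        A ``.TextGrid`` file (long text format) or a CSV with onset /
        offset / label columns.
    tier_or_columns
        For a TextGrid: the name of the interval tier to read (required
        when the file has more than one tier).  For a CSV: the three
        column names, default ``("onset", "offset", "label")``.
    label_map
        Stored on the annotation for later binarization; defaults to
        Praat's ``sounding``/``silent`` labels.
    """
    path = Path(path)
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    if path.suffix.lower() == ".textgrid":
        tier = tier_or_columns if isinstance(tier_or_columns, str) else None
        return _read_textgrid(path, tier, label_map)
    columns = tier_or_columns if tier_or_columns is not None else ("onset", "offset", "label")
    if isinstance(columns, str):
        raise ConfigurationError(
            "for CSV input, tier_or_columns must be a sequence of three column names"
        )
    return _read_interval_csv(path, tuple(columns), label_map)


def _read_interval_csv(
    path: Path, columns: tuple[str, ...], label_map: Mapping[str, int]
) -> IntervalAnnotation:
    if len(columns) != 3:
        raise ConfigurationError(f"need exactly 3 column names, got {columns}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in columns):
            raise ConfigurationError(
                f"{path} is missing columns {columns}; found {reader.fieldnames}"
            )
        on, off, lab = columns
        intervals = [(float(r[on]), float(r[off]), r[lab]) for r in reader]
    total = intervals[-1][1] if intervals else 0.0
    return IntervalAnnotation(tuple(intervals), total, source_id=path.stem, label_map=label_map)


def _read_textgrid(
    path: Path, tier: str | None, label_map: Mapping[str, int]
) -> IntervalAnnotation:
    """Parse a long-format (``ooTextFile``) TextGrid and extract one tier."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise FormatError(f"{path} does not look like a Praat TextGrid")
    # Split on tier headers; each chunk holds one tier's class, name, intervals.
    chunks = re.split(r"item\s*\[\s*\d+\s*\]\s*:", text)
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    for chunk in chunks[1:]:
        if "IntervalTier" not in chunk:
            continue
        name_m = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', chunk)
        name = name_m.group(1).replace('""', '"') if name_m else ""
        ivs: list[tuple[float, float, str]] = []
        for m in re.finditer(
            r"intervals\s*\[\s*\d+\s*\]\s*:\s*"
            r"xmin\s*=\s*([-\d.eE+]+)\s*xmax\s*=\s*([-\d.eE+]+)\s*"
            r'text\s*=\s*"((?:[^"]|"")*)"',
            chunk,
        ):
            ivs.append((float(m.group(1)), float(m.group(2)), m.group(3).replace('""', '"')))
        tiers[name] = ivs
    if not tiers:
        raise FormatError(f"{path} contains no interval tiers")
    if tier is None:
        if len(tiers) > 1:
            raise ConfigurationError(
                f"{path} has tiers {sorted(tiers)}; specify which one to read"
            )
        tier = next(iter(tiers))
    if tier not in tiers:
        raise ConfigurationError(f"tier {tier!r} not found in {path}; have {sorted(tiers)}")
    ivs = tiers[tier]
    total = ivs[-1][1] if ivs else 0.0
    return IntervalAnnotation(tuple(ivs), total, source_id=f"{path.stem}:{tier}", label_map=label_map)


# ---------------------------------------------------------------------------
# Binarization and alignment


def binarize(
    ann: IntervalAnnotation,
    rule: str = "majority",
    *,
    dyad_id: str = "",
    participant_id: str | None = None,
    task: str = "introduction",
) -> SpeechSeries:
    """Resample an annotation onto 1-second bins.

    ``floor(total_duration)`` bins are produced; bin ``t`` covers
    ``[t, t+1)``.  ``majority``: speech iff speech overlap >= 0.5 s
    (tie -> speech).  ``any_speech``: speech iff overlap > 0.
    """
    if rule not in ("majority", "any_speech"):
        raise ConfigurationError(f"unknown binarization rule {rule!r}")
    n_bins = int(math.floor(ann.total_duration))
    if n_bins < 1:
        raise FormatError(
            f"annotation of {ann.total_duration} s has no complete 1-s bin"
        )
    overlap = np.zeros(n_bins)
    for onset, offset, label in ann.intervals:
        if label not in ann.label_map:
            raise ConfigurationError(
                f"label {label!r} not in label_map {dict(ann.label_map)}"
            )
        if ann.label_map[label] != 1:
            continue
        first = int(math.floor(onset))
        last = min(int(math.ceil(offset)), n_bins)
        for t in range(first, last):
            overlap[t] += max(0.0, min(offset, t + 1) - max(onset, t))
    values = (overlap >= 0.5) if rule == "majority" else (overlap > 0)
    return SpeechSeries(
        values=values.astype(np.int8),
        dyad_id=dyad_id,
        participant_id=ann.source_id if participant_id is None else participant_id,
        task=task,
    )


def align_dyad(a: SpeechSeries, b: SpeechSeries) -> DyadSeries:
    """Pair two partners, truncating both to the shorter length."""
    if a.dyad_id != b.dyad_id or a.task != b.task:
        raise FormatError(
            f"cannot align ({a.dyad_id}, {a.task}) with ({b.dyad_id}, {b.task})"
        )
    n = min(len(a), len(b))
    if n == 0:
        raise FormatError("aligned length is 0")

    def _cut(s: SpeechSeries) -> SpeechSeries:
        if len(s) == n:
            return s
        return SpeechSeries(s.values[:n], s.dyad_id, s.participant_id, s.task)

    return DyadSeries(_cut(a), _cut(b))


# ---------------------------------------------------------------------------
# Round-trip helpers


def series_to_intervals(series: SpeechSeries) -> IntervalAnnotation:
    """Export a binary series back to labelled intervals (inverse of binarize)."""
    vals = series.values
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vals)]))
    intervals = tuple(
        (float(s), float(e), "sounding" if vals[s] else "silent")
        for s, e in zip(starts, ends)
    )
    return IntervalAnnotation(intervals, float(len(vals)), source_id=series.participant_id)


def write_series_csv(series: SpeechSeries, path: str | Path) -> None:
    """Write the series as a two-column CSV (second_index, value)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["second_index", "value"])
        for t, v in enumerate(series.values):
            w.writerow([t, int(v)])


def read_series_csv(
    path: str | Path, *, dyad_id: str, participant_id: str, task: str
) -> SpeechSeries:
    """Read back a CSV written by :func:`write_series_csv`."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "value" not in reader.fieldnames:
            raise ConfigurationError(f"{path} is not a SpeechSeries CSV")
        values = [int(r["value"]) for r in reader]
    return SpeechSeries(np.asarray(values, dtype=np.int8), dyad_id, participant_id, task)
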