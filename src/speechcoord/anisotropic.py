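"""Anisotropic line structure: directional laminarity and trapping time.

Vertical and horizontal line segments in the cross-recurrence plot mark
episodes in which one partner's momentary state is matched by a sustained
run in the other.  Treating the two directions separately ("anisotropic"
analysis) quantifies how asymmetric that mutual influence is:

* ``LAM_dir`` — fraction of recurrent points lying on lines of length
  >= l_min in the given direction (laminarity).
* ``TT_dir`` — mean length of those lines (trapping time, seconds).
* ``LAM_ARD`` / ``TT_ARD`` — absolute relative differences
  ``|ver - hor| / (ver + hor)``, the dyad-level indices of asymmetry in
  nonverbal interactional dominance (0 = symmetric influence).

Partner A occupies the horizontal axis, so a vertical line (fixed column
``i``, a run over B's time) is an episode in which A's state at second
``i`` "traps" B; vertical statistics are attributed to A's influence and
horizontal to B's.  The ARD measures are absolute, so downstream results
do not depend on this attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .recurrence import (
    CrossRecurrencePlot,
    build_crp,
    diagonal_profile,
    q_dcrp,
    recurrence_rate_global,
    recurrence_rate_los,
)
from .timeseries import DyadSeries


@dataclass(frozen=True)
class LineStatistics:
    """Directional line measures of one plot."""

    lam_ver: float
    lam_hor: float
    tt_ver: float
    tt_hor: float
    min_line_length: int
    n_ver_lines: int
    n_hor_lines: int


@dataclass(frozen=True)
class DyadMeasures:
    """One dyad-task row: the five response measures plus raw components."""

    dyad_id: str
    task: str
    rr_global: float
    rr_los: float
    q_dcrp: float
    lam_ard: float
    tt_ard: float
    line_stats: LineStatistics
    speech_time_seconds: int  # summed over both partners
    n_seconds: int


def _run_lengths(rows: np.ndarray) -> np.ndarray:
    """Lengths of all maximal runs of True along the last axis of a 2-D array."""
    padded = np.zeros((rows.shape[0], rows.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = rows
    diff = np.diff(padded, axis=1)
    starts = np.nonzero(diff == 1)
    ends = np.nonzero(diff == -1)
    return ends[1] - starts[1]


def extract_lines(matrix: np.ndarray, direction: str, l_min: int = 2) -> list[int]:
    """Lengths of maximal runs of recurrent cells with length >= l_min.

    ``vertical`` scans each column (runs over the row index), ``horizontal``
    each row.  Runs touching the plot border count at their visible length.
    """
    if l_min < 2:
        raise ConfigurationError(f"l_min must be >= 2, got {l_min}")
    mat = np.asarray(matrix, dtype=bool)
    if mat.ndim != 2:
        raise ConfigurationError("matrix must be 2-D")
    if direction == "vertical":
        rows = mat.T
    elif direction == "horizontal":
        rows = mat
    else:
        raise ConfigurationError(f"direction must be vertical|horizontal, got {direction!r}")
    lengths = _run_lengths(rows.astype(np.int8))
    return sorted(int(x) for x in lengths[lengths >= l_min])


def line_statistics(
    crp: CrossRecurrencePlot | np.ndarray, l_min: int = 2
) -> LineStatistics:
    """Laminarity and trapping time in both directions.

    Accepts a plot or a raw boolean grid.  Laminarity divides by the
    count of recurrent points (0 for an empty plot); trapping time is 0
    for a direction with no qualifying line.
    """
    mat = crp.matrix if isinstance(crp, CrossRecurrencePlot) else np.asarray(crp, dtype=bool)
    total = int(mat.sum())
    ver = extract_lines(mat, "vertical", l_min)
    hor = extract_lines(mat, "horizontal", l_min)
    return LineStatistics(
        lam_ver=sum(ver) / total if total else 0.0,
        lam_hor=sum(hor) / total if total else 0.0,
        tt_ver=float(np.mean(ver)) if ver else 0.0,
        tt_hor=float(np.mean(hor)) if hor else 0.0,
        min_line_length=l_min,
        n_ver_lines=len(ver),
        n_hor_lines=len(hor),
    )


def _ard(x: float, y: float) -> float:
    return abs(x - y) / (x + y) if (x + y) > 0 else 0.0


def lam_ard(stats: LineStatistics) -> float:
    """Absolute relative difference of directional laminarity."""
    return _ard(stats.lam_ver, stats.lam_hor)


def tt_ard(stats: LineStatistics) -> float:
    """Absolute relative difference of directional trapping time."""
    return _ard(stats.tt_ver, stats.tt_hor)


def dyad_measures(d: DyadSeries, max_lag: int = 30, l_min: int = 2) -> DyadMeasures:
    """Compute the full measure bundle for one dyad-task series pair."""
    crp = build_crp(d)
    profile = diagonal_profile(crp, max_lag=max_lag)
    stats = line_statistics(crp, l_min=l_min)
    return DyadMeasures(
        dyad_id=d.dyad_id,
        task=d.task,
        rr_global=recurrence_rate_global(crp),
        rr_los=recurrence_rate_los(crp),
        q_dcrp=q_dcrp(profile),
        lam_ard=lam_ard(stats),
        tt_ard=tt_ard(stats),
        line_stats=stats,
        speech_time_seconds=d.series_a.speech_seconds + d.series_b.speech_seconds,
        n_seconds=d.n,
    )
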