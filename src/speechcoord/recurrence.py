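"""Categorical cross-recurrence plots and diagonal profiles.

A complementary-matching cross-recurrence plot (CRP) of two binary
speech/silence series marks cell ``(j, i)`` as recurrent exactly when
partner A at second ``i`` and partner B at second ``j`` are in opposite
states (one speaks while the other is silent, i.e. XOR).  From this plot:

* ``RR_global`` — fraction of recurrent cells over the whole n x n plot:
  speech coordination across all lags.
* ``RR_LOS`` — recurrence rate on the line of synchrony (main diagonal):
  lag-zero, simultaneous coordination.
* The diagonal profile ``RR(k)`` — recurrence rate on the diagonal at
  offset ``k`` from the LOS; its left/right imbalance is summarised by
  the absolute quotient ``Q_DCRP`` (0 = balanced leading/following,
  1 = one partner leads throughout).

Lag-sign convention: positive ``k`` pairs A at time ``t`` with B at time
``t + k``, i.e. B's matching behaviour *follows* A by ``k`` seconds.

The XOR structure makes the matrix redundant for the rate measures: every
quantity here is computed directly from the two series in O(n) per
diagonal, and the dense matrix is only materialised on demand (plots,
line extraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .timeseries import DyadSeries


@dataclass(frozen=True)
class CrossRecurrencePlot:
    """Complementary-matching CRP of a dyad.

    Axis convention: column ``i`` is partner A's time index (horizontal
    axis), row ``j`` is partner B's (vertical axis).
    """

    series_a: np.ndarray
    series_b: np.ndarray
    matching_rule: str = "complementary"

    @property
    def n(self) -> int:
        return int(self.series_a.size)

    @property
    def matrix(self) -> np.ndarray:
        """Dense boolean grid, ``matrix[j, i] = a_i XOR b_j``."""
        return np.not_equal.outer(self.series_b, self.series_a)


@dataclass(frozen=True)
class DiagonalProfile:
    """Recurrence rate per lag in a window of +/- max_lag around the LOS."""

    max_lag: int
    rr_by_lag: Mapping[int, float]
    rr_left: float = field(init=False)
    rr_right: float = field(init=False)

    def __post_init__(self) -> None:
        L = self.max_lag
        lags = set(self.rr_by_lag)
        if lags != set(range(-L, L + 1)):
            raise ConfigurationError(
                f"profile must cover every lag in [-{L}, {L}]; got {sorted(lags)}"
            )
        for k, r in self.rr_by_lag.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"rate at lag {k} outside [0, 1]: {r}")
        # fsum: exact accumulation, so a mirrored profile gives
        # rr_left == rr_right bit for bit and the quotient an exact 0.
        object.__setattr__(
            self, "rr_left", math.fsum(self.rr_by_lag[k] for k in range(-L, 0)) / L
        )
        object.__setattr__(
            self, "rr_right", math.fsum(self.rr_by_lag[k] for k in range(1, L + 1)) / L
        )

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.max_lag, self.max_lag + 1)

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.rr_by_lag[k] for k in self.lags])


def build_crp(d: DyadSeries) -> CrossRecurrencePlot:
    """Build the complementary-matching plot of an aligned dyad.

    No Theiler exclusion is applied; the line of synchrony is included.
    """
    return CrossRecurrencePlot(
        series_a=d.series_a.values.copy(), series_b=d.series_b.values.copy()
    )


def recurrence_rate_global(crp: CrossRecurrencePlot) -> float:
    """Recurrent cells / n^2.

    For XOR matching this reduces to marginal counts: with ``s_a`` speech
    seconds of A and ``s_b`` of B, the recurrent cell count is
    ``s_a (n - s_b) + s_b (n - s_a)``.
    """
    n = crp.n
    sa = int(crp.series_a.sum())
    sb = int(crp.series_b.sum())
    return (sa * (n - sb) + sb * (n - sa)) / (n * n)


def recurrence_rate_los(crp: CrossRecurrencePlot) -> float:
    """Recurrence rate on the line of synchrony: fraction of t with a_t != b_t."""
    return float(np.mean(crp.series_a != crp.series_b))


def diagonal_profile(crp: CrossRecurrencePlot, max_lag: int = 30) -> DiagonalProfile:
    """Recurrence rate on each diagonal at offset k in [-L, +L].

    Each diagonal is normalised by its own length ``n - |k|`` so short
    series and large lags stay comparable.  Positive k: B follows A.
    """
    n = crp.n
    if not 1 <= max_lag < n:
        raise ConfigurationError(f"max_lag must satisfy 1 <= max_lag < n={n}; got {max_lag}")
    a, b = crp.series_a, crp.series_b
    rr: dict[int, float] = {}
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            rr[k] = float(np.mean(a[: n - k] != b[k:]))
        else:
            rr[k] = float(np.mean(a[-k:] != b[: n + k]))
    return DiagonalProfile(max_lag=max_lag, rr_by_lag=rr)


def q_dcrp(profile: DiagonalProfile) -> float:
    """Absolute quotient of the diagonal profile.

    ``|RR_right - RR_left| / (RR_right + RR_left)``, and 0 when the
    profile carries no off-LOS recurrence at all.
    """
    total = profile.rr_right + profile.rr_left
    if total == 0:
        return 0.0
    return abs(profile.rr_right - profile.rr_left) / total


# ---------------------------------------------------------------------------
# Exports


def write_crp_coordinates(crp: CrossRecurrencePlot, path: str | Path) -> None:
    """Sparse coordinate CSV (i, j) of recurrent cells."""
    js, iis = np.nonzero(crp.matrix)
    with open(path, "w", newline="") as fh:
        fh.write("i,j\n")
        for i, j in zip(iis, js):
            fh.write(f"{i},{j}\n")


def write_profile_csv(profile: DiagonalProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("lag,rr\n")
        for k, r in zip(profile.lags, profile.rates):
            fh.write(f"{k},{r}\n")
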