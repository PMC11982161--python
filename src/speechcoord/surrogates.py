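"""Pseudosynchrony baselines: shuffled surrogates and chance comparison.

Observed coordination is meaningful only relative to what two unrelated
speakers with the same speech budgets would show.  The surrogate scheme
shuffles each partner's 1-s bins independently while keeping the real
pairing and lengths ("preserving the dyadic structure"): every surrogate
retains each partner's exact total speech seconds but destroys temporal
alignment, so coordination measured on surrogates estimates the chance
level.  An alternative block mode permutes whole speech/silence runs,
preserving the dwell-time distribution as well as the marginals.

Note on RR_global: under complementary (XOR) matching the global rate is
a function of the two marginal speech counts only, so every bin-level
permutation leaves it exactly unchanged; paired comparison on RR_global
is degenerate by construction and raises the zero-variance error.  Use
RR_LOS (or the other alignment-sensitive measures) for surrogate tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .anisotropic import dyad_measures
from .errors import ConfigurationError, DegenerateDataError
from .timeseries import DyadSeries, SpeechSeries

MEASURE_NAMES = ("rr_global", "rr_los", "q_dcrp", "lam_ard", "tt_ard")


@dataclass(frozen=True)
class SurrogateResult:
    """Real value of one measure and its shuffled-surrogate distribution."""

    dyad_id: str
    task: str
    measure_name: str
    real_value: float
    surrogate_values: tuple[float, ...]
    seed: int

    @property
    def n_surrogates(self) -> int:
        return len(self.surrogate_values)

    @property
    def surrogate_mean(self) -> float:
        return float(np.mean(self.surrogate_values))


@dataclass(frozen=True)
class ChanceComparison:
    """Paired t-test of real vs surrogate-mean values across dyads."""

    task: str
    measure_name: str
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    n_dyads: int


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def shuffle_series(s: SpeechSeries, seed: int | np.random.Generator) -> SpeechSeries:
    """Uniformly random permutation of the 1-s bins (marginals preserved)."""
    rng = _rng(seed)
    return SpeechSeries(rng.permutation(s.values), s.dyad_id, s.participant_id, s.task)


def block_shuffle_series(s: SpeechSeries, seed: int | np.random.Generator) -> SpeechSeries:
    """Permute speech runs among themselves and silence runs among
    themselves, keeping the speech/silence alternation.

    Exactly preserves the dwell-time (run-length) distribution of each
    state and the total speech seconds; only the arrangement changes.
    """
    rng = _rng(seed)
    vals = s.values
    change = np.flatnonzero(np.diff(vals)) + 1
    runs = np.split(vals, change)
    speech = [r for r in runs if r[0] == 1]
    silence = [r for r in runs if r[0] == 0]
    speech = [speech[i] for i in rng.permutation(len(speech))]
    silence = [silence[i] for i in rng.permutation(len(silence))]
    rebuilt, si, zi = [], 0, 0
    for r in runs:  # original alternation pattern
        if r[0] == 1:
            rebuilt.append(speech[si])
            si += 1
        else:
            rebuilt.append(silence[zi])
            zi += 1
    return SpeechSeries(np.concatenate(rebuilt), s.dyad_id, s.participant_id, s.task)


def surrogate_dyad(
    d: DyadSeries, rng: np.random.Generator, mode: str = "shuffle"
) -> DyadSeries:
    """One surrogate: both partners shuffled independently, pairing retained."""
    if mode == "shuffle":
        fn = shuffle_series
    elif mode == "block":
        fn = block_shuffle_series
    else:
        raise ConfigurationError(f"surrogate mode must be shuffle|block, got {mode!r}")
    return DyadSeries(fn(d.series_a, rng), fn(d.series_b, rng))


def surrogate_distribution(
    d: DyadSeries,
    n_surrogates: int = 100,
    seed: int = 0,
    *,
    max_lag: int = 30,
    l_min: int = 2,
    mode: str = "shuffle",
    measures: Sequence[str] = MEASURE_NAMES,
) -> dict[str, SurrogateResult]:
    """Real measures plus ``n_surrogates`` shuffled replicates of each."""
    if n_surrogates < 1:
        raise ConfigurationError("n_surrogates must be >= 1")
    unknown = set(measures) - set(MEASURE_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown measures {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    real = dyad_measures(d, max_lag=max_lag, l_min=l_min)
    draws: dict[str, list[float]] = {m: [] for m in measures}
    for _ in range(n_surrogates):
        sm = dyad_measures(surrogate_dyad(d, rng, mode), max_lag=max_lag, l_min=l_min)
        for m in measures:
            draws[m].append(getattr(sm, m))
    return {
        m: SurrogateResult(
            dyad_id=d.dyad_id,
            task=d.task,
            measure_name=m,
            real_value=getattr(real, m),
            surrogate_values=tuple(draws[m]),
            seed=seed,
        )
        for m in measures
    }


def mean_surrogate_profile(
    d: DyadSeries, n_surrogates: int = 100, seed: int = 0, max_lag: int = 30,
    mode: str = "shuffle",
) -> np.ndarray:
    """Mean diagonal profile (rates per lag, -L..L) over shuffled surrogates."""
    from .recurrence import build_crp, diagonal_profile

    rng = np.random.default_rng(seed)
    acc = np.zeros(2 * max_lag + 1)
    for _ in range(n_surrogates):
        sur = surrogate_dyad(d, rng, mode)
        acc += diagonal_profile(build_crp(sur), max_lag=max_lag).rates
    return acc / n_surrogates


def compare_to_chance(
    results: Sequence[SurrogateResult], measure_name: str | None = None
) -> ChanceComparison:
    """Paired t-test across dyads of (real - mean surrogate) differences.

    Also reports the 95% confidence interval of the mean *real* value,
    the quantity the chance level is being compared against.
    """
    if measure_name is not None:
        results = [r for r in results if r.measure_name == measure_name]
    if len(results) < 2:
        raise ConfigurationError("need surrogate results from at least 2 dyads")
    names = {r.measure_name for r in results}
    if len(names) > 1:
        raise ConfigurationError(f"mixed measures in one comparison: {sorted(names)}")
    real = np.array([r.real_value for r in results])
    diffs = real - np.array([r.surrogate_mean for r in results])
    # Tolerance absorbs float rounding from averaging identical surrogates.
    if np.std(diffs, ddof=1) <= 1e-12 * max(1.0, float(np.abs(real).max())):
        raise DegenerateDataError(
            "real - surrogate differences have zero variance; the paired t-test "
            "is undefined (RR_global is permutation-invariant under complementary "
            "matching - use an alignment-sensitive measure)"
        )
    t_res = stats.ttest_1samp(diffs, 0.0)
    sem = stats.sem(real)
    if sem == 0:
        ci_low = ci_high = float(np.mean(real))
    else:
        ci_low, ci_high = stats.t.interval(
            0.95, len(real) - 1, loc=np.mean(real), scale=sem
        )
    tasks = {r.task for r in results}
    return ChanceComparison(
        task=tasks.pop() if len(tasks) == 1 else "mixed",
        measure_name=names.pop(),
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_dyads=len(results),
    )
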