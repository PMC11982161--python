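"""Simulated coupled turn-taking dyads and whole synthetic studies.

The generator is a coupled two-state chain in 1-second steps.  Each
partner is a speech/silence process with per-second start and stop
hazards; coupling enters multiplicatively through the *other* partner's
state ``delay_d`` seconds earlier:

* ``yield_gain`` (> 1) multiplies the stop hazard while the partner was
  speaking — the speaker yields the floor sooner;
* ``initiative_gain`` (> 1) multiplies the start hazard while the partner
  was silent — silences get filled sooner.

Both gains push the pair toward complementary (anti-phase) speech, which
is exactly the structure the recurrence measures detect: coupling raises
RR_LOS, a gain asymmetry between partners shifts the diagonal profile off
lag zero (leader-follower), and a stop-hazard asymmetry stretches one
partner's dwell times and with them the directional trapping times.
A per-second state-flip probability ``noise_eps`` models annotation noise.

Uncoupled (all gains 1, no noise), each partner is a two-state Markov
chain with stationary speech probability ``p_start / (p_start + p_stop)``.

A whole synthetic study mirrors the design the analysis expects: 50 dyads
by default, three 300-s conversation tasks per dyad, standard-normal
Extraversion/Agreeableness scores per participant that feed the coupling
parameters through log-linear coefficients, and 1-5 Likert appraisal
items generated from the traits and the *computed* lag-zero coordination
of the simulated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .anisotropic import dyad_measures
from .errors import ConfigurationError
from .timeseries import TASKS, DyadSeries, SpeechSeries


@dataclass(frozen=True)
class DyadSimConfig:
    """Parameters of one simulated dyad-task conversation.

    Defaults give each partner an uncoupled stationary speech share of
    0.08 / (0.08 + 0.12) = 0.40 (conversation leaves room for mutual
    silences) and moderate symmetric coupling, which pushes the pair
    toward complementary speech: RR_global lands near the high-0.4s and
    RR_LOS clearly above chance — the regime the five measures resolve.
    """

    n_seconds: int = 300
    p_start_a: float = 0.08
    p_start_b: float = 0.08
    p_stop_a: float = 0.12
    p_stop_b: float = 0.12
    yield_gain_a: float = 2.5
    yield_gain_b: float = 2.5
    initiative_gain_a: float = 2.5
    initiative_gain_b: float = 2.5
    delay_d: int = 1
    noise_eps: float = 0.02
    seed: int | None = None
    deterministic_complement: bool = False

    def __post_init__(self) -> None:
        if self.n_seconds < 10:
            raise ConfigurationError("n_seconds must be >= 10")
        if self.delay_d < 1:
            raise ConfigurationError("delay_d must be >= 1")
        for name in ("p_start_a", "p_start_b", "p_stop_a", "p_stop_b", "noise_eps"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        for name in ("yield_gain_a", "yield_gain_b", "initiative_gain_a", "initiative_gain_b"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def with_gains(self, yield_gain: float, initiative_gain: float) -> "DyadSimConfig":
        """Convenience: set both partners' gains symmetrically."""
        return replace(
            self,
            yield_gain_a=yield_gain,
            yield_gain_b=yield_gain,
            initiative_gain_a=initiative_gain,
            initiative_gain_b=initiative_gain,
        )

    def with_lead_asymmetry(self, factor: float) -> "DyadSimConfig":
        """Make partner A lead by ``factor``: scale B's responsiveness up
        and A's down.

        A leader initiates and is insensitive to the partner's past state;
        a follower adapts strongly to it.  Dividing A's start/stop gains by
        ``factor`` and multiplying B's pushes the recurrence mass of the
        diagonal profile onto the positive-lag side (B follows A), so
        Q_DCRP grows with ``factor``.  ``factor = 1`` is symmetric.
        Scaling acts on *both* hazard gains because one-sided start-hazard
        asymmetry alone leaves the lag profile flat in this process family
        (the extra early starts raise recurrence on both sides equally).
        """
        if factor <= 0:
            raise ConfigurationError("asymmetry factor must be positive")
        return replace(
            self,
            yield_gain_a=self.yield_gain_a / factor,
            initiative_gain_a=self.initiative_gain_a / factor,
            yield_gain_b=self.yield_gain_b * factor,
            initiative_gain_b=self.initiative_gain_b * factor,
        )


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def simulate_dyad(
    cfg: DyadSimConfig, *, dyad_id: str = "sim", task: str = "introduction"
) -> DyadSeries:
    """Simulate one dyad-task pair of coupled binary series.

    Deterministic for a given ``cfg.seed``.  With
    ``deterministic_complement`` the second partner is the exact
    complement of the first (forced anti-phase, RR_LOS = 1).
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_seconds, cfg.delay_d
    a = np.zeros(n, dtype=np.int8)
    b = np.zeros(n, dtype=np.int8)
    # Start from each chain's uncoupled stationary distribution.
    pa = cfg.p_start_a / (cfg.p_start_a + cfg.p_stop_a) if cfg.p_start_a + cfg.p_stop_a else 0.0
    pb = cfg.p_start_b / (cfg.p_start_b + cfg.p_stop_b) if cfg.p_start_b + cfg.p_stop_b else 0.0
    a[0] = rng.random() < pa
    b[0] = rng.random() < pb

    if cfg.deterministic_complement:
        for t in range(1, n):
            hazard = cfg.p_stop_a if a[t - 1] else cfg.p_start_a
            a[t] = (1 - a[t - 1]) if rng.random() < hazard else a[t - 1]
        return DyadSeries(
            SpeechSeries(a, dyad_id, "p1", task),
            SpeechSeries(1 - a, dyad_id, "p2", task),
        )

    for t in range(1, n):
        other_for_a = b[max(t - d, 0)]
        other_for_b = a[max(t - d, 0)]
        if a[t - 1]:  # A speaking: may stop, sooner if B was speaking
            h = cfg.p_stop_a * (cfg.yield_gain_a if other_for_a else 1.0)
            a[t] = 0 if rng.random() < _clip01(h) else 1
        else:  # A silent: may start, sooner if B was silent
            h = cfg.p_start_a * (1.0 if other_for_a else cfg.initiative_gain_a)
            a[t] = 1 if rng.random() < _clip01(h) else 0
        if b[t - 1]:
            h = cfg.p_stop_b * (cfg.yield_gain_b if other_for_b else 1.0)
            b[t] = 0 if rng.random() < _clip01(h) else 1
        else:
            h = cfg.p_start_b * (1.0 if other_for_b else cfg.initiative_gain_b)
            b[t] = 1 if rng.random() < _clip01(h) else 0

    if cfg.noise_eps > 0:
        a ^= (rng.random(n) < cfg.noise_eps).astype(np.int8)
        b ^= (rng.random(n) < cfg.noise_eps).astype(np.int8)
    return DyadSeries(
        SpeechSeries(a, dyad_id, "p1", task), SpeechSeries(b, dyad_id, "p2", task)
    )


@dataclass(frozen=True)
class StudySimConfig:
    """Design of a whole synthetic study (dyads x tasks, traits, appraisals).

    Trait scores (Extraversion, Agreeableness) are drawn standard normal
    per participant and mapped onto each partner's coupling parameters
    log-linearly: ``initiative_gain_i = base * task_offset *
    exp(extraversion_initiative_coef * zE_i)`` and analogously
    Agreeableness onto the yield gain.  Task offsets let conversation
    types differ in coupling (the argumentative task the most, mirroring
    the ordering the measures are meant to resolve).  Appraisal items are
    ``item_mean + trait_coef * z_trait + rrlos_coef * z(dyad-mean RR_LOS)
    + N(0, noise_sd)``, clipped to the 1-5 Likert range.
    """

    n_dyads: int = 50
    tasks: Sequence[str] = TASKS
    base: DyadSimConfig = field(default_factory=DyadSimConfig)
    task_coupling_offsets: dict = field(
        default_factory=lambda: {
            "introduction": 1.0,
            "self_disclosure": 1.1,
            "argumentative": 1.25,
        }
    )
    extraversion_initiative_coef: float = 0.25
    agreeableness_yield_coef: float = 0.15
    dyad_coupling_sd: float = 0.4  # SD of per-dyad log-normal coupling multiplier
    appraisal_items: Sequence[str] = (
        "need_to_communicate",
        "enjoyment",
        "smooth_natural_relaxed",
    )
    appraisal_item_mean: float = 3.0
    appraisal_trait_coef: float = 0.3
    appraisal_rrlos_coef: float = 0.4
    appraisal_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ConfigurationError("n_dyads must be >= 2")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ConfigurationError(f"unknown tasks {sorted(unknown)}")


@dataclass(frozen=True)
class StudyData:
    """Output of :func:`simulate_study`."""

    traits: pd.DataFrame  # one row per participant
    dyads: list[DyadSeries]  # n_dyads * n_tasks series pairs
    appraisals: pd.DataFrame  # one row per participant, one column per item


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_study(cfg: StudySimConfig) -> StudyData:
    """Simulate traits, all dyad-task series, and appraisal items.

    Fully reproducible from ``cfg.seed``; per-dyad-task streams are
    spawned from a master SeedSequence so dyads are independent.
    """
    master = np.random.SeedSequence(cfg.seed)
    ss_traits, ss_dyads, ss_appr, ss_dyadfx = master.spawn(4)
    rng_t = np.random.default_rng(ss_traits)
    # Persistent dyad-level coupling heterogeneity: some pairs simply click.
    # This is what makes measures cluster within dyads (nonzero ICC).
    dyad_mult = np.exp(
        np.random.default_rng(ss_dyadfx).normal(0.0, cfg.dyad_coupling_sd, cfg.n_dyads)
    )

    n_part = 2 * cfg.n_dyads
    traits = pd.DataFrame(
        {
            "participant_id": [f"d{i // 2:03d}_p{i % 2 + 1}" for i in range(n_part)],
            "dyad_id": [f"d{i // 2:03d}" for i in range(n_part)],
            "extraversion": _standardize(rng_t.standard_normal(n_part)),
            "agreeableness": _standardize(rng_t.standard_normal(n_part)),
        }
    )

    dyad_streams = ss_dyads.spawn(cfg.n_dyads * len(cfg.tasks))
    dyads: list[DyadSeries] = []
    for i in range(cfg.n_dyads):
        dyad_id = f"d{i:03d}"
        zE = traits.loc[traits.dyad_id == dyad_id, "extraversion"].to_numpy()
        zA = traits.loc[traits.dyad_id == dyad_id, "agreeableness"].to_numpy()
        for j, task in enumerate(cfg.tasks):
            off = cfg.task_coupling_offsets.get(task, 1.0) * dyad_mult[i]
            stream = dyad_streams[i * len(cfg.tasks) + j]
            child_seed = int(stream.generate_state(1)[0] % (2**31))
            dcfg = replace(
                cfg.base,
                initiative_gain_a=cfg.base.initiative_gain_a
                * off
                * float(np.exp(cfg.extraversion_initiative_coef * zE[0])),
                initiative_gain_b=cfg.base.initiative_gain_b
                * off
                * float(np.exp(cfg.extraversion_initiative_coef * zE[1])),
                yield_gain_a=cfg.base.yield_gain_a
                * off
                * float(np.exp(cfg.agreeableness_yield_coef * zA[0])),
                yield_gain_b=cfg.base.yield_gain_b
                * off
                * float(np.exp(cfg.agreeableness_yield_coef * zA[1])),
                seed=child_seed,
            )
            dyads.append(simulate_dyad(dcfg, dyad_id=dyad_id, task=task))

    # Appraisals consume the computed lag-zero coordination of each dyad
    # (mean over tasks), so the appraisal-model stage is testable end to end.
    rr_los_by_dyad = (
        pd.DataFrame(
            {
                "dyad_id": [d.dyad_id for d in dyads],
                "rr_los": [
                    float(np.mean(d.series_a.values != d.series_b.values)) for d in dyads
                ],
            }
        )
        .groupby("dyad_id")["rr_los"]
        .mean()
    )
    z_rr = _standardize(rr_los_by_dyad.loc[traits.dyad_id].to_numpy())
    rng_a = np.random.default_rng(ss_appr)
    appraisals = traits[["participant_id", "dyad_id"]].copy()
    for item in cfg.appraisal_items:
        raw = (
            cfg.appraisal_item_mean
            + cfg.appraisal_trait_coef * traits["extraversion"].to_numpy()
            + cfg.appraisal_rrlos_coef * z_rr
            + rng_a.normal(0.0, cfg.appraisal_noise_sd, n_part)
        )
        appraisals[item] = np.clip(raw, 1.0, 5.0)
    return StudyData(traits=traits, dyads=dyads, appraisals=appraisals)


def study_measures(
    data: StudyData, max_lag: int = 30, l_min: int = 2
) -> list:
    """Dyad-task measure bundles for every simulated series pair."""
    return [dyad_measures(d, max_lag=max_lag, l_min=l_min) for d in data.dyads]
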