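"""Tier 2: Markov-chain nest productivity simulation.

Each simulated female progresses through laying, incubation and nestling
phases day by day inside her breeding season.  On every active day the
phase's surrogate exposure metric (peak dose or a time-weighted average of
dietary concentration) is compared to its threshold — exceedance fails the
attempt that day; otherwise the nest survives the day with the phase's
background daily survival probability.  A completed nestling phase fledges
the clutch.  After success or failure the female waits the corresponding
renesting interval and starts again if a full attempt still fits in the
season and her brood limit is not exhausted.  Seasonal productivity is total
fledglings per female; risk output compares treated against no-pesticide
control simulations run on common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TierResult
from .exposure import ExposureSeries, build_exposure, twa, zero_exposure
from .synth import (
    NEST_PHASES,
    PesticideScenario,
    SpeciesProfile,
    ToxicityProfile,
)


@dataclass
class NestAttempt:
    start_day: int
    phase_log: list[tuple[str, int, int]]  # (phase, first day, last day)
    fate: str  # fledged | failed_exposure | failed_background | truncated_by_season
    fledglings: int

    def __post_init__(self) -> None:
        if self.fledglings > 0 and self.fate != "fledged":
            raise ValueError("fledglings only from a fledged attempt")


@dataclass
class SeasonOutcome:
    female_id: int
    attempts: list[NestAttempt] = field(default_factory=list)

    @property
    def total_fledglings(self) -> int:
        return sum(a.fledglings for a in self.attempts)


def _surrogate_value(exposure: ExposureSeries, metric: str, window_days: int, day: int) -> float:
    pos = exposure.pos(day)
    if metric == "peak_dose":
        return float(exposure.dose_metric[pos])
    if metric == "twa_dietary_conc":
        if exposure.diet_conc is None:
            raise ValueError("dietary concentration not computed for this series")
        # early-season windows are truncated at the series start
        window = min(window_days, pos + 1)
        return twa(exposure.diet_conc, window, pos)
    raise ValueError(f"unknown surrogate metric {metric!r}")


def _run_attempt(
    species: SpeciesProfile,
    exposure: ExposureSeries,
    tox: ToxicityProfile,
    start_day: int,
    rng: np.random.Generator,
    season_end: int,
) -> NestAttempt:
    day = start_day
    phase_log = []
    for phase in NEST_PHASES:
        dur = species.phase_durations[phase]
        ep = tox.surrogate_endpoints[phase]
        p_survive = species.daily_nest_survival[phase]
        phase_start = day
        for _ in range(dur):
            if day > season_end:
                phase_log.append((phase, phase_start, day - 1))
                return NestAttempt(start_day, phase_log, "truncated_by_season", 0)
            # exposure exceedance is evaluated before the background survival
            # draw, so a day that is lethal on both counts is logged as an
            # exposure failure
            val = _surrogate_value(exposure, ep["metric"], ep["window_days"], day)
            if val > ep["threshold"]:
                phase_log.append((phase, phase_start, day))
                return NestAttempt(start_day, phase_log, "failed_exposure", 0)
            if rng.random() > p_survive:
                phase_log.append((phase, phase_start, day))
                return NestAttempt(start_day, phase_log, "failed_background", 0)
            day += 1
        phase_log.append((phase, phase_start, day - 1))
    return NestAttempt(start_day, phase_log, "fledged", species.clutch_size)


def simulate_female(
    species: SpeciesProfile,
    exposure: ExposureSeries,
    tox: ToxicityProfile,
    rng_seed: int | np.random.Generator,
    female_id: int = 0,
    require_full_fit: bool = True,
) -> SeasonOutcome:
    """Simulate one female's breeding season.

    With ``require_full_fit`` (default) an attempt starts only if its entire
    laying-to-fledging span fits before the season end; the permissive
    alternative starts attempts any day in season and truncates them at the
    season boundary.
    """
    for phase in NEST_PHASES:
        if phase not in tox.surrogate_endpoints:
            raise ValueError(f"surrogate endpoint missing for phase {phase!r}")
    if not exposure.covers(species.season_start_day, species.season_end_day):
        raise ValueError("exposure series does not cover the breeding season")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    outcome = SeasonOutcome(female_id=female_id)
    duration = species.attempt_duration
    day = species.season_start_day
    broods = 0
    while broods < species.max_broods:
        if require_full_fit:
            if day + duration - 1 > species.season_end_day:
                break
        elif day > species.season_end_day:
            break
        attempt = _run_attempt(
            species, exposure, tox, day, rng, species.season_end_day
        )
        outcome.attempts.append(attempt)
        last_day = attempt.phase_log[-1][2]
        if attempt.fate == "fledged":
            broods += 1
            day = last_day + 1 + species.renest_wait_success
        elif attempt.fate == "truncated_by_season":
            break
        else:
            day = last_day + 1 + species.renest_wait_fail
    return outcome


def seasonal_productivity(
    species: SpeciesProfile,
    exposure: ExposureSeries,
    tox: ToxicityProfile,
    n_females: int,
    rng_seed: int,
    require_full_fit: bool = True,
) -> dict:
    """Monte-Carlo seasonal productivity over independent females.

    Returns mean, standard deviation and the per-female fledgling vector.
    Female i runs on the i-th spawned child of the seed's stream, so control
    and treated runs sharing a seed share random numbers female-for-female.
    """
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(n_females)
    per_female = np.empty(n_females, dtype=np.int64)
    for i, ss in enumerate(children):
        outcome = simulate_female(
            species,
            exposure,
            tox,
            np.random.default_rng(ss),
            female_id=i,
            require_full_fit=require_full_fit,
        )
        per_female[i] = outcome.total_fledglings
    return {
        "mean": float(per_female.mean()),
        "sd": float(per_female.std(ddof=1)) if n_females > 1 else 0.0,
        "per_female": per_female,
    }


def nest_tier(
    scenario: PesticideScenario,
    species: SpeciesProfile,
    tox: ToxicityProfile,
    exposure_variant: str = "screening",
    n_females: int = 1000,
    seed: int = 0,
    conservatism: str | None = None,
    elimination_halflife_days: float = 2.0,
    acceptable_effect: float = 0.10,
) -> TierResult:
    """Tier-2 comparison of treated versus control seasonal productivity.

    Control (no pesticide) and treated seasons share per-female random
    numbers.  The scaled effect is the proportional reduction
    1 - treated/control mean productivity (0 for a degenerate zero control,
    flagged in extras).  ``conservatism`` overrides the exposure variant's
    default residue bound (screening: upper, refined: central) for paired
    parameterization studies.
    """
    horizon = (1, 365)
    series = build_exposure(
        scenario,
        species,
        horizon=horizon,
        variant=exposure_variant,
        bound=conservatism,
        elimination_halflife_days=elimination_halflife_days,
    )
    control_series = zero_exposure(species, horizon)
    treated = seasonal_productivity(species, series, tox, n_females, seed)
    control = seasonal_productivity(species, control_series, tox, n_females, seed)

    degenerate = control["mean"] == 0.0
    m = 0.0 if degenerate else max(0.0, 1.0 - treated["mean"] / control["mean"])
    return TierResult(
        tier="nestsim",
        raw_endpoint=treated["mean"],
        units="mean seasonal productivity (fledglings/female)",
        control_endpoint=control["mean"],
        scaled_effect=m,
        decision="low_risk" if m < acceptable_effect else "escalate",
        conservatism=conservatism or ("upper" if exposure_variant == "screening" else "central"),
        seed=seed,
        extras={
            "exposure_variant": exposure_variant,
            "treated_sd": treated["sd"],
            "control_sd": control["sd"],
            "n_females": n_females,
            "degenerate_control": degenerate,
        },
    )
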