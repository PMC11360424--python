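"""Tier escalation, effect-magnitude scaling, and conservative-bias estimation.

A tiered assessment should be *efficient*: each tier's predicted effect
magnitude positively biased (conservative) relative to the truth, with the
bias shrinking as realism increases, so that a low-risk call at any tier
safely terminates the assessment.  This module operationalizes that idea:

* :func:`run_sequence` walks the four tiers (risk quotient -> nest
  productivity -> lifecycle fitness -> spatial population model) with the
  stopping rule "stop at the first low-risk tier"; only the final tier may
  conclude that a risk is unacceptable.
* :func:`scale_effect` puts tier endpoints on a common [0, 1]
  proportional-reduction scale; the risk-quotient tier is deliberately left
  off this scale (an exposure/toxicity ratio has no defensible mapping onto
  a population effect size) and participates in stopping only through its
  levels of concern.
* :func:`oracle_truth` simulates ground truth with the highest-tier model so
  that :func:`estimate_bias` can measure each nested tier's conservative
  bias E(y_hat - y) — the efficiency property is *measured*, never assumed,
  because added realism can raise as well as lower conservatism.
* :func:`paired_run` re-runs every tier with conservative (upper-bound) and
  central parameterizations, all else fixed, to isolate what the
  conservative assumptions contribute at each tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .core import TIER_ORDER, TierResult, derive_seeds, logger
from .elm import elm_tier
from .nestsim import nest_tier
from .rq import rq_tier
from .sepm import sepm_tier
from .synth import (
    Landscape,
    PesticideScenario,
    SpeciesProfile,
    ToxicityProfile,
    gen_landscape,
    gen_pesticide_scenario,
    gen_species_profile,
)


@dataclass
class RunConfig:
    """Everything one escalation run needs, in one validated bundle."""

    scenario: PesticideScenario
    species: SpeciesProfile
    tox: ToxicityProfile
    landscape: Landscape
    n_females: int = 500
    exposure_variant: str = "screening"
    elimination_halflife_days: float = 2.0
    years: int = 30
    sepm_reps: int = 10
    initial_density: float = 1.0
    acceptable_effect: float = 0.10
    locs: dict[str, float] | None = None
    #: fraction of fledglings that are female; converts tier-2 seasonal
    #: productivity (all offspring) to the female-based fecundity the
    #: lifecycle and population tiers run on
    female_fraction: float = 0.5
    master_seed: int = 0

    def validate(self) -> list[str]:
        v = []
        v += self.scenario.validate()
        v += self.species.validate()
        v += self.tox.validate()
        v += self.landscape.validate()
        if not 0 < self.acceptable_effect < 1:
            v.append("config.acceptable_effect must lie in (0, 1)")
        if self.n_females < 1:
            v.append("config.n_females must be >= 1")
        if self.years < 1 or self.sepm_reps < 1:
            v.append("config.years and config.sepm_reps must be >= 1")
        if not 0 < self.female_fraction <= 1:
            v.append("config.female_fraction must lie in (0, 1]")
        if self.exposure_variant not in ("screening", "refined"):
            v.append("config.exposure_variant must be 'screening' or 'refined'")
        return v

    def to_dict(self) -> dict[str, Any]:
        return {
            "scenario": self.scenario.to_dict(),
            "species": self.species.to_dict(),
            "tox": self.tox.to_dict(),
            "landscape": self.landscape.to_dict(),
            "n_females": self.n_females,
            "exposure_variant": self.exposure_variant,
            "elimination_halflife_days": self.elimination_halflife_days,
            "years": self.years,
            "sepm_reps": self.sepm_reps,
            "initial_density": self.initial_density,
            "acceptable_effect": self.acceptable_effect,
            "locs": self.locs,
            "female_fraction": self.female_fraction,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        d["scenario"] = PesticideScenario.from_dict(d["scenario"])
        d["species"] = SpeciesProfile.from_dict(d["species"])
        d["tox"] = ToxicityProfile.from_dict(d["tox"])
        d["landscape"] = Landscape.from_dict(d["landscape"])
        return cls(**d)


@dataclass
class EscalationReport:
    results: list[TierResult]
    stopping_tier: str | None
    final_decision: str
    acceptable_effect: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "results": [r.to_dict() for r in self.results],
            "stopping_tier": self.stopping_tier,
            "final_decision": self.final_decision,
            "acceptable_effect": self.acceptable_effect,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EscalationReport":
        d = dict(d)
        d["results"] = [TierResult.from_dict(r) for r in d["results"]]
        return cls(**d)


@dataclass
class BiasEstimate:
    """Conservative bias of one tier against oracle truth: mean(y_hat - y)."""

    tier: str
    mean_bias: float
    sd: float
    n_replicates: int
    sign_consistency: float  # fraction of replicates with positive bias

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("bias estimation needs >= 2 replicates")


def scale_effect(tier_raw: float, tier_control: float, tier: str = "nestsim") -> float:
    """Proportional reduction 1 - raw/control, clipped to [0, 1].

    This is the common effect-magnitude scale tiers 2-4 are compared on;
    the risk-quotient tier is never passed through it.
    """
    if tier == "rq":
        raise ValueError("risk quotients are not mapped onto the effect scale")
    if tier_control <= 0:
        raise ValueError("control endpoint must be > 0 to scale an effect")
    return min(1.0, max(0.0, 1.0 - tier_raw / tier_control))


def run_sequence(
    config: RunConfig,
    acceptable_effect: float | None = None,
    loc_schedule: dict[str, float] | None = None,
    seed: int | None = None,
) -> EscalationReport:
    """Run the tier sequence with the efficiency-principle stopping rule.

    Tiers run in order; the sequence stops at the first tier that renders
    low risk.  Tier 1 decides via its levels of concern; tiers 2-4 decide
    low risk when their scaled effect falls below ``acceptable_effect``.
    "Unacceptable" is only ever concluded at the final tier — lower tiers
    are conservative by design, so their exceedances merely escalate.
    """
    a = acceptable_effect if acceptable_effect is not None else config.acceptable_effect
    if not 0 < a < 1:
        raise ValueError("acceptable_effect must lie in (0, 1)")
    locs = loc_schedule if loc_schedule is not None else config.locs
    seeds = derive_seeds(seed if seed is not None else config.master_seed)
    notes: list[str] = []
    results: list[TierResult] = []

    r1 = rq_tier(config.scenario, config.species, config.tox, locs=locs or None)
    results.append(r1)
    logger.info("rq tier: decision=%s max RQ=%.4g", r1.decision, r1.raw_endpoint)
    if r1.decision == "low_risk":
        return EscalationReport(results, "rq", "low_risk", a, notes)
    if r1.decision == "indeterminate":
        notes.append("rq tier indeterminate (censored RQ bound above LOC); escalating")

    r2 = nest_tier(
        config.scenario,
        config.species,
        config.tox,
        exposure_variant=config.exposure_variant,
        n_females=config.n_females,
        seed=seeds["nestsim"],
        elimination_halflife_days=config.elimination_halflife_days,
        acceptable_effect=a,
    )
    results.append(r2)
    logger.info("nest tier: decision=%s m=%.4f", r2.decision, r2.scaled_effect)
    if r2.decision == "low_risk":
        return EscalationReport(results, "nestsim", "low_risk", a, notes)

    f_control = r2.control_endpoint * config.female_fraction
    f_treated = r2.raw_endpoint * config.female_fraction
    if f_control <= 0:
        notes.append("degenerate nest-tier control (zero productivity); sequence halted")
        return EscalationReport(results, None, "indeterminate", a, notes)

    r3 = elm_tier(
        f_control,
        f_treated,
        config.species.s_j,
        config.species.s_a,
        config.species.alpha,
        acceptable_effect=a,
        seed=seeds["elm"],
    )
    results.append(r3)
    logger.info("elm tier: decision=%s m=%.4f", r3.decision, r3.scaled_effect)
    if r3.decision == "low_risk":
        return EscalationReport(results, "elm", "low_risk", a, notes)

    r4 = sepm_tier(
        config.landscape,
        config.species,
        f_control,
        f_treated,
        years=config.years,
        reps=config.sepm_reps,
        seed=seeds["sepm"],
        initial_density=config.initial_density,
        acceptable_effect=a,
    )
    logger.info("sepm tier: decision=%s m=%.4f", r4.decision, r4.scaled_effect)
    if r4.decision == "low_risk":
        results.append(r4)
        return EscalationReport(results, "sepm", "low_risk", a, notes)
    # the highest tier cannot escalate further: its exceedance is final
    r4.decision = "unacceptable"
    results.append(r4)
    return EscalationReport(results, None, "unacceptable", a, notes)


def oracle_truth(config: RunConfig, reps: int, seed: int) -> dict[str, Any]:
    """Simulate ground-truth scaled effects with the highest-tier model.

    The nested chain (nest-tier fecundities feeding the landscape model) is
    run once to fix the stressor, then *reps* independent replicate pairs of
    treated/control trajectories yield draws of the true proportional
    reduction in realized growth.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = derive_seeds(seed)
    r2 = nest_tier(
        config.scenario,
        config.species,
        config.tox,
        exposure_variant=config.exposure_variant,
        n_females=config.n_females,
        seed=seeds["nestsim"],
        elimination_halflife_days=config.elimination_halflife_days,
    )
    f_control = r2.control_endpoint * config.female_fraction
    f_treated = r2.raw_endpoint * config.female_fraction
    if f_control <= 0:
        raise ValueError("degenerate control: zero nest-tier productivity")
    draws = np.empty(reps)
    for i in range(reps):
        res = sepm_tier(
            config.landscape,
            config.species,
            f_control,
            f_treated,
            years=config.years,
            reps=config.sepm_reps,
            seed=int((seeds["oracle"] + 7919 * i) & 0x7FFFFFFF),
            initial_density=config.initial_density,
        )
        draws[i] = res.scaled_effect
    return {
        "draws": draws,
        "mean": float(draws.mean()),
        "f_treated": f_treated,
        "f_control": f_control,
    }


def estimate_bias(
    tier_predictions: Mapping[str, Sequence[float]],
    truth: Mapping[str, Any] | Sequence[float],
) -> tuple[list[BiasEstimate], dict[str, bool]]:
    """Per-tier conservative bias against oracle truth.

    ``tier_predictions`` maps tier name to replicate predictions y_hat_i;
    ``truth`` supplies the paired true draws y_i.  Returns the per-tier
    estimates (in escalation order) and the efficiency diagnostic: whether
    every tier's mean bias is non-negative and whether the biases are
    non-increasing along the sequence.  The diagnostic is a report, not an
    assumption — added realism can push bias in either direction.
    """
    y = np.asarray(truth["draws"] if isinstance(truth, Mapping) else truth, dtype=float)
    estimates = []
    for tier in TIER_ORDER:
        if tier not in tier_predictions:
            continue
        yhat = np.asarray(tier_predictions[tier], dtype=float)
        if len(yhat) != len(y):
            raise ValueError(
                f"{tier}: {len(yhat)} predictions but {len(y)} truth draws"
            )
        diff = yhat - y
        estimates.append(
            BiasEstimate(
                tier=tier,
                mean_bias=float(diff.mean()),
                sd=float(diff.std(ddof=1)),
                n_replicates=len(diff),
                sign_consistency=float((diff > 0).mean()),
            )
        )
    biases = [e.mean_bias for e in estimates]
    diagnostic = {
        "all_nonnegative": all(b >= 0 for b in biases),
        "nonincreasing": all(b1 >= b2 - 1e-12 for b1, b2 in zip(biases, biases[1:])),
    }
    diagnostic["efficiency_holds"] = (
        diagnostic["all_nonnegative"] and diagnostic["nonincreasing"]
    )
    return estimates, diagnostic


@dataclass
class BatterySpec:
    """A family of random risk scenarios for an efficiency study.

    Each replicate draws a fresh pesticide scenario (seeded) against a fixed
    species and landscape, then evaluates every tier plus the highest-tier
    oracle on it.
    """

    name: str = "battery"
    archetype: str = "passerine"
    species_seed: int = 0
    n_applications: int = 2
    rate: float = 1.0
    half_life: float = 35.0
    landscape_kwargs: dict[str, Any] = field(
        default_factory=lambda: {
            "n_rows": 10,
            "n_cols": 10,
            "refugia_fraction": 0.3,
            "smoothing": 1.0,
            "k_max": 10,
            "dispersal_radius": 2,
        }
    )
    landscape_seed: int = 0
    n_females: int = 200
    years: int = 20
    sepm_reps: int = 2
    exposure_variant: str = "screening"
    elimination_halflife_days: float = 2.0
    female_fraction: float = 0.5


def run_battery(spec: BatterySpec, reps: int, seed: int) -> dict[str, Any]:
    """Run an efficiency study over *reps* replicate scenario draws.

    For each draw the nested tiers predict the scaled effect, the
    highest-tier model simulates the paired truth, and
    :func:`estimate_bias` summarizes the per-tier conservative bias.
    """
    if reps < 2:
        raise ValueError("an efficiency study needs >= 2 replicates")
    seeds = derive_seeds(seed)
    species = gen_species_profile(spec.archetype, spec.species_seed)
    landscape = gen_landscape(seed=spec.landscape_seed, **spec.landscape_kwargs)
    preds: dict[str, list[float]] = {"nestsim": [], "elm": [], "sepm": []}
    truth_draws = []
    for i in range(reps):
        rep_seed = int((seeds["battery"] + 104729 * i) & 0x7FFFFFFF)
        scenario, tox = gen_pesticide_scenario(
            rep_seed, spec.n_applications, spec.rate, spec.half_life
        )
        r2 = nest_tier(
            scenario,
            species,
            tox,
            exposure_variant=spec.exposure_variant,
            n_females=spec.n_females,
            seed=rep_seed,
            elimination_halflife_days=spec.elimination_halflife_days,
        )
        preds["nestsim"].append(r2.scaled_effect)
        f_c = r2.control_endpoint * spec.female_fraction
        f_t = r2.raw_endpoint * spec.female_fraction
        r3 = elm_tier(f_c, f_t, species.s_j, species.s_a, species.alpha)
        preds["elm"].append(r3.scaled_effect)
        r4 = sepm_tier(
            landscape, species, f_c, f_t,
            years=spec.years, reps=spec.sepm_reps, seed=rep_seed + 1,
        )
        preds["sepm"].append(r4.scaled_effect)
        truth = sepm_tier(
            landscape, species, f_c, f_t,
            years=spec.years, reps=spec.sepm_reps, seed=rep_seed + 2,
        )
        truth_draws.append(truth.scaled_effect)
    estimates, diagnostic = estimate_bias(preds, np.array(truth_draws))
    return {
        "name": spec.name,
        "predictions": preds,
        "truth": np.array(truth_draws),
        "bias": estimates,
        "diagnostic": diagnostic,
    }


def paired_run(config: RunConfig, seed: int) -> dict[str, Any]:
    """Conservative (upper-bound) versus central parameterization, per tier.

    Both arms share every input except the residue bound.  For the scaled
    tiers the distance is conservative minus central scaled effect; the
    risk-quotient tier reports the distance between its maximum quotients
    (its own units — quotients live off the common effect scale, which is
    why ``diminishing`` is judged over tiers 2-4 only).
    """
    seeds = derive_seeds(seed)
    arms: dict[str, dict[str, float]] = {}
    for arm, bound in (("conservative", "upper"), ("central", "central")):
        r1 = rq_tier(config.scenario, config.species, config.tox, conservatism=bound,
                     locs=config.locs or None)
        r2 = nest_tier(
            config.scenario, config.species, config.tox,
            exposure_variant=config.exposure_variant,
            n_females=config.n_females, seed=seeds["nestsim"],
            conservatism=bound,
            elimination_halflife_days=config.elimination_halflife_days,
        )
        f_c = r2.control_endpoint * config.female_fraction
        f_t = r2.raw_endpoint * config.female_fraction
        if f_c <= 0:
            raise ValueError("degenerate control: zero nest-tier productivity")
        r3 = elm_tier(f_c, f_t, config.species.s_j, config.species.s_a, config.species.alpha)
        r4 = sepm_tier(
            config.landscape, config.species, f_c, f_t,
            years=config.years, reps=config.sepm_reps, seed=seeds["sepm"],
            initial_density=config.initial_density,
        )
        arms[arm] = {
            "rq": r1.raw_endpoint,
            "nestsim": r2.scaled_effect,
            "elm": r3.scaled_effect,
            "sepm": r4.scaled_effect,
        }
    distance = {
        tier: arms["conservative"][tier] - arms["central"][tier] for tier in TIER_ORDER
    }
    scaled = [distance[t] for t in ("nestsim", "elm", "sepm")]
    return {
        "conservative": arms["conservative"],
        "central": arms["central"],
        "distance": distance,
        "diminishing": all(a >= b - 1e-12 for a, b in zip(scaled, scaled[1:])),
    }


def plot_bias_curve(estimates: Sequence[BiasEstimate], path: str | None = None):
    """Bias-versus-tier curve with +/- 1 sd whiskers from replicate spread."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tiers = [e.tier for e in estimates]
    means = [e.mean_bias for e in estimates]
    sds = [e.sd for e in estimates]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(range(len(tiers)), means, yerr=sds, marker="o", capsize=4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(range(len(tiers)), tiers)
    ax.set_xlabel("tier (increasing realism)")
    ax.set_ylabel("conservative bias  E(y_hat - y)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
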