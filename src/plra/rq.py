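"""Tier 1: risk quotients against levels of concern.

A risk quotient is the ratio of an estimated exposure to a toxicity endpoint
in matching units, screened against a level of concern (LOC): 0.5 for the
acute LD50- and LC50-based quotients, 1.0 for quotients from the avian
reproduction test.  An RQ at or below its LOC is a low-risk determination;
exceedance escalates the assessment.  Censored endpoints (LD50 reported as a
lower bound) make the RQ an *upper* bound: below the LOC that still supports
low risk, above it the comparison is indeterminate rather than an exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Endpoint, TierResult, as_endpoint
from .exposure import build_exposure
from .synth import PesticideScenario, SpeciesProfile, ToxicityProfile

#: Default levels of concern per endpoint kind.
DEFAULT_LOCS = {"acute_dose": 0.5, "acute_dietary": 0.5, "reproduction": 1.0}


@dataclass
class RiskQuotient:
    """An exposure/toxicity ratio; ``censored_upper`` marks it as an upper
    bound (denominator was a lower-bound endpoint), printed '<value'."""

    value: float
    censored_upper: bool
    endpoint_kind: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("risk quotient must be non-negative")

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.censored_upper else f"{self.value:g}"


def compute_rq(eec: float, endpoint: Endpoint | float | str) -> RiskQuotient:
    """RQ = exposure / toxicity, propagating endpoint censoring."""
    if eec < 0:
        raise ValueError("exposure estimate must be non-negative")
    ep = as_endpoint(endpoint)
    return RiskQuotient(
        value=eec / ep.value, censored_upper=ep.censored, endpoint_kind="unspecified"
    )


def loc_decision(rq: RiskQuotient, loc: float) -> str:
    """Screen one RQ against a level of concern.

    Exceedance requires RQ strictly above the LOC.  An upper-bound RQ below
    the LOC is safely low risk; above it, the true RQ could fall either side,
    so the comparison is indeterminate.
    """
    if not loc > 0:
        raise ValueError("level of concern must be > 0")
    if rq.value <= loc:
        return "low_risk"
    return "indeterminate" if rq.censored_upper else "exceeds"


def rq_tier(
    scenario: PesticideScenario,
    species: SpeciesProfile,
    tox: ToxicityProfile,
    conservatism: str = "upper",
    locs: dict[str, float] | None = None,
    horizon: tuple[int, int] = (1, 365),
) -> TierResult:
    """Run the full tier-1 screen for a scenario.

    The acute dose EEC is the peak daily dietary dose (mg a.i./kg bw/day,
    via the species intake fraction); the dietary and reproduction EECs are
    the peak diet-weighted concentration (mg a.i./kg diet).  ``conservatism``
    selects upper-bound or central nomogram residues.  The tier is low risk
    only if every endpoint's RQ is low risk at its LOC; any exceedance
    escalates; otherwise (censored bounds above their LOC) the screen is
    indeterminate, which also fails to clear the tier.
    """
    locs = dict(DEFAULT_LOCS, **(locs or {}))
    series = build_exposure(
        scenario, species, horizon=horizon, variant="screening", bound=conservatism
    )
    peak_dose = float(np.max(series.daily_dose))
    peak_conc = float(np.max(series.diet_conc))

    endpoints = {
        "acute_dose": (peak_dose, tox.ld50),
        "acute_dietary": (peak_conc, tox.lc50),
        "reproduction": (peak_conc, tox.noael),
    }
    rqs: dict[str, RiskQuotient] = {}
    decisions: dict[str, str] = {}
    for kind, (eec, ep) in endpoints.items():
        if ep is None:
            continue
        q = compute_rq(eec, ep)
        q.endpoint_kind = kind
        rqs[kind] = q
        decisions[kind] = loc_decision(q, locs[kind])
    if not rqs:
        raise ValueError("no toxicity endpoints available for the RQ tier")

    if any(d == "exceeds" for d in decisions.values()):
        overall = "escalate"
    elif any(d == "indeterminate" for d in decisions.values()):
        overall = "indeterminate"
    else:
        overall = "low_risk"

    return TierResult(
        tier="rq",
        raw_endpoint=max(q.value for q in rqs.values()),
        units="max risk quotient (dimensionless)",
        control_endpoint=None,
        scaled_effect=None,
        decision=overall,
        conservatism=conservatism,
        extras={
            "rqs": {k: {"value": q.value, "censored_upper": q.censored_upper} for k, q in rqs.items()},
            "decisions": decisions,
            "locs": locs,
            "peak_dose_mg_per_kg_bw": peak_dose,
            "peak_dietary_conc_mg_per_kg": peak_conc,
        },
    )
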