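"""Shared primitives: censoring-aware endpoints, tier results, seed derivation.

Toxicity endpoints from standard avian tests are frequently censored: an
acute oral study that kills fewer than half the birds at the highest dose
tested reports the LD50 as a lower bound (">2250 mg/kg bw").  Censoring has
to be carried through every ratio built on such an endpoint, because a risk
quotient computed from a lower-bound denominator is itself an *upper* bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

logger = logging.getLogger("plra")

#: Canonical tier ordering of the escalation sequence.
TIER_ORDER = ("rq", "nestsim", "elm", "sepm")

#: Decisions a tier can render.
DECISIONS = ("low_risk", "escalate", "unacceptable", "indeterminate")


@dataclass(frozen=True)
class Endpoint:
    """A toxicity endpoint that may be left-censored at the highest tested level.

    ``censored=True`` means *value* is a lower bound on the true endpoint
    (printed ">value" in study summaries); the true toxicity threshold is at
    least this high, i.e. the chemical is at most this toxic.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"endpoint must be positive, got {self.value}")

    def __str__(self) -> str:  # mirrors study-report notation
        return f">{self.value:g}" if self.censored else f"{self.value:g}"


def as_endpoint(x: "Endpoint | float | str") -> Endpoint:
    """Coerce a raw number or '>123'-style string to an :class:`Endpoint`."""
    if isinstance(x, Endpoint):
        return x
    if isinstance(x, str):
        s = x.strip()
        if s.startswith(">"):
            return Endpoint(float(s[1:]), censored=True)
        return Endpoint(float(s))
    return Endpoint(float(x))


@dataclass
class TierResult:
    """Outcome of one tier of the escalation sequence.

    ``scaled_effect`` is the tier's effect magnitude rescaled to a common
    [0, 1] proportional-reduction scale so tiers can be compared; it is None
    for the risk-quotient tier, whose output (a ratio of exposure to
    toxicity) has no defensible mapping onto a population-level effect size.
    """

    tier: str
    raw_endpoint: float
    units: str
    control_endpoint: float | None
    scaled_effect: float | None
    decision: str
    conservatism: str = "upper"
    seed: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")
        if self.scaled_effect is None and self.tier != "rq":
            raise ValueError(f"scaled_effect required for tier {self.tier!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "tier": self.tier,
            "raw_endpoint": self.raw_endpoint,
            "units": self.units,
            "control_endpoint": self.control_endpoint,
            "scaled_effect": self.scaled_effect,
            "decision": self.decision,
            "conservatism": self.conservatism,
            "seed": self.seed,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TierResult":
        return cls(**d)


# Fixed labels for the master-seed -> per-module seed derivation.  The scheme
# is a simple documented counter: label i receives the i-th 31-bit word of the
# numpy SeedSequence keyed on the master seed.
SEED_LABELS = (
    "scenario",
    "species",
    "landscape",
    "rq",
    "nestsim",
    "elm",
    "sepm",
    "oracle",
    "battery",
)


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Derive one reproducible 31-bit seed per pipeline stage from a master seed."""
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    words = np.random.SeedSequence(master_seed).generate_state(len(SEED_LABELS))
    return {
        label: int(w & 0x7FFFFFFF) for label, w in zip(SEED_LABELS, words)
    }
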