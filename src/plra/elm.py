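"""Tier 3: lifecycle fitness from annual vital rates.

For a temperate passerine-like lifecycle (first breeding at age 1, constant
adult survival s_a, juvenile survival s_j, annual fecundity f in female
offspring), two closed-form fitness measures follow from the female-based
lifecycle graph:

    LRS      = f * s_j / (1 - s_a)      expected lifetime reproductive success
    lambda_f = s_a + f * s_j            expected annual production of genetic
                                        descendants, including self

LRS is linear in f, so any proportional fecundity reduction passes through
to lifetime reproductive success unchanged; lambda_f has the adult-survival
term as a floor, so the same fecundity reduction always produces a smaller
proportional drop in annual fitness.  ``lambda_general`` extends lambda_f to
delayed maturity (first breeding at age alpha, pre-breeders surviving at
s_a), the eagle-like end of the avian lifecycle spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .core import TierResult

#: Annual fitness below this is insufficient for self-replacement.
REPLACEMENT_LAMBDA = 1.0


@dataclass
class FitnessResult:
    """Fitness measures with the vital rates they came from.  ``f`` and
    ``lrs`` share whatever offspring-sex convention the inputs use
    (female-only in the packaged gnatcatcher rates)."""

    lrs: float
    lambda_f: float
    f: float
    s_j: float
    s_a: float
    alpha: int = 1

    @property
    def below_replacement(self) -> bool:
        return self.lambda_f < REPLACEMENT_LAMBDA


def _check_rates(f: float, s_j: float, s_a: float) -> None:
    if f < 0:
        raise ValueError("fecundity f must be >= 0")
    if not 0 <= s_j <= 1:
        raise ValueError("s_j must be a probability")
    if s_a < 0:
        raise ValueError("s_a must be non-negative")


def lrs(f: float, s_j: float, s_a: float) -> float:
    """Expected lifetime reproductive success f*s_j/(1 - s_a).

    Diverges as adult survival approaches 1 (an immortal adult breeds
    forever), so s_a must be strictly below 1.
    """
    _check_rates(f, s_j, s_a)
    if s_a >= 1:
        raise ValueError("s_a must be < 1 for a finite lifetime")
    return f * s_j / (1.0 - s_a)


def lambda_f(f: float, s_j: float, s_a: float) -> float:
    """Intrinsic annual fitness s_a + f*s_j (self plus recruited offspring)."""
    _check_rates(f, s_j, s_a)
    if s_a > 1:
        raise ValueError("s_a must be a probability")
    return s_a + f * s_j


def fitness(f: float, s_j: float, s_a: float, alpha: int = 1) -> FitnessResult:
    """Bundle LRS and lambda for one parameterization."""
    lam = lambda_f(f, s_j, s_a) if alpha == 1 else lambda_general(f, s_j, s_a, alpha)
    return FitnessResult(lrs=lrs(f, s_j, s_a), lambda_f=lam, f=f, s_j=s_j, s_a=s_a, alpha=alpha)


def lambda_general(f: float, s_j: float, s_a: float, alpha: int = 1) -> float:
    """Annual fitness with first breeding delayed to age *alpha*.

    Pre-breeders survive at s_a after their first year, giving the
    characteristic equation

        lambda^alpha = s_a * lambda^(alpha-1) + f * s_j * s_a^(alpha-1)

    whose unique positive root is returned (bracketed root-finding, residual
    below 1e-12).  alpha = 1 reduces exactly to s_a + f*s_j.
    """
    _check_rates(f, s_j, s_a)
    if s_a > 1:
        raise ValueError("s_a must be a probability")
    if alpha < 1 or int(alpha) != alpha:
        raise ValueError("alpha must be an integer >= 1")
    alpha = int(alpha)
    if alpha == 1:
        return s_a + f * s_j
    recruit = f * s_j * s_a ** (alpha - 1)
    if recruit == 0.0:
        if s_a == 0.0:
            warnings.warn("all-zero vital rates: fitness is 0", stacklevel=2)
            return 0.0
        return s_a  # no reproduction: fitness is bare survival

    def g(lam: float) -> float:
        return lam**alpha - s_a * lam ** (alpha - 1) - recruit

    hi = s_a + f * s_j + 1.0  # g(hi) > 0 since hi > s_a and hi >= 1 term-wise
    lam = brentq(g, 1e-12, hi, xtol=1e-15, rtol=8.9e-16)
    assert abs(g(lam)) < 1e-12
    return float(lam)


def elm_tier(
    control_f: float,
    treated_f: float,
    s_j: float,
    s_a: float,
    alpha: int = 1,
    acceptable_effect: float = 0.10,
    seed: int | None = None,
) -> TierResult:
    """Tier-3 fitness comparison driven by tier-2 fecundity output.

    Reports proportional reductions in both fitness measures:
    m_LRS = 1 - LRS(treated)/LRS(control), which equals the fecundity
    reduction exactly by linearity, and m_lambda = 1 - lambda(treated)/
    lambda(control), which is never larger because survival floors the
    annual measure.  The tier's scaled effect is m_lambda — the annual
    measure carried forward into the population tier.
    """
    if control_f <= 0:
        raise ValueError("control fecundity must be > 0")
    if treated_f < 0:
        raise ValueError("treated fecundity must be >= 0")
    control = fitness(control_f, s_j, s_a, alpha)
    treated = fitness(treated_f, s_j, s_a, alpha)
    m_lrs = 1.0 - treated.lrs / control.lrs
    m_lambda = 1.0 - treated.lambda_f / control.lambda_f if control.lambda_f > 0 else 0.0
    m = min(1.0, max(0.0, m_lambda))
    return TierResult(
        tier="elm",
        raw_endpoint=treated.lambda_f,
        units="intrinsic annual fitness lambda_f",
        control_endpoint=control.lambda_f,
        scaled_effect=m,
        decision="low_risk" if m < acceptable_effect else "escalate",
        seed=seed,
        extras={
            "m_lrs": m_lrs,
            "m_lambda": m_lambda,
            "treated_lrs": treated.lrs,
            "control_lrs": control.lrs,
            "treated_below_replacement": treated.below_replacement,
            "f_control": control_f,
            "f_treated": treated_f,
            "s_j": s_j,
            "s_a": s_a,
            "alpha": alpha,
        },
    )
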