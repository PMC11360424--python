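# Methods

This note records the models, the parameter choices that matter, and the
design decisions made where the design was genuinely open.

## Exposure model

Dietary residues on each item class (short grass, tall grass,
broadleaf/small insects, fruits/pods/large insects, seeds) are initialized
at `application_rate × RUD` on each application day and decay first-order
with the foliar dissipation half-life; multiple applications are additive
and exposure before the first application is exactly zero. The default RUD
(residue per unit application rate) table is the Kenaga/Fletcher nomogram
pair (upper bound, central): 240/85, 110/36, 135/45, 15/7, 15/7 mg/kg diet
per lb a.i./acre. It is an argument, not a constant, so measured residue
data can replace it.

The daily dose bridge is `dose = intake_fraction × Σ_c diet_fraction_c ×
C_c(t)` (mg a.i./kg bw/day, since intake is g food per g body weight per
day). Two variants feed the nest tier:

* **screening** — upper-bound RUDs, external daily dose;
* **refined** — central RUDs plus first-order elimination kinetics,
  `B(t) = B(t−1)·e^(−k_e) + dose(t)`, with the body burden as the dose
  metric. Slow elimination accumulates an internal dose above any single
  day's intake, so refinement can *raise* as well as lower conservatism
  depending on the elimination half-life (default 2 days, a mid-range
  avian clearance; configurable everywhere it is used).

Time-weighted averages are discrete arithmetic means of daily values over a
trailing window — simpler than a continuous integral, exactly testable, and
consistent with the daily time step. Windows that would extend before the
series raise; within the nest simulator an early-season window is truncated
at the series start rather than failing mid-simulation.

All time is 1-based day-of-year with closed intervals.

## Tier 1: risk quotients

EECs are the peak daily dose (acute oral) and peak diet-weighted
concentration (dietary, reproduction) over the horizon. The LOC schedule is
0.5 for LD50/LC50 quotients and 1.0 for reproduction quotients; exceedance
requires strictly RQ > LOC, so RQ = LOC is low risk. A censored endpoint
(lower bound) makes its RQ an upper bound: below the LOC it still supports
low risk, above it the tier is indeterminate (which does not clear the
screen). The tier decision is the conjunction over endpoint kinds — the
most conservative aggregation, appropriate for a screen. Converting dietary
intake to a mg/kg-bw dose via the species intake fraction is a convention
of this package; regulatory EEC mechanics differ in detail.

Applying this schedule to the packaged 13-pesticide screening table flags
five compounds (chlorpyrifos, dimethoate, lambda-cyhalothrin, malathion,
methomyl); the set is regression-locked in the tests.

## Tier 2: nest productivity

Three phases (laying, incubation, nestling) with configurable durations;
daily nest survival is phase-specific and constant within a phase. Each
active day the phase's surrogate endpoint is evaluated first (exposure
exceedance fails the attempt and is labelled as such), then the background
survival draw; the ordering only affects fate labels, not productivity.
Renesting is deterministic when time and the brood limit allow —
`max_broods` caps *successful* broods, failures renest freely within the
season. A new attempt starts only if its full span fits before the season
end (conservative-completion rule); a start-anytime alternative that
truncates at the season boundary is available via `require_full_fit=False`.
Control and treated seasons share per-female random streams (common random
numbers), so a control-vs-control comparison is exactly zero and
treated-control differences are low-variance.

The Monte-Carlo calibration case — one 24-day attempt at uniform daily
survival 0.98, clutch 4 — has closed-form mean `4 × 0.98^24 ≈ 2.46` and is
checked at n = 10,000 females within 3 standard errors.

## Tier 3: lifecycle fitness

`LRS = f·s_j/(1 − s_a)` and `λ_f = s_a + f·s_j` for first breeding at age
1. LRS is linear in f, so halving fecundity halves LRS for any survival
rates — an identity, property-tested over 1,000 random draws. λ_f has the
adult-survival floor, so the proportional λ reduction never exceeds the
proportional LRS reduction; the tier carries λ forward as its scaled
effect because it is the measure the population tier realizes.

Delayed maturity solves `λ^α = s_a·λ^(α−1) + f·s_j·s_a^(α−1)` (pre-breeders
survive at s_a after year 1, the simplest lifecycle spanning the
passerine/eagle contrast; a stage-specific survival vector would override
it) by bracketed root-finding to residual < 1e−12, cross-checked against
dominant eigenvalues of the equivalent Leslie-type projection matrices to
1e−9 on 100 random draws.

With the packaged gnatcatcher rates (s_j = 0.4314, s_a = 0.52, f = 2.26):
LRS = 2.0312 and λ_f = 1.495; at the stressed fecundity f = 0.65,
λ_f = 0.8004 (prints 0.8) and LRS = 0.5842 by the closed form. A published
companion value of 0.4852 for this LRS is inconsistent with the closed form
(it appears to be a digit transposition) and is not reproduced.

## Tier 4: spatial population model

Female-only annual steps on a square grid. Habitat quality q ∈ [0, 1]
scales fecundity (default; a quality-on-survival option exists) and sets
the ceiling K = round(q·k_max). Per cell: Poisson fledglings at the
effective fecundity (treated cells use the reduced treated fecundity,
refugia the background rate), binomial juvenile survival to recruitment,
binomial adult survival. Recruits settle natally first (recruits of one
cell are exchangeable, so bulk natal settlement equals per-recruit order),
then overflow recruits — globally shuffled each year — search cells within
a Chebyshev dispersal radius in random per-recruit order; unsettled
recruits die. Density dependence and movement limitation are therefore
emergent, not imposed. Extinction is absorbing.

Nesting check: one cell with unlimited K realizes one-year growth within
Monte-Carlo error of λ_f, so the population tier strictly contains the
lifecycle tier. At carrying capacity the realized growth is ≈ 1 regardless
of λ_f > 1 — the population model reports the minimum fitness required for
persistence, one of the ways a *more* realistic tier can look *more*
conservative on a fitness scale.

Default study landscape: 20×20 cells, smoothing 1.0 (Gaussian blur of a
uniform field, min-max rescaled to [0, 1]), k_max 25 females/ideal cell,
dispersal radius 2, initial density 1.0 — a few thousand females, large
enough that demographic stochasticity does not dominate but small enough
that 50 replicates of 50 years run in seconds. No published dispersal
distances or capacities exist for the motivating system; these are this
package's documented defaults.

## Escalation, scaling, bias

Tiers 2–4 are compared on the proportional-reduction scale
`m = 1 − treated/control`, clipped to [0, 1]. The RQ tier is deliberately
excluded from this scale (an exposure/toxicity ratio has no defensible
mapping onto a population effect magnitude) and participates in stopping
only through its LOCs. The sequence stops at the first low-risk tier;
tiers 2–4 call low risk when m < `acceptable_effect` (default 0.10, a
conventional population-assessment choice; there is no canonical value).
"Unacceptable" is concluded only at the final tier, because lower tiers
are conservative by design and their exceedances merely escalate.

The nested hand-off multiplies tier-2 seasonal productivity by
`female_fraction` (default 0.5, a 1:1 fledgling sex ratio) to obtain the
female-based fecundity tiers 3–4 run on.

Oracle truth is simulated with the highest-tier model on the same nested
chain; per-tier conservative bias is the paired sample mean of ŷ − y with
its sd and sign consistency. The efficiency diagnostic (all biases
non-negative and non-increasing with tier) is *reported*: batteries of
weak-stressor scenarios routinely break monotonicity because the [0, 1]
clipping of noisy near-zero spatial-tier effects induces a small positive
bias at the top tier while lower tiers sit at zero.

Paired conservative/central runs vary only the residue bound (upper vs
central RUD), holding seeds and everything else fixed, and report the
per-tier distance between arms; for the RQ tier the distance is in RQ
units and is excluded from the diminishing-with-tier judgement.

## Synthetic data

Generated species are two archetypes: a passerine (α = 1, May–July season,
clutch 3–5, s_a ≈ 0.5) and a long-lived bird (α = 6, high adult survival,
clutch 2, single brood), with seeded trait jitter so batteries are not
degenerate. Generated toxicity profiles draw lognormal endpoints around
moderately toxic centers and censor at the top test levels (2250 mg/kg bw
acute, 5620 mg/kg diet dietary). Landscapes are smoothed uniform random
fields with a seeded random refugia subset. All generators are pure
functions of seed and parameters.

What the generator does *not* emulate: correlated exposure across diet
classes from measured residue studies, real land-cover structure,
off-field foraging, non-dietary exposure routes, and survival-route
toxicity. Passing tests therefore demonstrate internal consistency of the
tier logic under controlled conditions, not predictive accuracy for any
real landscape or chemical.

## Reproducibility and numerics

A master seed derives one 31-bit seed per pipeline stage from a fixed label
list via numpy's `SeedSequence`; per-female and per-replicate streams are
spawned children, so runs are bitwise reproducible. Reports serialize
floats at 10 significant digits (byte-identical re-runs); configs at full
precision (exact round-trip). Degenerate cases: zero-control productivity
flags the nest tier and halts the sequence as indeterminate; an all-zero
landscape starts extinct; all-zero vital rates return zero fitness with a
warning.

## Known limitations

* The nest phase set is fixed at three phases (egg development and
  pair-formation sub-phases are not modelled); surrogate-endpoint selection
  is an input, not a derivation from test data.
* No probabilistic exposure distributions — conservatism enters through the
  upper/central residue bound only.
* The spatial model is a minimal grid SEPM: no hexagonal geometry, no
  habitat maps, no survival stressor wired end-to-end.
* Bias estimation treats the highest tier as truth; if the spatial model
  itself is misspecified for a real system, measured biases inherit that
  misspecification.
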