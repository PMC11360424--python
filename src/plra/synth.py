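"""Synthetic study inputs: species profiles, pesticide scenarios, landscapes.

Every downstream tier consumes one or more of the record types defined here.
The generators are pure functions of their seed and parameters so that whole
assessments are bitwise reproducible, and the packaged fixture tables carry
the published comparison values (a 13-pesticide risk-quotient screen and the
California gnatcatcher ideal-habitat vital rates) for regression testing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Endpoint, as_endpoint

#: Dietary item classes tracked by the residue model, mirroring the standard
#: nomogram categories (grasses, foliage/small insects, fruits/pods/large
#: insects, seeds).
DIET_CLASSES = (
    "short_grass",
    "tall_grass",
    "broadleaf_small_insects",
    "fruits_pods_large_insects",
    "seeds",
)

#: Kenaga/Fletcher nomogram residue-per-unit-rate values (mg a.i./kg diet per
#: lb a.i./acre): (upper-bound, central) per diet class.  Overridable wherever
#: a scenario is generated.
DEFAULT_RUD_TABLE: dict[str, tuple[float, float]] = {
    "short_grass": (240.0, 85.0),
    "tall_grass": (110.0, 36.0),
    "broadleaf_small_insects": (135.0, 45.0),
    "fruits_pods_large_insects": (15.0, 7.0),
    "seeds": (15.0, 7.0),
}

NEST_PHASES = ("laying", "incubation", "nestling")


@dataclass
class PesticideScenario:
    """A pesticide use pattern: when, how much, and how fast residues dissipate."""

    name: str
    application_days: list[int]
    application_rate: float  # lbs a.i./acre
    foliar_half_life_days: float
    rud_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RUD_TABLE)
    )

    def validate(self) -> list[str]:
        v = []
        if not self.application_rate > 0:
            v.append("scenario.application_rate must be > 0")
        if not self.foliar_half_life_days > 0:
            v.append("scenario.foliar_half_life_days must be > 0")
        if sorted(self.application_days) != list(self.application_days):
            v.append("scenario.application_days must be sorted")
        if any(not 1 <= d <= 365 for d in self.application_days):
            v.append("scenario.application_days must lie in [1, 365]")
        for cls, (hi, mid) in self.rud_table.items():
            if hi < mid:
                v.append(f"scenario.rud_table[{cls!r}]: upper bound < central value")
        return v

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "application_days": list(self.application_days),
            "application_rate": self.application_rate,
            "foliar_half_life_days": self.foliar_half_life_days,
            "rud_table": {k: list(v) for k, v in self.rud_table.items()},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PesticideScenario":
        d = dict(d)
        d["rud_table"] = {k: tuple(v) for k, v in d["rud_table"].items()}
        return cls(**d)


@dataclass
class SpeciesProfile:
    """Life history of the assessed bird: exposure ecology, breeding phenology,
    and the annual vital rates (s_j, s_a, f, age at first breeding alpha) the
    lifecycle and population tiers run on.  Fecundity ``f`` follows the
    female-offspring-only convention of classical female-based models."""

    name: str
    body_weight_g: float
    diet_fractions: dict[str, float]
    intake_fraction: float  # g food / g body weight / day
    season_start_day: int
    season_end_day: int
    phase_durations: dict[str, int]
    clutch_size: int
    renest_wait_fail: int
    renest_wait_success: int
    max_broods: int
    daily_nest_survival: dict[str, float]
    s_j: float
    s_a: float
    f: float
    alpha: int = 1

    def validate(self) -> list[str]:
        v = []
        if abs(sum(self.diet_fractions.values()) - 1.0) > 1e-9:
            v.append("species.diet_fractions must sum to 1")
        if not self.season_start_day < self.season_end_day:
            v.append("species.season_start_day must precede season_end_day")
        for ph in NEST_PHASES:
            if ph not in self.phase_durations:
                v.append(f"species.phase_durations missing phase {ph!r}")
            if ph not in self.daily_nest_survival:
                v.append(f"species.daily_nest_survival missing phase {ph!r}")
        for ph, p in self.daily_nest_survival.items():
            if not 0 <= p <= 1:
                v.append(f"species.daily_nest_survival[{ph!r}] outside [0, 1]")
        for r in ("s_j", "s_a"):
            if not 0 <= getattr(self, r) <= 1:
                v.append(f"species.{r} outside [0, 1]")
        if self.f < 0:
            v.append("species.f must be >= 0")
        if self.alpha < 1:
            v.append("species.alpha must be >= 1")
        if self.body_weight_g <= 0:
            v.append("species.body_weight_g must be > 0")
        return v

    @property
    def attempt_duration(self) -> int:
        return sum(self.phase_durations[p] for p in NEST_PHASES)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SpeciesProfile":
        return cls(**d)


@dataclass
class ToxicityProfile:
    """Endpoints from the three standard avian tests (acute oral LD50, dietary
    LC50, reproduction NOAEL) plus nest-phase-specific surrogate endpoints
    whose exceedance fails a nest attempt in the tier-2 simulator."""

    ld50: Endpoint  # mg a.i./kg bw
    lc50: Endpoint  # mg a.i./kg diet
    noael: Endpoint  # mg a.i./kg diet
    test_species: str
    surrogate_endpoints: dict[str, dict[str, Any]]  # phase -> {metric, window_days, threshold}

    def validate(self) -> list[str]:
        v = []
        for ph in NEST_PHASES:
            if ph not in self.surrogate_endpoints:
                v.append(f"tox.surrogate_endpoints missing phase {ph!r}")
        for ph, ep in self.surrogate_endpoints.items():
            if ep.get("metric") not in ("peak_dose", "twa_dietary_conc"):
                v.append(f"tox.surrogate_endpoints[{ph!r}].metric unknown")
            if not ep.get("window_days", 0) >= 1:
                v.append(f"tox.surrogate_endpoints[{ph!r}].window_days must be >= 1")
            if not ep.get("threshold", 0) > 0:
                v.append(f"tox.surrogate_endpoints[{ph!r}].threshold must be > 0")
        return v

    def to_dict(self) -> dict[str, Any]:
        def full(e: Endpoint) -> str:  # full precision, round-trip safe
            return (">" if e.censored else "") + repr(e.value)

        return {
            "ld50": full(self.ld50),
            "lc50": full(self.lc50),
            "noael": full(self.noael),
            "test_species": self.test_species,
            "surrogate_endpoints": self.surrogate_endpoints,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ToxicityProfile":
        return cls(
            ld50=as_endpoint(d["ld50"]),
            lc50=as_endpoint(d["lc50"]),
            noael=as_endpoint(d["noael"]),
            test_species=d["test_species"],
            surrogate_endpoints=d["surrogate_endpoints"],
        )


@dataclass
class Landscape:
    """Gridded habitat: per-cell quality in [0, 1] scales fecundity and the
    carrying capacity round(quality * k_max); untreated cells are refugia."""

    n_rows: int
    n_cols: int
    quality: np.ndarray  # (n_rows, n_cols) floats in [0, 1]
    treated_mask: np.ndarray  # (n_rows, n_cols) bool; False = refugium
    k_max: int
    dispersal_radius: int

    @property
    def capacity(self) -> np.ndarray:
        return np.rint(self.quality * self.k_max).astype(np.int64)

    @property
    def refugia_fraction(self) -> float:
        return float((~self.treated_mask).mean())

    def validate(self) -> list[str]:
        v = []
        if self.quality.shape != (self.n_rows, self.n_cols):
            v.append("landscape.quality shape mismatch")
        if self.treated_mask.shape != (self.n_rows, self.n_cols):
            v.append("landscape.treated_mask shape mismatch")
        if np.any(self.quality < 0) or np.any(self.quality > 1):
            v.append("landscape.quality must lie in [0, 1]")
        if self.k_max < 0:
            v.append("landscape.k_max must be >= 0")
        if self.dispersal_radius < 0:
            v.append("landscape.dispersal_radius must be >= 0")
        return v

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "quality": self.quality.tolist(),
            "treated_mask": self.treated_mask.astype(int).tolist(),
            "k_max": self.k_max,
            "dispersal_radius": self.dispersal_radius,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Landscape":
        return cls(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            quality=np.asarray(d["quality"], dtype=float),
            treated_mask=np.asarray(d["treated_mask"]).astype(bool),
            k_max=d["k_max"],
            dispersal_radius=d["dispersal_radius"],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell table (row, col, quality, treated)."""
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "quality": self.quality.ravel(),
                "treated": self.treated_mask.ravel().astype(int),
            }
        )


def gen_species_profile(archetype: str, seed: int) -> SpeciesProfile:
    """Generate a species profile for one of two contrasting lifecycles.

    ``passerine`` is a small, short-lived, insectivorous songbird breeding in
    a north-temperate spring window and first reproducing at age 1;
    ``long_lived`` is an eagle-like bird with delayed maturity (first
    reproduction at year 6), high adult survival, and low fecundity.  A seed
    fully determines the profile; trait-level jitter keeps generated batteries
    from being degenerate copies of one another.
    """
    rng = np.random.default_rng(seed)
    if archetype == "passerine":
        clutch = int(rng.integers(3, 6))
        return SpeciesProfile(
            name=f"passerine-{seed}",
            body_weight_g=float(rng.uniform(15.0, 25.0)),
            diet_fractions={
                "broadleaf_small_insects": 0.7,
                "fruits_pods_large_insects": 0.2,
                "seeds": 0.1,
                "short_grass": 0.0,
                "tall_grass": 0.0,
            },
            intake_fraction=float(rng.uniform(0.9, 1.1)),
            season_start_day=121,  # early May
            season_end_day=196,  # mid July
            phase_durations={"laying": clutch, "incubation": 13, "nestling": 16},
            clutch_size=clutch,
            renest_wait_fail=5,
            renest_wait_success=10,
            max_broods=2,
            daily_nest_survival={
                ph: float(rng.uniform(0.97, 0.995)) for ph in NEST_PHASES
            },
            s_j=float(rng.uniform(0.35, 0.5)),
            s_a=float(rng.uniform(0.45, 0.6)),
            f=float(rng.uniform(1.8, 2.8)),
            alpha=1,
        )
    if archetype == "long_lived":
        return SpeciesProfile(
            name=f"long-lived-{seed}",
            body_weight_g=float(rng.uniform(4000.0, 5500.0)),
            diet_fractions={
                "fruits_pods_large_insects": 1.0,
                "broadleaf_small_insects": 0.0,
                "seeds": 0.0,
                "short_grass": 0.0,
                "tall_grass": 0.0,
            },
            intake_fraction=float(rng.uniform(0.08, 0.12)),
            season_start_day=60,
            season_end_day=240,
            phase_durations={"laying": 3, "incubation": 35, "nestling": 77},
            clutch_size=2,
            renest_wait_fail=14,
            renest_wait_success=30,
            max_broods=1,
            daily_nest_survival={
                ph: float(rng.uniform(0.985, 0.999)) for ph in NEST_PHASES
            },
            s_j=float(rng.uniform(0.55, 0.7)),
            s_a=float(rng.uniform(0.85, 0.92)),
            f=float(rng.uniform(0.3, 0.5)),
            alpha=6,
        )
    raise ValueError(
        f"unknown archetype {archetype!r}; expected 'passerine' or 'long_lived'"
    )


def gen_pesticide_scenario(
    seed: int,
    n_applications: int,
    rate: float,
    half_life: float,
    window: tuple[int, int] = (140, 185),
    rud_table: dict[str, tuple[float, float]] | None = None,
) -> tuple[PesticideScenario, ToxicityProfile]:
    """Generate a use scenario and a matching toxicity profile.

    Application days are drawn inside *window* (default: overlapping a
    north-temperate breeding season).  Toxicity endpoints are drawn lognormal
    around moderately toxic defaults, occasionally censored at the top test
    level; surrogate endpoints cover all three nest phases (time-weighted
    average dietary concentration for laying/incubation, peak daily dose for
    nestling care).
    """
    if n_applications < 1:
        raise ValueError("n_applications must be >= 1")
    if rate <= 0:
        raise ValueError("application rate must be > 0")
    if half_life <= 0:
        raise ValueError("foliar half-life must be > 0")
    rng = np.random.default_rng(seed)
    days = sorted(
        int(d)
        for d in rng.choice(
            np.arange(window[0], window[1] + 1),
            size=n_applications,
            replace=False,
        )
    )
    scenario = PesticideScenario(
        name=f"scenario-{seed}",
        application_days=days,
        application_rate=float(rate),
        foliar_half_life_days=float(half_life),
        rud_table=dict(rud_table or DEFAULT_RUD_TABLE),
    )
    ld50 = float(rng.lognormal(np.log(150.0), 1.0))
    lc50 = float(rng.lognormal(np.log(500.0), 1.0))
    noael = float(rng.lognormal(np.log(60.0), 1.0))
    tox = ToxicityProfile(
        ld50=Endpoint(min(ld50, 2250.0), censored=ld50 > 2250.0),
        lc50=Endpoint(min(lc50, 5620.0), censored=lc50 > 5620.0),
        noael=Endpoint(noael),
        test_species="Colinus virginianus",
        surrogate_endpoints={
            "laying": {
                "metric": "twa_dietary_conc",
                "window_days": 7,
                "threshold": noael * float(rng.uniform(0.8, 1.5)),
            },
            "incubation": {
                "metric": "twa_dietary_conc",
                "window_days": 7,
                "threshold": noael * float(rng.uniform(0.8, 1.5)),
            },
            "nestling": {
                "metric": "peak_dose",
                "window_days": 1,
                "threshold": min(ld50, 2250.0) * float(rng.uniform(0.05, 0.2)),
            },
        },
    )
    return scenario, tox


def gen_landscape(
    n_rows: int,
    n_cols: int,
    refugia_fraction: float,
    smoothing: float,
    seed: int,
    k_max: int = 25,
    dispersal_radius: int = 2,
) -> Landscape:
    """Generate a patchy landscape with spatially autocorrelated habitat quality.

    Quality is a uniform random field passed through a Gaussian blur of width
    *smoothing* (cells) and rescaled to span [0, 1]; refugia (untreated cells)
    are a seeded random subset of round(refugia_fraction * n_cells) cells.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("landscape grid must be non-empty")
    if not 0.0 <= refugia_fraction <= 1.0:
        raise ValueError("refugia_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=(n_rows, n_cols))
    if smoothing > 0:
        raw = ndimage.gaussian_filter(raw, sigma=smoothing, mode="wrap")
    lo, hi = raw.min(), raw.max()
    quality = (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)

    n_cells = n_rows * n_cols
    n_refugia = int(round(refugia_fraction * n_cells))
    treated = np.ones(n_cells, dtype=bool)
    refugia_idx = rng.choice(n_cells, size=n_refugia, replace=False)
    treated[refugia_idx] = False
    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        quality=quality,
        treated_mask=treated.reshape(n_rows, n_cols),
        k_max=k_max,
        dispersal_radius=dispersal_radius,
    )


_FIXTURES = ("table2_rq", "table5_gnatcatcher")


def load_fixture(name: str):
    """Load a packaged comparison table.

    ``table2_rq``: 13-pesticide insectivore risk-quotient screen as a
    DataFrame with censoring flags parsed from '>'/'<' notation.
    ``table5_gnatcatcher``: California gnatcatcher ideal-habitat vital rates
    as a dict {s_j, s_a, f}.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    path = importlib.resources.files("plra.data").joinpath(f"{name}.csv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, dtype=str)
    if name == "table5_gnatcatcher":
        return {row["rate"]: float(row["value"]) for _, row in df.iterrows()}

    def split(col: str, flag_char: str) -> tuple[pd.Series, pd.Series]:
        flagged = df[col].str.startswith(flag_char)
        vals = df[col].str.lstrip("<>").astype(float)
        return vals, flagged

    out = pd.DataFrame({"pesticide": df["pesticide"], "test_species": df["test_species"]})
    out["ld50"], out["ld50_censored"] = split("ld50", ">")
    out["lc50"], out["lc50_censored"] = split("lc50", ">")
    # RQs built on censored denominators are printed as upper bounds ("<x")
    out["acute_rq"], out["acute_rq_censored"] = split("acute_rq", "<")
    out["chronic_rq"], out["chronic_rq_censored"] = split("chronic_rq", "<")
    return out


def species_from_rates(
    s_j: float,
    s_a: float,
    f: float,
    alpha: int = 1,
    name: str = "custom",
    archetype: str = "passerine",
    seed: int = 0,
) -> SpeciesProfile:
    """A generated archetype profile with its annual vital rates overridden —
    the easiest way to run the lifecycle and population tiers on published
    rates (e.g. the gnatcatcher fixture)."""
    base = gen_species_profile(archetype, seed)
    return replace(base, name=name, s_j=s_j, s_a=s_a, f=f, alpha=alpha)


def untreated(landscape: Landscape) -> Landscape:
    """Copy of *landscape* with no treated cells (all refugia)."""
    return replace(landscape, treated_mask=np.zeros_like(landscape.treated_mask))
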