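"""Nest-productivity simulator: deterministic cases, Monte-Carlo calibration,
exposure dominance, and season accounting."""

from dataclasses import replace

import numpy as np
import pytest

import plra
from conftest import single_pulse_scenario


def make_species(
    clutch=4,
    durations=(4, 10, 10),
    survival=1.0,
    season=(100, 200),
    waits=(5, 10),
    max_broods=2,
):
    phases = dict(zip(("laying", "incubation", "nestling"), durations))
    return plra.SpeciesProfile(
        name="test-bird",
        body_weight_g=20.0,
        diet_fractions={"seeds": 1.0},
        intake_fraction=1.0,
        season_start_day=season[0],
        season_end_day=season[1],
        phase_durations=phases,
        clutch_size=clutch,
        renest_wait_fail=waits[0],
        renest_wait_success=waits[1],
        max_broods=max_broods,
        daily_nest_survival={p: survival for p in phases},
        s_j=0.43,
        s_a=0.52,
        f=2.26,
    )


def make_tox(threshold=np.inf, metric="peak_dose", window=1):
    ep = {"metric": metric, "window_days": window, "threshold": threshold}
    return plra.ToxicityProfile(
        ld50=plra.Endpoint(100.0),
        lc50=plra.Endpoint(500.0),
        noael=plra.Endpoint(50.0),
        test_species="Colinus virginianus",
        surrogate_endpoints={p: dict(ep) for p in ("laying", "incubation", "nestling")},
    )


class TestSimulateFemale:
    def test_deterministic_two_broods(self):
        # 24-day attempts, perfect survival, no exposure: the 101-day season
        # fits exactly two broods of four
        sp = make_species(clutch=4, durations=(4, 10, 10), survival=1.0, season=(100, 200))
        exposure = plra.zero_exposure(sp, horizon=(1, 250))
        out = plra.simulate_female(sp, exposure, make_tox(), rng_seed=0)
        assert out.total_fledglings == 8
        assert [a.fate for a in out.attempts] == ["fledged", "fledged"]

    def test_zero_threshold_with_exposure_fails_everything(self, passerine):
        scen = single_pulse_scenario(day=1, half_life=1e6)
        exposure = plra.build_exposure(scen, passerine)
        tox = make_tox(threshold=0.0)
        tox.surrogate_endpoints = {
            p: {"metric": "peak_dose", "window_days": 1, "threshold": 1e-12}
            for p in ("laying", "incubation", "nestling")
        }
        out = plra.simulate_female(passerine, exposure, tox, rng_seed=0)
        assert out.total_fledglings == 0
        assert all(a.fate == "failed_exposure" for a in out.attempts)

    def test_phases_in_order_with_configured_durations(self):
        sp = make_species(durations=(3, 7, 9), survival=1.0, max_broods=1)
        exposure = plra.zero_exposure(sp, horizon=(1, 250))
        out = plra.simulate_female(sp, exposure, make_tox(), rng_seed=0)
        log = out.attempts[0].phase_log
        assert [p for p, _, _ in log] == ["laying", "incubation", "nestling"]
        assert [e - s + 1 for _, s, e in log] == [3, 7, 9]
        # consecutive phases abut
        assert all(log[i + 1][1] == log[i][2] + 1 for i in range(2))

    def test_attempts_never_overlap_and_respect_season(self):
        sp = make_species(survival=0.95, season=(100, 180))
        exposure = plra.zero_exposure(sp, horizon=(1, 250))
        for seed in range(30):
            out = plra.simulate_female(sp, exposure, make_tox(), rng_seed=seed)
            ends = [a.phase_log[-1][2] for a in out.attempts]
            starts = [a.start_day for a in out.attempts]
            assert all(s2 > e1 for e1, s2 in zip(ends, starts[1:]))
            assert all(e <= sp.season_end_day for e in ends)

    def test_start_anytime_truncates_at_season_end(self):
        sp = make_species(survival=1.0, season=(100, 110), max_broods=1)
        exposure = plra.zero_exposure(sp, horizon=(1, 250))
        strict = plra.simulate_female(sp, exposure, make_tox(), 0)
        loose = plra.simulate_female(sp, exposure, make_tox(), 0, require_full_fit=False)
        assert strict.attempts == []  # 24-day attempt cannot fit
        assert [a.fate for a in loose.attempts] == ["truncated_by_season"]
        assert loose.total_fledglings == 0

    def test_exposure_not_covering_season_rejected(self):
        sp = make_species(season=(100, 200))
        exposure = plra.zero_exposure(sp, horizon=(120, 250))
        with pytest.raises(ValueError, match="cover"):
            plra.simulate_female(sp, exposure, make_tox(), 0)


class TestSeasonalProductivity:
    def test_monte_carlo_matches_survival_product_oracle(self):
        # single 24-day attempt, uniform survival 0.98: closed-form mean
        # 4 * 0.98**24; Monte-Carlo must agree within 3 standard errors
        sp = make_species(
            clutch=4, durations=(4, 10, 10), survival=0.98, season=(100, 124), max_broods=1
        )
        exposure = plra.zero_exposure(sp, horizon=(1, 250))
        res = plra.seasonal_productivity(sp, exposure, make_tox(), 10_000, rng_seed=7)
        expected = 4 * 0.98**24
        se = res["sd"] / np.sqrt(10_000)
        assert abs(res["mean"] - expected) < 3 * se

    def test_determinism_with_shared_seed(self, passerine):
        exposure = plra.zero_exposure(passerine)
        a = plra.seasonal_productivity(passerine, exposure, make_tox(), 50, rng_seed=3)
        b = plra.seasonal_productivity(passerine, exposure, make_tox(), 50, rng_seed=3)
        np.testing.assert_array_equal(a["per_female"], b["per_female"])

    def test_control_vs_control_difference_exactly_zero(self, passerine):
        exposure = plra.zero_exposure(passerine)
        a = plra.seasonal_productivity(passerine, exposure, make_tox(), 200, rng_seed=5)
        b = plra.seasonal_productivity(passerine, exposure, make_tox(), 200, rng_seed=5)
        assert a["mean"] - b["mean"] == 0.0

    def test_treated_mean_never_above_control_with_common_randomness(self, passerine):
        scen = single_pulse_scenario(day=150, rud=135.0)
        tox = make_tox()
        tox.surrogate_endpoints = {
            p: {"metric": "peak_dose", "window_days": 1, "threshold": 50.0}
            for p in ("laying", "incubation", "nestling")
        }
        sp = replace(passerine, daily_nest_survival={p: 0.98 for p in ("laying", "incubation", "nestling")})
        treated_exp = plra.build_exposure(scen, sp)
        control_exp = plra.zero_exposure(sp)
        diffs = []
        for seed in range(20):
            t = plra.seasonal_productivity(sp, treated_exp, tox, 100, rng_seed=seed)
            c = plra.seasonal_productivity(sp, control_exp, tox, 100, rng_seed=seed)
            diffs.append(c["mean"] - t["mean"])
        assert np.mean(diffs) >= 0

    def test_invalid_n_females_rejected(self, passerine):
        with pytest.raises(ValueError):
            plra.seasonal_productivity(passerine, plra.zero_exposure(passerine), make_tox(), 0, 1)


class TestNestTier:
    def test_null_scenario_zero_effect(self, passerine):
        scen = single_pulse_scenario(day=150, rud=0.0)
        result = plra.nest_tier(scen, passerine, make_tox(), n_females=100, seed=4)
        assert result.scaled_effect == 0.0
        assert result.decision == "low_risk"

    def test_total_failure_gives_effect_one(self, passerine):
        scen = single_pulse_scenario(day=1, half_life=1e6)
        tox = make_tox()
        tox.surrogate_endpoints = {
            p: {"metric": "peak_dose", "window_days": 1, "threshold": 1e-12}
            for p in ("laying", "incubation", "nestling")
        }
        result = plra.nest_tier(scen, passerine, tox, n_females=100, seed=4)
        assert result.scaled_effect == 1.0
        assert result.decision == "escalate"

    def test_refined_vs_screening_ranks_either_way(self, passerine):
        """Elimination kinetics raise the dose metric while central residues
        lower it, so the refined variant can land on either side of the
        screening variant depending on the elimination half-life."""
        scen = single_pulse_scenario(day=150, half_life=20.0, rud=30.0)
        tox = make_tox()
        tox.surrogate_endpoints = {
            p: {"metric": "peak_dose", "window_days": 1, "threshold": 25.0}
            for p in ("laying", "incubation", "nestling")
        }
        kw = dict(n_females=200, seed=9)
        screening = plra.nest_tier(scen, passerine, tox, "screening", **kw)
        fast = plra.nest_tier(
            scen, passerine, tox, "refined", elimination_halflife_days=0.1, **kw
        )
        slow = plra.nest_tier(
            scen, passerine, tox, "refined", elimination_halflife_days=30.0, **kw
        )
        signs = {
            np.sign(fast.scaled_effect - screening.scaled_effect),
            np.sign(slow.scaled_effect - screening.scaled_effect),
        }
        assert {-1.0, 1.0} <= signs
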