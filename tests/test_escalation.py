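"""Escalation sequence, effect scaling, bias estimation, paired parameterizations."""

from dataclasses import replace

import numpy as np
import pytest

import plra
from plra.core import TIER_ORDER


class TestScaleEffect:
    def test_basic_values(self):
        assert plra.scale_effect(10.0, 10.0) == 0.0
        assert plra.scale_effect(5.0, 10.0) == 0.5
        assert plra.scale_effect(0.0, 10.0) == 1.0

    def test_clipped_to_unit_interval(self):
        assert plra.scale_effect(15.0, 10.0) == 0.0  # treated above control

    def test_rq_tier_refused(self):
        with pytest.raises(ValueError, match="risk quotient"):
            plra.scale_effect(1.0, 2.0, tier="rq")

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            plra.scale_effect(1.0, 0.0)


class TestRunSequence:
    def test_zero_rate_scenario_stops_at_rq(self, run_config):
        cfg = replace(
            run_config, scenario=replace(run_config.scenario, application_rate=1e-9)
        )
        report = plra.run_sequence(cfg, seed=1)
        assert report.stopping_tier == "rq"
        assert report.final_decision == "low_risk"
        assert [r.tier for r in report.results] == ["rq"]

    def test_worst_case_runs_all_tiers_and_is_unacceptable(self, run_config):
        tox = run_config.tox
        tox = replace(
            tox,
            surrogate_endpoints={
                p: {"metric": "peak_dose", "window_days": 1, "threshold": 1e-9}
                for p in ("laying", "incubation", "nestling")
            },
        )
        scen = replace(
            run_config.scenario, application_days=[1], foliar_half_life_days=1e6
        )
        land = plra.gen_landscape(10, 10, 0.0, 1.0, 5, k_max=10)
        cfg = replace(run_config, tox=tox, scenario=scen, landscape=land, years=40)
        report = plra.run_sequence(cfg, seed=2)
        assert [r.tier for r in report.results] == list(TIER_ORDER)
        assert report.final_decision == "unacceptable"
        assert report.results[-1].decision == "unacceptable"

    def test_refugia_can_overturn_lower_tier_escalation(self, run_config):
        """The lifecycle tier predicts collapse for exposed individuals, but
        the population tier's refugia relax that conservatism."""
        tox = replace(
            run_config.tox,
            surrogate_endpoints={
                p: {"metric": "peak_dose", "window_days": 1, "threshold": 1e-9}
                for p in ("laying", "incubation", "nestling")
            },
        )
        scen = replace(
            run_config.scenario, application_days=[1], foliar_half_life_days=1e6
        )
        land = plra.gen_landscape(10, 10, 0.4, 1.0, 5, k_max=15)
        cfg = replace(run_config, tox=tox, scenario=scen, landscape=land, years=30)
        report = plra.run_sequence(cfg, seed=2)
        assert [r.tier for r in report.results] == list(TIER_ORDER)
        nest_m = report.results[1].scaled_effect
        sepm_m = report.results[3].scaled_effect
        assert nest_m == pytest.approx(1.0)
        assert sepm_m < nest_m

    def test_ordering_and_stopping_invariants_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            seed = int(rng.integers(0, 2**16))
            scenario, tox = plra.gen_pesticide_scenario(
                seed, int(rng.integers(1, 4)), float(rng.uniform(0.01, 2.0)), 20.0
            )
            species = plra.gen_species_profile("passerine", seed)
            land = plra.gen_landscape(6, 6, 0.3, 1.0, seed, k_max=6)
            cfg = plra.RunConfig(
                scenario=scenario, species=species, tox=tox, landscape=land,
                n_females=50, years=10, sepm_reps=2, master_seed=seed,
            )
            report = plra.run_sequence(cfg)
            tiers = [r.tier for r in report.results]
            assert tiers == list(TIER_ORDER)[: len(tiers)]
            if report.stopping_tier is not None:
                # nothing runs after the stopping tier, which rendered low risk
                assert tiers[-1] == report.stopping_tier
                assert report.results[-1].decision == "low_risk"
                assert all(r.decision != "low_risk" for r in report.results[:-1])

    def test_invalid_acceptable_effect_rejected(self, run_config):
        with pytest.raises(ValueError, match="acceptable_effect"):
            plra.run_sequence(run_config, acceptable_effect=1.5)


class TestOracleTruth:
    def test_null_treatment_truth_near_zero(self, run_config):
        cfg = replace(
            run_config, scenario=replace(run_config.scenario, application_rate=1e-9)
        )
        truth = plra.oracle_truth(cfg, reps=4, seed=3)
        assert truth["mean"] == pytest.approx(0.0, abs=0.05)

    def test_fixed_seed_reproducible(self, run_config):
        a = plra.oracle_truth(run_config, reps=3, seed=5)
        b = plra.oracle_truth(run_config, reps=3, seed=5)
        np.testing.assert_array_equal(a["draws"], b["draws"])

    def test_replicate_spread_shrinks_with_landscape_size(self, run_config):
        big = replace(
            run_config,
            landscape=plra.gen_landscape(20, 20, 0.3, 1.0, 5, k_max=30),
            sepm_reps=4,
        )
        small = replace(
            run_config,
            landscape=plra.gen_landscape(4, 4, 0.3, 1.0, 5, k_max=3),
            sepm_reps=1,
        )
        sd_small = plra.oracle_truth(small, reps=8, seed=7)["draws"].std()
        sd_big = plra.oracle_truth(big, reps=8, seed=7)["draws"].std()
        assert sd_big < sd_small


class TestEstimateBias:
    def test_zero_when_predictions_equal_truth(self):
        y = [0.1, 0.3, 0.5, 0.2]
        estimates, diag = plra.estimate_bias({"nestsim": y, "elm": y, "sepm": y}, y)
        assert all(e.mean_bias == 0.0 for e in estimates)
        assert diag["efficiency_holds"]

    def test_constant_shift_recovered_exactly(self):
        y = np.array([0.1, 0.3, 0.5, 0.2])
        estimates, _ = plra.estimate_bias({"nestsim": y + 0.1}, y)
        assert estimates[0].mean_bias == pytest.approx(0.1)
        assert estimates[0].sign_consistency == 1.0

    def test_hand_computed_mean_and_sd(self):
        y = np.array([0.0, 0.0])
        estimates, _ = plra.estimate_bias({"elm": [0.2, 0.4]}, y)
        assert estimates[0].mean_bias == pytest.approx(0.3)
        assert estimates[0].sd == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="truth draws"):
            plra.estimate_bias({"elm": [0.1]}, [0.1, 0.2])

    def test_nonmonotone_bias_detected(self):
        y = [0.0, 0.0, 0.0]
        _, diag = plra.estimate_bias(
            {"nestsim": [0.1] * 3, "elm": [0.05] * 3, "sepm": [0.2] * 3}, y
        )
        assert not diag["nonincreasing"]
        assert not diag["efficiency_holds"]


class TestBattery:
    def test_strong_stressor_battery_is_conservative_and_ordered(self):
        out = plra.run_battery(plra.BatterySpec(rate=1.0), reps=5, seed=5)
        by_tier = {e.tier: e.mean_bias for e in out["bias"]}
        assert set(by_tier) == {"nestsim", "elm", "sepm"}
        assert out["diagnostic"]["all_nonnegative"]

    def test_some_battery_breaks_monotone_decline(self):
        """Added realism need not reduce conservatism: across a small family
        of scenario batteries at least one yields a non-monotone bias
        sequence."""
        monotone = []
        for rate in (1e-4, 0.05, 1.0):
            out = plra.run_battery(
                plra.BatterySpec(rate=rate, sepm_reps=1, n_females=100),
                reps=6,
                seed=17,
            )
            monotone.append(out["diagnostic"]["nonincreasing"])
        assert not all(monotone)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            plra.run_battery(plra.BatterySpec(), reps=1, seed=0)


class TestPairedRun:
    def test_conservative_rq_dominates_central(self, run_config):
        out = plra.paired_run(run_config, seed=3)
        assert out["conservative"]["rq"] >= out["central"]["rq"]
        assert out["distance"]["rq"] >= 0

    def test_distances_reported_for_all_tiers(self, run_config):
        out = plra.paired_run(run_config, seed=3)
        assert set(out["distance"]) == set(TIER_ORDER)
        assert isinstance(out["diminishing"], bool)

    def test_identical_parameterizations_zero_distance(self, run_config):
        """Collapsing the RUD table to a single value makes the conservative
        and central arms identical, so every distance vanishes."""
        scen = run_config.scenario
        flat = replace(
            scen, rud_table={c: (45.0, 45.0) for c in scen.rud_table}
        )
        out = plra.paired_run(replace(run_config, scenario=flat), seed=3)
        assert all(d == pytest.approx(0.0) for d in out["distance"].values())


def test_plot_bias_curve_writes_figure(tmp_path):
    estimates = [
        plra.BiasEstimate("nestsim", 0.4, 0.1, 5, 1.0),
        plra.BiasEstimate("elm", 0.2, 0.1, 5, 0.8),
        plra.BiasEstimate("sepm", 0.05, 0.1, 5, 0.6),
    ]
    out = tmp_path / "bias.png"
    plra.plot_bias_curve(estimates, str(out))
    assert out.stat().st_size > 0
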