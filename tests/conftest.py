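import numpy as np
import pytest

import plra


@pytest.fixture
def passerine():
    return plra.gen_species_profile("passerine", 1)


@pytest.fixture
def scenario_tox():
    return plra.gen_pesticide_scenario(3, 2, 1.0, 35.0)


@pytest.fixture
def gnatcatcher():
    """Species profile carrying the packaged gnatcatcher vital rates."""
    rates = plra.load_fixture("table5_gnatcatcher")
    return plra.species_from_rates(
        rates["s_j"], rates["s_a"], rates["f"], name="gnatcatcher-like"
    )


@pytest.fixture
def small_landscape():
    return plra.gen_landscape(10, 10, 0.3, 1.0, 5, k_max=10, dispersal_radius=2)


@pytest.fixture
def run_config(passerine, scenario_tox, small_landscape):
    scenario, tox = scenario_tox
    return plra.RunConfig(
        scenario=scenario,
        species=passerine,
        tox=tox,
        landscape=small_landscape,
        n_females=200,
        years=15,
        sepm_reps=3,
        master_seed=11,
    )


def single_pulse_scenario(rate=1.0, half_life=35.0, day=150, rud=135.0):
    """Scenario with one application and a single flat RUD across classes."""
    return plra.PesticideScenario(
        name="pulse",
        application_days=[day],
        application_rate=rate,
        foliar_half_life_days=half_life,
        rud_table={cls: (rud, rud / 3.0) for cls in plra.DIET_CLASSES},
    )
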