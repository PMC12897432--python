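import pytest

from cowcalf import (GenotypeSpec, SimulationConfig, run_experiment,
                     summarize_scenarios)


@pytest.fixture()
def small_config():
    """A quick-running configuration for unit and property tests."""
    return SimulationConfig(rng_seed=7, herd_size=40, horizon_years=6,
                            n_replicates=1, burn_in_years=2)


@pytest.fixture()
def mid_genotype():
    return GenotypeSpec(msbw_mean=550.0, peak_milk_mean=10.0)


@pytest.fixture(scope="session")
def study_run():
    """The full study design at its stated scale: 9 genotypes x 4 intake
    levels x 5 seeded replicates, 100 cows for 24 years, 3-year burn-in.

    Session-scoped because the stacked simulation takes ~half a minute;
    acceptance-level checks all read from this single run.
    """
    config = SimulationConfig(rng_seed=1)
    result = run_experiment(config)
    summary = summarize_scenarios(result.per_year, config)
    return config, result, summary
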