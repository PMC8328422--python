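import numpy as np
import pytest

from scalechron import (
    CohortConfig,
    GenerativeParams,
    GrowthModelSpec,
    SamplerConfig,
    build_design,
    exclude_rare_life_histories,
    filter_increments,
    fit,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-composition cohort (1,603 fish incl. rare life histories), unfiltered."""
    dataset, temperature, year_effects = generate_cohort(
        CohortConfig(), GenerativeParams(), seed=11
    )
    return dataset, temperature, year_effects


@pytest.fixture(scope="session")
def small_filtered():
    """Small filtered dataset for cheap model tests."""
    dataset, temperature, year_effects = generate_cohort(
        CohortConfig(n_fish=150, rare_life_histories={}), GenerativeParams(), seed=7
    )
    dataset = filter_increments(exclude_rare_life_histories(dataset))
    return dataset, temperature, year_effects


@pytest.fixture(scope="session")
def medium_fit():
    """Mid-sized cohort with a fitted model, shared by chronology/climate tests."""
    dataset, temperature, year_effects = generate_cohort(
        CohortConfig(n_fish=400, rare_life_histories={}), GenerativeParams(), seed=5
    )
    dataset = filter_increments(exclude_rare_life_histories(dataset))
    spec = GrowthModelSpec()
    design = build_design(dataset, spec)
    with np.errstate(all="ignore"):
        samples = fit(design, spec, SamplerConfig(draws=600, burnin=300, chains=2), seed=6)
    return dataset, temperature, year_effects, design, samples
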